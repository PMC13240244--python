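import numpy as np
import pytest

from glpop.simdata import gl_from_genotypes  # noqa: F401  (shared fixture helper)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_deme_sim():
    """Small two-deme simulated dataset shared across tests (FST 0.05)."""
    from glpop import simdata
    cfg = simdata.SimConfig(n_demes=2, n_per_deme=30, seed=99,
                            chrom_layout=(("chr1", 10_000_000, 10_000),),
                            deme_graph=((0, 1, 0.05),), mean_depth=2.0)
    return simdata.simulate_dataset(cfg)
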