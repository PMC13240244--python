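#!/usr/bin/env python
"""Quality control: site filters, paralog surrogate, sample filters.

Reads the Beagle dataset from 01_simulate.py, applies the MAF / coverage /
depth site filters and the excess-heterozygosity paralog surrogate, then
reports per-sample missingness and duplicate screening.  Writes the
filtered marker list and the per-stage reports under results/qc/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from glpop import gl_io, qc

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = BASE / "data"
    out = BASE / "qc"
    out.mkdir(parents=True, exist_ok=True)
    ds = gl_io.read_beagle(data / "study.beagle")
    depths = gl_io.read_depth_sidecar(data / "study.depths.tsv", ds)

    kept, site_report = qc.filter_sites(ds, depths=depths)
    site_report.to_csv(out / "site_filters.tsv", sep="\t", index=False)
    print(f"site filters: {ds.n_markers} -> {kept.n_markers} "
          f"({site_report['pass_maf'].sum()} pass MAF, "
          f"{site_report['pass_cover'].sum()} pass coverage)")

    flags, het_report = qc.excess_het_filter(kept)
    het_report.to_csv(out / "excess_het.tsv", sep="\t", index=False)
    kept2 = kept.subset_markers(np.where(~flags)[0])
    print(f"excess-het surrogate: removed {int(flags.sum())} deviant sites, "
          f"{kept2.n_markers} remain")

    miss = qc.sample_missingness(kept2)
    kept3, removed, cutoff = qc.filter_samples(kept2)
    pd.DataFrame({"id": kept2.individuals, "missingness": miss,
                  "removed": [i in removed for i in kept2.individuals]}
                 ).to_csv(out / "sample_missingness.tsv", sep="\t",
                          index=False)
    print(f"missingness cutoff {cutoff:.3f}: removed {len(removed)} samples")

    pairs, to_remove = qc.detect_duplicates(kept3)
    pd.DataFrame(pairs, columns=["a", "b", "r"]).to_csv(
        out / "duplicates.tsv", sep="\t", index=False)
    print(f"duplicate screen: {len(pairs)} pairs flagged, "
          f"{len(to_remove)} samples marked")

    final = kept3.subset_individuals(
        [i for i, ind in enumerate(kept3.individuals)
         if ind not in to_remove])
    gl_io.write_beagle(final, data / "study.filtered.beagle")
    print(f"final: {final.n_markers} markers x {final.n_individuals} samples")


if __name__ == "__main__":
    main()
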