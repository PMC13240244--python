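"""Synthetic low-coverage genotype-likelihood datasets with known truth.

The generator emulates the statistical structure low-coverage population
pipelines assume: multiple demes connected by a drift graph (Balding-Nichols
frequency draws along a spanning tree), an optional divergently selected
region, an optional inversion polymorphism (two non-recombining haplogroups
producing three karyotype clusters with elevated heterokaryotype
heterozygosity and elevated internal LD), shallow Poisson read depth with
sequencing error, and emission as genotype likelihoods plus a truth ledger.

Drift calibration
-----------------
An edge drift coefficient ``F`` is defined as the *target pairwise Hudson
FST* across that edge.  A child deme's frequency is drawn from
``Beta(p(1-c)/c, (1-p)(1-c)/c)`` around its parent's frequency ``p`` with
conditional coefficient ``c = 2F``: with the parent the pair's common
ancestor, expected Hudson FST equals ``c/2 = F`` exactly (ratio of expected
numerator and denominator), so a two-deme graph with edge ``F = 0.05``
yields genome-wide FST near 0.05.  Valid edge range is therefore (0, 0.5).

SNP positions are laid on a regular per-chromosome grid, and divergent
inversion sites are placed by a regular stride within the span; both choices
make window membership and LD-based boundary refinement deterministic up to
sampling noise (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gl_io import GLDataset, RasterMap, SampleTable

_SUBSTREAMS = ("ancestral", "drift", "inversion", "outlier", "genotypes",
               "reads", "alleles", "misc")

_FREQ_CLAMP = 1e-6


@dataclass
class InversionSpec:
    chrom: str
    start: int
    end: int
    deme_freqs: tuple[float, ...]      # inversion-allele frequency per deme
    divergent_fraction: float = 0.5    # fraction of in-span SNPs split by delta
    delta: float = 0.8                 # |p_A - p_B| at divergent sites


@dataclass
class OutlierRegionSpec:
    chrom: str
    start: int
    end: int
    deme_shifts: tuple[float, ...]     # allele-frequency shift per deme


@dataclass
class SimConfig:
    n_demes: int = 2
    n_per_deme: int = 30
    chrom_layout: tuple[tuple[str, int, int], ...] = (("chr1", 10_000_000, 10_000),)
    deme_graph: tuple[tuple[int, int, float], ...] = ((0, 1, 0.05),)
    deme_coords: tuple[tuple[int, int], ...] | None = None  # (row, col) per deme
    inversion: InversionSpec | None = None
    outlier_region: OutlierRegionSpec | None = None
    mean_depth: float = 1.5            # Poisson lambda, reads per site
    error_rate: float = 0.005          # per-read miscall probability
    maf_floor: float = 0.05            # ancestral Uniform(maf_floor, 0.5)
    neutral_sfs_mode: bool = False     # ancestral density ~ 1/x (neutral SFS)
    pop_size: int = 10_000             # truncation 1/(2N) in neutral mode
    individual_q: np.ndarray | None = None  # (N, n_demes) admixture proportions
    seed: int = 0

    @property
    def n_snps(self) -> int:
        return sum(n for _, _, n in self.chrom_layout)

    @property
    def n_individuals(self) -> int:
        if self.individual_q is not None:
            return self.individual_q.shape[0]
        return self.n_demes * self.n_per_deme

    def validate(self) -> None:
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        for u, v, f in self.deme_graph:
            if not (0.0 < f < 0.5):
                raise ValueError(
                    f"edge drift F={f} outside (0, 0.5); F is the target pairwise "
                    "FST across the edge (realised conditional coefficient 2F)")
        lengths = {c: l for c, l, _ in self.chrom_layout}
        for spec in (self.inversion, self.outlier_region):
            if spec is not None:
                if spec.chrom not in lengths:
                    raise ValueError(f"{spec.chrom} not in chrom_layout")
                if not (1 <= spec.start < spec.end <= lengths[spec.chrom]):
                    raise ValueError("region span outside chromosome")
        if self.inversion is not None and self.outlier_region is not None:
            a, b = self.inversion, self.outlier_region
            if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                raise ValueError("inversion and outlier spans overlap")


@dataclass
class TruthLedger:
    """Ground truth recorded by the generator, used by recovery tests."""

    deme_freqs: np.ndarray              # (S, D)
    expected_fst: np.ndarray            # (D, D)
    genotypes: np.ndarray               # (S, N) in {0,1,2}
    deme_of_individual: np.ndarray      # (N,)
    inversion_span: tuple[str, int, int] | None = None
    karyotypes: np.ndarray | None = None          # (N,) copies of arrangement B
    inversion_divergent_sites: np.ndarray | None = None  # marker ordinals
    outlier_span: tuple[str, int, int] | None = None
    ancestral_freqs: np.ndarray | None = None     # (S,)


@dataclass
class SimResult:
    dataset: GLDataset
    depths: np.ndarray
    samples: SampleTable
    truth: TruthLedger
    config: SimConfig


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_SUBSTREAMS, children)}


def _spanning_tree(n_demes: int, edges) -> list[tuple[int, int, float]]:
    """BFS spanning tree from deme 0; errors on a disconnected graph."""
    adj: dict[int, list[tuple[int, float]]] = {d: [] for d in range(n_demes)}
    for u, v, f in edges:
        adj[u].append((v, f))
        adj[v].append((u, f))
    seen = {0}
    order: list[tuple[int, int, float]] = []
    frontier = [0]
    while frontier:
        nxt = []
        for u in frontier:
            for v, f in sorted(adj[u]):
                if v not in seen:
                    seen.add(v)
                    order.append((u, v, f))
                    nxt.append(v)
        frontier = nxt
    if len(seen) != n_demes:
        raise ValueError("deme_graph is disconnected")
    return order


def _balding_nichols(rng, p: np.ndarray, c: float) -> np.ndarray:
    a = p * (1.0 - c) / c
    b = (1.0 - p) * (1.0 - c) / c
    q = rng.beta(a, b)
    return np.clip(q, _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)


def simulate_ancestral_frequencies(config: SimConfig,
                                   rng: np.random.Generator) -> np.ndarray:
    s = config.n_snps
    if config.neutral_sfs_mode:
        # density ~ 1/x truncated to [1/(2N), 1 - 1/(2N)]; inverse-CDF sampling
        a = 1.0 / (2 * config.pop_size)
        b = 1.0 - a
        u = rng.random(s)
        return a * (b / a) ** u
    return rng.uniform(config.maf_floor, 0.5, size=s)


def simulate_deme_frequencies(config: SimConfig,
                              rng: np.random.Generator | None = None,
                              ancestral: np.ndarray | None = None,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-deme frequencies along a spanning traversal of the deme graph.

    Returns ``(freqs (S, D), ancestral (S,))``.  Deme 0 carries the ancestral
    frequencies; each tree child is a Balding-Nichols draw around its parent
    with conditional coefficient ``2 F_edge`` (see module docstring).
    """
    config.validate()
    if rng is None:
        rng = _substreams(config.seed)["drift"]
    if ancestral is None:
        ancestral = simulate_ancestral_frequencies(config, rng)
    freqs = np.empty((config.n_snps, config.n_demes))
    freqs[:, 0] = ancestral
    for u, v, f_edge in _spanning_tree(config.n_demes, config.deme_graph):
        freqs[:, v] = _balding_nichols(rng, freqs[:, u], 2.0 * f_edge)
    return freqs, ancestral


def expected_pairwise_fst(config: SimConfig) -> np.ndarray:
    """Model-expected pairwise Hudson FST from the spanning-tree drift path.

    Within-deme heterozygosity decays by ``(1 - 2F)`` per traversal edge;
    FST(u, v) = 1 - mean residual heterozygosity relative to the MRCA.
    """
    tree = _spanning_tree(config.n_demes, config.deme_graph)
    parent = {0: None}
    decay = {0: 1.0}   # prod(1 - 2F) along root -> node
    for u, v, f in tree:
        parent[v] = u
        decay[v] = decay[u] * (1.0 - 2.0 * f)

    def path_to_root(x):
        out = [x]
        while parent[x] is not None:
            x = parent[x]
            out.append(x)
        return out

    d = config.n_demes
    fst = np.zeros((d, d))
    for i in range(d):
        pi = path_to_root(i)
        for j in range(i + 1, d):
            pj = path_to_root(j)
            mrca = next(x for x in pi if x in set(pj))
            ri = decay[i] / decay[mrca]
            rj = decay[j] / decay[mrca]
            fst[i, j] = fst[j, i] = 1.0 - (ri + rj) / 2.0
    return fst


def marker_grid(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Regularly spaced marker positions per chromosome."""
    chroms, positions = [], []
    for name, length, n in config.chrom_layout:
        spacing = length / (n + 1)
        pos = np.round((np.arange(1, n + 1)) * spacing).astype(np.int64)
        pos = np.maximum.accumulate(np.maximum(pos, np.arange(1, n + 1)))
        chroms += [name] * n
        positions.append(pos)
    return np.array(chroms, dtype=object), np.concatenate(positions)


def _span_markers(chroms, positions, chrom, start, end) -> np.ndarray:
    return np.where((chroms == chrom) & (positions >= start)
                    & (positions <= end))[0]


def simulate_inversion(config: SimConfig, deme_freqs: np.ndarray,
                       chroms: np.ndarray, positions: np.ndarray,
                       deme_of_ind: np.ndarray,
                       rng: np.random.Generator,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two non-recombining haplogroups A/B inside the inversion span.

    Returns ``(hap_freqs (S_span, 2), karyotypes (N,), span_idx, divergent_idx)``.
    Divergent sites (a regular stride covering ``divergent_fraction`` of the
    span) get ``|p_A - p_B| = delta``; other in-span sites share the carrying
    deme's frequency in both arrangements.  Karyotypes are Hardy-Weinberg
    draws at each deme's inversion-allele frequency.
    """
    spec = config.inversion
    if spec is None:
        raise ValueError("no inversion configured")
    if not (0.0 < spec.divergent_fraction <= 1.0):
        raise ValueError("divergent_fraction must be in (0, 1]")
    span = _span_markers(chroms, positions, spec.chrom, spec.start, spec.end)
    if span.size == 0:
        raise ValueError("inversion span contains no markers")
    stride = max(1, int(round(1.0 / spec.divergent_fraction)))
    divergent = span[::stride]
    half = spec.delta / 2.0
    if half > 0.5:
        raise ValueError("delta > 1 would push a frequency outside [0, 1]")
    # midpoints drawn so p_A = mid - delta/2 and p_B = mid + delta/2 stay legal
    lo, hi = half + 0.01, 1.0 - half - 0.01
    if spec.delta >= 0.98:
        lo, hi = 0.5, 0.5
    mid = rng.uniform(lo, hi, size=divergent.size)
    hap_freqs = np.zeros((span.size, 2))
    # default: both arrangements carry the (deme-averaged) ancestral column;
    # per-deme frequencies are substituted at genotype-draw time for
    # non-divergent sites, so store a NaN sentinel there.
    hap_freqs[:] = np.nan
    div_local = np.searchsorted(span, divergent)
    hap_freqs[div_local, 0] = np.clip(mid - half, 0.0, 1.0)
    hap_freqs[div_local, 1] = np.clip(mid + half, 0.0, 1.0)
    inv_freq = np.asarray(spec.deme_freqs, dtype=float)
    if inv_freq.size != config.n_demes:
        raise ValueError("inversion deme_freqs length != n_demes")
    karyo = rng.binomial(2, inv_freq[deme_of_ind])
    return hap_freqs, karyo, span, divergent


def simulate_genotypes(config: SimConfig, deme_freqs: np.ndarray,
                       chroms: np.ndarray, positions: np.ndarray,
                       rng: np.random.Generator,
                       inv_rng: np.random.Generator | None = None,
                       ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draw true genotypes for all individuals; returns (G (S,N), deme_of_ind, extras)."""
    n_demes, n_per = config.n_demes, config.n_per_deme
    if config.individual_q is not None:
        q = np.asarray(config.individual_q, dtype=float)
        n_ind = q.shape[0]
        deme_of_ind = np.argmax(q, axis=1)
        p_ind = deme_freqs @ q.T                      # (S, N)
    else:
        n_ind = n_demes * n_per
        deme_of_ind = np.repeat(np.arange(n_demes), n_per)
        p_ind = deme_freqs[:, deme_of_ind]
    freqs_eff = deme_freqs.copy()
    extras: dict = {}

    if config.outlier_region is not None:
        spec = config.outlier_region
        span = _span_markers(chroms, positions, spec.chrom, spec.start, spec.end)
        shifts = np.asarray(spec.deme_shifts, dtype=float)
        freqs_eff[np.ix_(span, np.arange(n_demes))] = np.clip(
            freqs_eff[span] + shifts[None, :], 0.01, 0.99)
        p_ind = (freqs_eff @ config.individual_q.T
                 if config.individual_q is not None
                 else freqs_eff[:, deme_of_ind])
        extras["outlier_span"] = (spec.chrom, spec.start, spec.end)
        extras["outlier_markers"] = span

    genotypes = rng.binomial(2, p_ind).astype(np.int8)

    if config.inversion is not None:
        if inv_rng is None:
            inv_rng = rng
        hap_freqs, karyo, span, divergent = simulate_inversion(
            config, freqs_eff, chroms, positions, deme_of_ind, inv_rng)
        # zero recombination: each individual carries karyo[i] copies of B
        n_b = karyo[None, :]                      # haplogroup-B copies
        s_local = span.size
        pa = hap_freqs[:, 0][:, None]
        pb = hap_freqs[:, 1][:, None]
        deme_p = freqs_eff[span][:, deme_of_ind]  # non-divergent fallback
        pa = np.where(np.isnan(pa), deme_p, pa)
        pb = np.where(np.isnan(pb), deme_p, pb)
        g_a = inv_rng.binomial((2 - n_b).astype(np.int64),
                               np.broadcast_to(pa, (s_local, n_ind)))
        g_b = inv_rng.binomial(np.broadcast_to(n_b, (s_local, n_ind)).astype(np.int64),
                               np.broadcast_to(pb, (s_local, n_ind)))
        genotypes[span] = (g_a + g_b).astype(np.int8)
        extras["inversion_span"] = (config.inversion.chrom,
                                    config.inversion.start, config.inversion.end)
        extras["karyotypes"] = karyo
        extras["inversion_markers"] = span
        extras["divergent_markers"] = divergent
    return genotypes, deme_of_ind, extras


def simulate_reads_to_gl(genotypes: np.ndarray, mean_depth: float,
                         error_rate: float,
                         rng: np.random.Generator | int,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depths, binomial read counts, and normalised GL triplets.

    Depth-0 entries get the flat triplet (1/3, 1/3, 1/3) marking missingness.
    Returns ``(likelihoods (S, N, 3), depths (S, N))``.
    """
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    g = np.asarray(genotypes)
    depths = rng.poisson(mean_depth, size=g.shape)
    # P(alt read | genotype g) = g/2 (1-e) + (1 - g/2) e
    p_alt = (g / 2.0) * (1 - error_rate) + (1 - g / 2.0) * error_rate
    alt = rng.binomial(depths, p_alt)
    ref = depths - alt
    gl = np.empty(g.shape + (3,))
    for gg in range(3):
        q = (gg / 2.0) * (1 - error_rate) + (1 - gg / 2.0) * error_rate
        if q == 0.0:
            loglik = np.where(alt > 0, -np.inf, 0.0)
        elif q == 1.0:
            loglik = np.where(ref > 0, -np.inf, 0.0)
        else:
            loglik = alt * np.log(q) + ref * np.log1p(-q)
        gl[..., gg] = loglik
    m = gl.max(axis=-1, keepdims=True)
    gl = np.exp(gl - m)
    gl /= gl.sum(axis=-1, keepdims=True)
    gl[depths == 0] = 1.0 / 3.0
    return gl, depths


def simulate_dataset(config: SimConfig) -> SimResult:
    """End-to-end generation: frequencies -> genotypes -> reads -> GL dataset."""
    config.validate()
    rngs = _substreams(config.seed)
    chroms, positions = marker_grid(config)
    deme_freqs, ancestral = simulate_deme_frequencies(config, rngs["drift"])
    genotypes, deme_of_ind, extras = simulate_genotypes(
        config, deme_freqs, chroms, positions, rngs["genotypes"],
        inv_rng=rngs["inversion"])
    gl, depths = simulate_reads_to_gl(genotypes, config.mean_depth,
                                      config.error_rate, rngs["reads"])
    n_ind = genotypes.shape[1]
    letters = np.array(list("ACGT"), dtype=object)
    maj = letters[rngs["alleles"].integers(0, 4, size=len(chroms))]
    mino = letters[(rngs["alleles"].integers(1, 4, size=len(chroms))
                    + np.searchsorted(letters, maj)) % 4]
    ids = [f"ind{deme_of_ind[i]}_{i:03d}" for i in range(n_ind)]
    dataset = GLDataset(chroms, positions, maj, mino, gl, ids)

    coords = config.deme_coords
    rows = []
    for i in range(n_ind):
        d = int(deme_of_ind[i])
        rc = coords[d] if coords is not None else (0, d)
        rows.append({"id": ids[i], "site": f"deme{d}",
                     "lat": float(rc[0]), "lon": float(rc[1]),
                     "row": int(rc[0]), "col": int(rc[1])})
    samples = SampleTable(pd.DataFrame(rows))

    truth = TruthLedger(
        deme_freqs=deme_freqs,
        expected_fst=expected_pairwise_fst(config),
        genotypes=genotypes,
        deme_of_individual=deme_of_ind,
        inversion_span=extras.get("inversion_span"),
        karyotypes=extras.get("karyotypes"),
        inversion_divergent_sites=extras.get("divergent_markers"),
        outlier_span=extras.get("outlier_span"),
        ancestral_freqs=ancestral,
    )
    return SimResult(dataset, depths, samples, truth, config)


def gl_from_genotypes(genotypes, chroms=None, positions=None,
                      spacing: int = 1000, chrom: str = "chr1") -> GLDataset:
    """GLDataset with (near-)certain likelihoods encoding hard genotypes.

    Missing entries are encoded as -1 and become flat triplets.  Useful for
    oracle tests and fixtures where genotypes should be treated as known.
    """
    g = np.asarray(genotypes)
    m, n = g.shape
    gl = np.full((m, n, 3), 1e-12)
    for gg in range(3):
        gl[..., gg][g == gg] = 1.0
    gl[g < 0] = 1.0 / 3.0
    if positions is None:
        positions = (np.arange(m) + 1) * spacing
    if chroms is None:
        chroms = np.array([chrom] * m, dtype=object)
    return GLDataset(np.asarray(chroms, dtype=object), np.asarray(positions),
                     np.array(["A"] * m, dtype=object),
                     np.array(["C"] * m, dtype=object), gl,
                     [f"ind{i}" for i in range(n)])


def corridor_raster(n_cells: int, cellsize_km: float = 10.0,
                    width: int = 3) -> RasterMap:
    """A straight all-water corridor bordered by land, for IBD fixtures."""
    grid = np.ones((width + 2, n_cells + 2), dtype=int)
    grid[1:width + 1, 1:n_cells + 1] = 0
    return RasterMap(grid, 0.0, 0.0, cellsize_km)


def write_truth_ledger(truth: TruthLedger, path) -> None:
    """Plain key-value text dump of the scalar/summary truth fields."""
    with open(path, "w") as fh:
        def kv(key, val):
            fh.write(f"{key}\t{val}\n")
        kv("n_snps", truth.genotypes.shape[0])
        kv("n_individuals", truth.genotypes.shape[1])
        kv("n_demes", truth.deme_freqs.shape[1])
        kv("deme_of_individual", ",".join(map(str, truth.deme_of_individual)))
        for i in range(truth.expected_fst.shape[0]):
            for j in range(i + 1, truth.expected_fst.shape[1]):
                kv(f"expected_fst_{i}_{j}", f"{truth.expected_fst[i, j]:.6f}")
        if truth.inversion_span is not None:
            kv("inversion_span", "{}:{}-{}".format(*truth.inversion_span))
            kv("karyotypes", ",".join(map(str, truth.karyotypes)))
        if truth.outlier_span is not None:
            kv("outlier_span", "{}:{}-{}".format(*truth.outlier_span))
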