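"""Differentiation statistics and isolation-by-distance testing.

Hudson's FST is computed as a ratio of averages from per-site components
(Bhatia-style sample-size corrections), with per-group allele frequencies
estimated by EM from the genotype likelihoods with a globally fixed allele
polarity.  Geographic separation uses least-cost in-water distances on a
land/water raster (infinite resistance to land, unit resistance to water),
and the association is tested with a one-tailed Mantel permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .gl_io import GLDataset, RasterMap
from .structure import estimate_maf_em, posterior_dosages


@dataclass
class PopFreqs:
    """Per-population per-site frequency of the globally polarised minor allele.

    When built with ``split_half=True`` the two independent half-sample
    estimates (``freqs_a``, ``freqs_b``) are carried alongside the pooled
    estimate, enabling noise-free differentiation numerators by
    cross-multiplication.
    """

    groups: list[str]
    freqs: np.ndarray      # (G, M)
    n_chrom: np.ndarray    # (G, M) haploid sample sizes (2 x covered diploids)
    freqs_a: np.ndarray | None = None  # (G, M) first-half estimates
    freqs_b: np.ndarray | None = None  # (G, M) second-half estimates


def pop_allele_freqs(dataset: GLDataset, labels,
                     split_half: bool = True) -> PopFreqs:
    """EM allele frequencies per group, counting the dataset's minor allele.

    Polarity is fixed by the dataset's major/minor columns, shared across
    groups, so frequencies are comparable without re-folding.  With
    ``split_half`` (default) each group is also split deterministically into
    two halves (alternating individuals) whose independent EM estimates
    allow Hudson's numerator to be formed without an explicit sampling
    variance correction — the correction that hard-genotype formulas apply
    through p(1-p)/(n-1) cannot account for read-level noise at shallow
    coverage, whereas the cross-product of independent halves is unbiased
    for (p1 - p2)^2 by construction.
    """
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    covered = ~dataset.missing_mask()
    freqs = np.empty((len(groups), dataset.n_markers))
    n_chrom = np.empty_like(freqs)
    fa = np.full_like(freqs, np.nan) if split_half else None
    fb = np.full_like(freqs, np.nan) if split_half else None
    for g, name in enumerate(groups):
        idx = np.where(labels == name)[0]
        sub = dataset.subset_individuals(idx)
        f, flagged = estimate_maf_em(sub)
        f[flagged] = np.nan
        freqs[g] = f
        n_chrom[g] = 2 * covered[:, idx].sum(axis=1)
        if split_half:
            for arr, half in ((fa, idx[0::2]), (fb, idx[1::2])):
                if half.size == 0:
                    continue
                fh, flg = estimate_maf_em(dataset.subset_individuals(half))
                fh[flg] = np.nan
                arr[g] = fh
    return PopFreqs(groups=[str(g) for g in groups], freqs=freqs,
                    n_chrom=n_chrom, freqs_a=fa, freqs_b=fb)


def hudson_fst(pf: PopFreqs, g1, g2) -> tuple[pd.DataFrame, float]:
    """Hudson FST between two groups as a ratio of per-site component sums.

    With split-half frequencies (the default from :func:`pop_allele_freqs`)
    the per-site components are cross-products of the independent halves,

        N = (p1A - p2A)(p1B - p2B),
        D = [p1A(1-p2B) + p2A(1-p1B) + p1B(1-p2A) + p2B(1-p1A)] / 2,

    both unbiased for the population quantities (p1-p2)^2 and
    p1(1-p2)+p2(1-p1) regardless of genotype-likelihood noise.  Without
    halves the hard-genotype form N = (p1-p2)^2 - p1(1-p1)/(n1-1)
    - p2(1-p2)/(n2-1) is used.  Genome-wide FST = sum(N)/sum(D); sites with
    a haploid sample size below 2 in either group are skipped.
    """
    i1, i2 = pf.groups.index(str(g1)), pf.groups.index(str(g2))
    p1, p2 = pf.freqs[i1], pf.freqs[i2]
    n1, n2 = pf.n_chrom[i1], pf.n_chrom[i2]
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    if pf.freqs_a is not None and pf.freqs_b is not None:
        p1a, p1b = pf.freqs_a[i1], pf.freqs_b[i1]
        p2a, p2b = pf.freqs_a[i2], pf.freqs_b[i2]
        ok &= (np.isfinite(p1a) & np.isfinite(p1b)
               & np.isfinite(p2a) & np.isfinite(p2b))
        sel = ok
        num = (p1a[sel] - p2a[sel]) * (p1b[sel] - p2b[sel])
        den = 0.5 * (p1a[sel] * (1 - p2b[sel]) + p2a[sel] * (1 - p1b[sel])
                     + p1b[sel] * (1 - p2a[sel]) + p2b[sel] * (1 - p1a[sel]))
    else:
        sel = ok
        p1s, p2s, n1s, n2s = p1[sel], p2[sel], n1[sel], n2[sel]
        num = ((p1s - p2s) ** 2 - p1s * (1 - p1s) / (n1s - 1)
               - p2s * (1 - p2s) / (n2s - 1))
        den = p1s * (1 - p2s) + p2s * (1 - p1s)
    per_site = pd.DataFrame({"site": np.where(sel)[0], "num": num, "den": den})
    fst = float(num.sum() / den.sum())
    return per_site, fst


def afd(pf: PopFreqs, g1, g2) -> float:
    """Allele frequency difference: mean |p1 - p2| over shared sites."""
    i1, i2 = pf.groups.index(str(g1)), pf.groups.index(str(g2))
    p1, p2 = pf.freqs[i1], pf.freqs[i2]
    ok = (pf.n_chrom[i1] >= 2) & (pf.n_chrom[i2] >= 2) \
        & np.isfinite(p1) & np.isfinite(p2)
    if not ok.any():
        raise ValueError("no shared sites between groups")
    return float(np.abs(p1[ok] - p2[ok]).mean())


def linearize_fst(f: float) -> float:
    """Rousset's linearisation f / (1 - f); requires f < 1."""
    if f >= 1:
        raise ValueError("FST must be < 1 to linearise")
    return f / (1.0 - f)


def pairwise_matrices(pf: PopFreqs) -> dict[str, np.ndarray]:
    """Symmetric pairwise FST / linearised-FST / AFD matrices over groups."""
    g = len(pf.groups)
    fst = np.zeros((g, g))
    afd_m = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            _, f = hudson_fst(pf, pf.groups[i], pf.groups[j])
            fst[i, j] = fst[j, i] = f
            afd_m[i, j] = afd_m[j, i] = afd(pf, pf.groups[i], pf.groups[j])
    lin = fst / (1.0 - fst)
    np.fill_diagonal(lin, 0.0)
    return {"fst": fst, "linearized_fst": lin, "afd": afd_m}


def least_cost_distance(raster: RasterMap, coords) -> np.ndarray:
    """In-water least-cost km between sample coordinates on a land/water grid.

    Movement is 8-neighbour between water cells; a step costs the cell size
    (x sqrt(2) diagonally).  Land is impassable.  Samples are snapped to the
    nearest water cell; disconnected basins give infinite distance.
    """
    rows, cols = raster.shape
    coords = [(int(r), int(c)) for r, c in coords]
    for r, c in coords:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"coordinate ({r},{c}) outside the {rows}x{cols} grid")
    water = np.argwhere(raster.grid == 0)
    cell_id = -np.ones((rows, cols), dtype=int)
    for k, (r, c) in enumerate(water):
        cell_id[r, c] = k
    src_i, dst_i, w = [], [], []
    moves = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for r, c in water:
        for dr, dc in moves:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and cell_id[rr, cc] >= 0:
                src_i.append(cell_id[r, c])
                dst_i.append(cell_id[rr, cc])
                w.append(raster.cellsize_km * (np.sqrt(2) if dr and dc else 1.0))
    graph = coo_matrix((w, (src_i, dst_i)), shape=(len(water), len(water)))

    def snap(r, c):
        if cell_id[r, c] >= 0:
            return cell_id[r, c]
        d2 = ((water[:, 0] - r) ** 2 + (water[:, 1] - c) ** 2)
        return int(np.argmin(d2))

    nodes = [snap(r, c) for r, c in coords]
    dist_all = _dijkstra(graph.tocsr(), directed=False, indices=sorted(set(nodes)))
    row_of = {n: i for i, n in enumerate(sorted(set(nodes)))}
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = dist_all[row_of[nodes[i]], nodes[j]]
    return out


def mantel(a: np.ndarray, b: np.ndarray, permutations: int = 9999,
           seed: int = 0) -> tuple[float, float]:
    """One-tailed (greater) Mantel test with simultaneous row/col permutation.

    r is the Pearson correlation over lower-triangle entries;
    p = (count of permuted r >= observed + 1) / (permutations + 1).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    n = a.shape[0]
    tril = np.tril_indices(n, k=-1)
    x = a[tril]
    r_obs = float(np.corrcoef(x, b[tril])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        if np.corrcoef(x, bp[tril])[0, 1] >= r_obs:
            count += 1
    return r_obs, (count + 1) / (permutations + 1)
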