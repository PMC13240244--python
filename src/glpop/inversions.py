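"""Characterisation of candidate regions as putative chromosomal inversions.

Given a candidate region (typically an MDS-outlier cluster), individuals are
karyotyped by k-means on their local PC1 score (middle cluster = AB, the
commoner extreme = AA); heterokaryotype excess heterozygosity is tested with
one-sided Wilcoxon rank-sum tests; the region's internal LD is compared with
1000 random same-length windows by a Z-test; and boundaries are refined from
chromosome-wide top-5% LD link counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .gl_io import GLDataset
from .diversity import hard_calls
from .structure import estimate_maf_em, posterior_dosages


@dataclass
class KaryotypeCalls:
    labels: np.ndarray        # (N,) of "AA" | "AB" | "BB"
    pc1: np.ndarray           # (N,) scores used for clustering
    centers: dict[str, float]
    fallback_used: bool = False


def region_pc1(dataset: GLDataset, marker_idx: np.ndarray,
               f: np.ndarray | None = None,
               dosages: np.ndarray | None = None) -> np.ndarray:
    """PC1 of the standardized expected genotypes restricted to a region."""
    if f is None:
        f, _ = estimate_maf_em(dataset)
    if dosages is None:
        dosages = posterior_dosages(dataset, f)
    fc = np.clip(f[marker_idx], 1e-6, 1 - 1e-6)
    z = (dosages[marker_idx] - 2 * fc[:, None]) / np.sqrt(2 * fc * (1 - fc))[:, None]
    cov = z.T @ z / z.shape[0]
    vals, vecs = np.linalg.eigh(cov)
    u = vecs[:, np.argmax(vals)]
    return u * np.sqrt(vals.max())


def karyotype_kmeans(pc1: np.ndarray, k: int = 3, restarts: int = 50,
                     seed: int = 0, max_fallback_k: int = 6) -> KaryotypeCalls:
    """Assign AA/AB/BB karyotypes by 1-D k-means on PC1 scores.

    If the k=3 solution has a cluster with fewer than 2 members or a
    silhouette below 0.3, re-cluster with k=4..``max_fallback_k`` and merge
    the cluster centers back into 3 groups by 1-D 3-means.
    """
    pc1 = np.asarray(pc1, dtype=float)
    if pc1.size < 6:
        raise ValueError("karyotyping needs at least 6 individuals")
    x = pc1.reshape(-1, 1)

    def fit(kk, seed_off=0):
        km = KMeans(n_clusters=kk, n_init=restarts,
                    random_state=seed + seed_off).fit(x)
        return km.labels_, km.cluster_centers_.ravel()

    labels3, centers3 = fit(3)
    sizes = np.bincount(labels3, minlength=3)
    sil = silhouette_score(x, labels3) if len(set(labels3)) > 1 else -1.0
    fallback = bool(sizes.min() < 2 or sil < 0.3)
    if fallback:
        best = None
        for kk in range(4, max_fallback_k + 1):
            if kk >= pc1.size:
                break
            lab_k, cent_k = fit(kk, seed_off=kk)
            s = silhouette_score(x, lab_k) if len(set(lab_k)) > 1 else -1.0
            if best is None or s > best[0]:
                best = (s, lab_k, cent_k)
        _, lab_k, cent_k = best
        km3 = KMeans(n_clusters=3, n_init=restarts, random_state=seed).fit(
            cent_k.reshape(-1, 1))
        group_of_cluster = km3.labels_
        labels3 = group_of_cluster[lab_k]
        centers3 = np.array([pc1[labels3 == g].mean() for g in range(3)])

    order = np.argsort(centers3)             # left, middle, right on PC1
    name_of = {}
    name_of[order[1]] = "AB"
    left, right = order[0], order[2]
    n_left = (labels3 == left).sum()
    n_right = (labels3 == right).sum()
    if n_left >= n_right:
        name_of[left], name_of[right] = "AA", "BB"
    else:
        name_of[left], name_of[right] = "BB", "AA"
    named = np.array([name_of[l] for l in labels3], dtype=object)
    centers = {name_of[c]: float(centers3[c]) for c in range(3)}
    return KaryotypeCalls(labels=named, pc1=pc1, centers=centers,
                          fallback_used=fallback)


def region_het_test(dataset: GLDataset, marker_idx: np.ndarray,
                    calls: KaryotypeCalls, f: np.ndarray | None = None,
                    ) -> dict:
    """Per-karyotype heterozygosity over region SNPs + one-sided Wilcoxon tests.

    Tests AB > AA and AB > BB on per-individual heterozygote fractions.  The
    fraction is the mean posterior heterozygote probability over covered
    region sites: hard calls at shallow depth are prior-dominated where the
    site frequency sits near 0.5, which can invert the karyotype-group
    ordering, while the posterior preserves it.
    """
    from .structure import estimate_maf_em as _em, hwe_prior as _prior
    if f is None:
        f, _ = _em(dataset)
    post = dataset.likelihoods[marker_idx] * _prior(f[marker_idx])[:, None, :]
    post = post / post.sum(axis=2, keepdims=True)
    covered = ~dataset.missing_mask()[marker_idx]
    het = np.full(dataset.n_individuals, np.nan)
    for i in range(dataset.n_individuals):
        cov = covered[:, i]
        if cov.sum():
            het[i] = float(post[cov, i, 1].mean())
    out = {"het_fraction": het, "medians": {}, "p_ab_gt_aa": np.nan,
           "p_ab_gt_bb": np.nan, "skipped": []}
    groups = {lab: het[(calls.labels == lab) & np.isfinite(het)]
              for lab in ("AA", "AB", "BB")}
    for lab, v in groups.items():
        out["medians"][lab] = float(np.median(v)) if v.size else np.nan
    for other, key in (("AA", "p_ab_gt_aa"), ("BB", "p_ab_gt_bb")):
        if groups["AB"].size == 0 or groups[other].size == 0:
            out["skipped"].append(other)
            continue
        res = stats.mannwhitneyu(groups["AB"], groups[other],
                                 alternative="greater")
        out[key] = float(res.pvalue)
    return out


def _standardized_dosages(dataset: GLDataset, f: np.ndarray,
                          dosages: np.ndarray) -> np.ndarray:
    """Column-standardised (per-site) dosage matrix for fast r^2 products."""
    z = dosages - dosages.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf          # monomorphic dosage -> r = 0
    return z / sd


def _mean_r2_pairs(z: np.ndarray, idx: np.ndarray, rng: np.random.Generator,
                   max_pairs: int) -> float:
    """Mean r^2 over (subsampled) site pairs of ``idx``, from standardized rows."""
    m = idx.size
    n_pairs = m * (m - 1) // 2
    if n_pairs == 0:
        return np.nan
    if n_pairs <= max_pairs:
        ii, jj = np.triu_indices(m, k=1)
    else:
        ii = rng.integers(0, m, size=max_pairs)
        jj = rng.integers(0, m - 1, size=max_pairs)
        jj = np.where(jj >= ii, jj + 1, jj)
    n = z.shape[1]
    r = (z[idx[ii]] * z[idx[jj]]).sum(axis=1) / n
    return float(np.mean(r ** 2))


def ld_block_test(dataset: GLDataset, chrom: str, start: int, end: int,
                  n_random: int = 1000, seed: int = 0,
                  max_pairs: int = 100_000, null_max_pairs: int = 2000,
                  f: np.ndarray | None = None,
                  dosages: np.ndarray | None = None) -> dict:
    """Z-test of the region's mean pairwise r^2 against random same-length windows.

    The null draws ``n_random`` uniform-start windows of the same bp length
    on the same chromosome, excluding windows that overlap the candidate
    region.  p is the upper-tail normal probability of the observed mean.
    """
    if f is None:
        f, _ = estimate_maf_em(dataset)
    if dosages is None:
        dosages = posterior_dosages(dataset, f)
    rng = np.random.default_rng(seed)
    z = _standardized_dosages(dataset, f, dosages)
    on_chrom = dataset.chroms == chrom
    pos = dataset.positions
    region_idx = np.where(on_chrom & (pos >= start) & (pos <= end))[0]
    mean_in = _mean_r2_pairs(z, region_idx, rng, max_pairs)
    length = end - start
    chrom_pos = pos[on_chrom]
    chrom_idx = np.where(on_chrom)[0]
    chrom_span = (int(chrom_pos.min()), int(chrom_pos.max()))
    if chrom_span[1] - chrom_span[0] < 2 * length:
        import warnings
        warnings.warn("chromosome shorter than twice the region; "
                      "null windows will be scarce")
    null_means = []
    attempts = 0
    while len(null_means) < n_random and attempts < 20 * n_random:
        attempts += 1
        s = int(rng.integers(chrom_span[0], max(chrom_span[1] - length, chrom_span[0]) + 1))
        e = s + length
        if s <= end and start <= e:      # overlaps the candidate region
            continue
        sel = chrom_idx[(chrom_pos >= s) & (chrom_pos <= e)]
        if sel.size < 2:
            continue
        null_means.append(_mean_r2_pairs(z, sel, rng, null_max_pairs))
    null_means = np.asarray(null_means)
    mu, sd = float(null_means.mean()), float(null_means.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null: all random-window r^2 identical")
    z_stat = (mean_in - mu) / sd
    return {"mean_r2_in": mean_in, "null_mean": mu, "null_sd": sd,
            "z": float(z_stat), "p": float(stats.norm.sf(z_stat)),
            "n_null": int(null_means.size)}


def refine_boundaries(dataset: GLDataset, chrom: str, start: int, end: int,
                      pad_frac: float = 0.25, top_q: float = 0.95,
                      max_dist: int = 200_000, f: np.ndarray | None = None,
                      dosages: np.ndarray | None = None) -> dict:
    """LD-based boundary refinement of a candidate inversion span.

    The chromosome-wide r^2 threshold is the ``top_q`` quantile over all
    same-chromosome pairs within ``max_dist``.  Within the padded region the
    start is the SNP tightly linked (r^2 >= threshold) to the most
    downstream SNPs of the padded window (ties -> smallest position) and the
    end the SNP linked to the most upstream ones (ties -> largest position).
    Link counts deliberately ignore ``max_dist`` (it applies to the
    threshold pair set only): capping them makes the count profile flat and
    noise-dominated inside any span longer than ``max_dist``, whereas
    whole-window counts decrease monotonically away from the true
    breakpoints.  Falls back to the original span (flagged) when the
    refinement degenerates.
    """
    if f is None:
        f, _ = estimate_maf_em(dataset)
    if dosages is None:
        dosages = posterior_dosages(dataset, f)
    z = _standardized_dosages(dataset, f, dosages)
    n = z.shape[1]
    pos = dataset.positions
    on_chrom = np.where(dataset.chroms == chrom)[0]
    cpos = pos[on_chrom]
    m = on_chrom.size

    # all same-chromosome pairs within max_dist, blocked by index offset
    r2_chunks = []
    offset = 1
    while True:
        valid = np.where(cpos[offset:] - cpos[:-offset] <= max_dist)[0]
        if valid.size == 0:
            break
        zi = z[on_chrom[valid]]
        zj = z[on_chrom[valid + offset]]
        r = (zi * zj).sum(axis=1) / n
        r2_chunks.append(r ** 2)
        offset += 1
        if offset >= m:
            break
    if not r2_chunks:
        return {"start": start, "end": end, "fallback": True,
                "threshold": np.nan}
    all_r2 = np.concatenate(r2_chunks)
    thr = float(np.quantile(all_r2, top_q))

    pad = int(round((end - start) * pad_frac))
    lo, hi = start - pad, end + pad
    cand = np.where((cpos >= lo) & (cpos <= hi))[0]
    if cand.size == 0:
        return {"start": start, "end": end, "fallback": True, "threshold": thr}

    zc = z[on_chrom[cand]]
    r_mat = (zc @ zc.T) / n
    high = r_mat ** 2 >= thr
    np.fill_diagonal(high, False)
    down_counts = np.triu(high, k=1).sum(axis=1)
    up_counts = np.tril(high, k=-1).sum(axis=1)

    if down_counts.max() == 0 or up_counts.max() == 0:
        return {"start": start, "end": end, "fallback": True, "threshold": thr}
    s_idx = cand[np.argmax(down_counts)]                 # ties -> smallest pos
    e_candidates = np.where(up_counts == up_counts.max())[0]
    e_idx = cand[e_candidates[-1]]                       # ties -> largest pos
    new_start, new_end = int(cpos[s_idx]), int(cpos[e_idx])
    if new_end <= new_start:
        return {"start": start, "end": end, "fallback": True, "threshold": thr}
    return {"start": new_start, "end": new_end, "fallback": False,
            "threshold": thr}


def region_length_kbp(start: int, end: int) -> float:
    """Region length in kbp, (end - start)/1000, one decimal."""
    if end <= start:
        raise ValueError("end must be > start")
    return round((end - start) / 1000.0, 1)


def karyotype_frequencies(calls: KaryotypeCalls, site_labels) -> pd.DataFrame:
    """Per-sampling-site karyotype fractions and inversion-allele frequency."""
    site_labels = np.asarray(site_labels)
    rows = []
    for site in pd.unique(site_labels):
        sel = site_labels == site
        n = int(sel.sum())
        if n == 0:
            continue
        counts = {lab: int((calls.labels[sel] == lab).sum())
                  for lab in ("AA", "AB", "BB")}
        freq_b = (counts["AB"] + 2 * counts["BB"]) / (2 * n)
        rows.append({"site": site, "n": n,
                     "f_AA": counts["AA"] / n, "f_AB": counts["AB"] / n,
                     "f_BB": counts["BB"] / n, "allele_freq": freq_b})
    return pd.DataFrame(rows)
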