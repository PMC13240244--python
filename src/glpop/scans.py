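"""Candidate-region calling and the local-PCA / MDS structural-variant scan.

Selection-scan outliers are aggregated in non-overlapping 1000-SNP windows;
windows with >= 10 outliers separated by fewer than 10 windows merge into
candidate regions.  The structural scan computes a PCA in each 100-SNP
window, summarises it by the unit-Frobenius rank-4 covariance approximation,
embeds pairwise window distances on 5 classical-MDS axes, and calls clusters
of >= 10 windows lying more than 3 SD from the mean on any axis (merging
flagged windows within 20 window indices).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .gl_io import GLDataset, RegionSet
from .structure import PCAModel, SelectionScan, estimate_maf_em, posterior_dosages


def make_snp_windows(chroms: np.ndarray, positions: np.ndarray,
                     size: int) -> pd.DataFrame:
    """Non-overlapping fixed-SNP-count windows per chromosome.

    Trailing partial windows are dropped; a chromosome with fewer than
    ``size`` SNPs contributes no windows (with a warning).
    """
    rows = []
    widx = 0
    for chrom in pd.unique(np.asarray(chroms)):
        idx = np.where(chroms == chrom)[0]
        n_win = len(idx) // size
        if n_win == 0:
            warnings.warn(f"chromosome {chrom} has {len(idx)} < {size} SNPs; "
                          "no windows")
            continue
        for w in range(n_win):
            members = idx[w * size:(w + 1) * size]
            rows.append({"chrom": chrom, "window": widx,
                         "first": int(members[0]), "last": int(members[-1]),
                         "start_bp": int(positions[members[0]]),
                         "end_bp": int(positions[members[-1]])})
            widx += 1
    return pd.DataFrame(rows, columns=["chrom", "window", "first", "last",
                                       "start_bp", "end_bp"])


def merge_flagged_windows(flagged_idx: np.ndarray, max_sep: int) -> list[list[int]]:
    """Group flagged window indices into clusters: merge when the index gap
    between consecutive flagged windows is <= ``max_sep``."""
    clusters: list[list[int]] = []
    for w in sorted(int(v) for v in flagged_idx):
        if clusters and w - clusters[-1][-1] <= max_sep:
            clusters[-1].append(w)
        else:
            clusters.append([w])
    return clusters


def _regions_from_clusters(clusters, windows: pd.DataFrame, provenance: str,
                           min_members: int = 1, scores=None):
    win = windows.set_index("window")
    rows, members_out = [], {}
    for ci, cluster in enumerate(clusters):
        if len(cluster) < min_members:
            continue
        chrom = win.loc[cluster[0], "chrom"]
        label = f"{provenance}_region{len(rows) + 1}"
        rows.append({"chrom": chrom,
                     "start": int(win.loc[cluster[0], "start_bp"]),
                     "end": int(win.loc[cluster[-1], "end_bp"]),
                     "label": label, "provenance": provenance,
                     "score": float(scores[ci]) if scores is not None else np.nan})
        members_out[label] = list(cluster)
    return rows, members_out


def call_outlier_regions(scan: SelectionScan, windows: pd.DataFrame,
                         min_outliers: int = 10, merge_gap: int = 10,
                         ) -> tuple[RegionSet, dict[str, list[int]]]:
    """Selection-scan candidate regions per axis.

    A window is flagged when it holds >= ``min_outliers`` SNPs with
    q < ``scan.q_cut`` on the axis; flagged windows on the same chromosome
    separated by fewer than ``merge_gap`` windows merge into one region.
    """
    rows, members = [], {}
    for a, axis in enumerate(scan.axes):
        out = scan.outliers[:, a]
        counts = {}
        for _, w in windows.iterrows():
            counts[int(w["window"])] = int(out[int(w["first"]):int(w["last"]) + 1].sum())
        flagged = [w for w, c in counts.items() if c >= min_outliers]
        for chrom in pd.unique(windows["chrom"]):
            chrom_wins = set(windows.loc[windows["chrom"] == chrom, "window"])
            fl = np.array([w for w in flagged if w in chrom_wins], dtype=int)
            # "separated by fewer than merge_gap windows": gap of merge_gap-1
            # intervening windows still merges, i.e. index difference <= merge_gap
            clusters = merge_flagged_windows(fl, merge_gap)
            scores = [sum(counts[w] for w in cl) for cl in clusters]
            prov = f"fastpca_axis{axis}"
            r, m = _regions_from_clusters(clusters, windows, prov, 1, scores)
            for rec in r:   # keep labels unique across axes/chromosomes
                rec["label"] = f"{rec['label']}_{chrom}_{len(rows)}"
            members.update({rec["label"]: m[lab] for rec, lab
                            in zip(r, list(m))})
            rows.extend(r)
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label",
                                                 "provenance", "score"])), members


def local_pca_windows(dataset: GLDataset, windows: pd.DataFrame, k: int = 4,
                      f: np.ndarray | None = None,
                      dosages: np.ndarray | None = None) -> np.ndarray:
    """Per-window rank-k local-PCA summaries.

    Each window's standardized expected-genotype matrix gives an individual
    covariance; the summary is its rank-k eigen approximation scaled to unit
    Frobenius norm.  Missing observations shrink to the site mean (dosage
    2f), i.e. zero after standardisation.  Returns (W, N, N).
    """
    if f is None:
        f, _ = estimate_maf_em(dataset)
    if dosages is None:
        dosages = posterior_dosages(dataset, f)
    fc = np.clip(f, 1e-6, 1 - 1e-6)
    x = (dosages - 2 * fc[:, None]) / np.sqrt(2 * fc * (1 - fc))[:, None]
    n = dataset.n_individuals
    out = np.empty((len(windows), n, n))
    for r, (_, w) in enumerate(windows.iterrows()):
        z = x[int(w["first"]):int(w["last"]) + 1]
        cov = z.T @ z / z.shape[0]
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][:k]
        approx = (vecs[:, order] * vals[order]) @ vecs[:, order].T
        norm = np.linalg.norm(approx)
        out[r] = approx / norm if norm > 0 else approx
    return out


def window_distances(summaries: np.ndarray) -> np.ndarray:
    """Pairwise Frobenius distances between window summaries."""
    flat = summaries.reshape(summaries.shape[0], -1)
    return squareform(pdist(flat))


def mds(distances: np.ndarray, axes: int = 5) -> np.ndarray:
    """Classical (Torgerson) scaling onto ``axes`` coordinates.

    Negative-eigenvalue axes are padded with zeros; each axis's sign is fixed
    by making its largest-|loading| coordinate positive.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:axes]
    coords = np.zeros((n, axes))
    for a, idx in enumerate(order):
        if vals[idx] > 1e-12:
            v = vecs[:, idx] * np.sqrt(vals[idx])
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, a] = v
    return coords


def mds_outlier_clusters(coords: np.ndarray, windows: pd.DataFrame,
                         sd_mult: float = 3.0, merge_gap: int = 20,
                         min_windows: int = 10,
                         ) -> tuple[RegionSet, dict[str, list[int]]]:
    """Clusters of MDS-outlier windows, per axis independently.

    A window is an outlier on an axis when its coordinate lies more than
    ``sd_mult`` SD from the axis mean (genome-wide).  Outliers on the same
    chromosome within ``merge_gap`` window indices merge; clusters with at
    least ``min_windows`` flagged members are kept.
    """
    rows, members = [], {}
    win_order = windows["window"].to_numpy()
    for a in range(coords.shape[1]):
        x = coords[:, a]
        mu, sd = x.mean(), x.std()
        if sd == 0:
            continue
        flagged_pos = np.where(np.abs(x - mu) > sd_mult * sd)[0]
        flagged = win_order[flagged_pos]
        for chrom in pd.unique(windows["chrom"]):
            chrom_wins = set(windows.loc[windows["chrom"] == chrom, "window"])
            fl = np.array([w for w in flagged if w in chrom_wins], dtype=int)
            clusters = [c for c in merge_flagged_windows(fl, merge_gap)
                        if len(c) >= min_windows]
            prov = f"mds_axis{a + 1}"
            r, m = _regions_from_clusters(clusters, windows, prov, min_windows,
                                          [len(c) for c in clusters])
            for rec, lab in zip(r, list(m)):
                new_lab = f"{rec['label']}_{chrom}_{len(rows)}"
                members[new_lab] = m[lab]
                rec["label"] = new_lab
                rows.append(rec)
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label",
                                                 "provenance", "score"])), members
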