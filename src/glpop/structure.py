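"""PCA and selection statistics from genotype likelihoods, plus LD tools.

The PCA follows the iterative individual-allele-frequency scheme used for
low-coverage data: posterior expected genotypes under a per-individual
Hardy-Weinberg prior, standardised by the site frequency, rank-K
reconstruction feeding back into the prior until the frequency surface
stabilises.  The selection statistic is the PCA-based genome-scan statistic
(squared SNP loading on an axis, scaled by the axis eigenvalue), which is
chi-square with 1 d.o.f. under genetic drift alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gl_io import GLDataset


def hwe_prior(f: np.ndarray) -> np.ndarray:
    """Genotype prior ((1-f)^2, 2f(1-f), f^2) stacked on the last axis."""
    f = np.asarray(f)[..., None]
    return np.concatenate([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=-1)


def estimate_maf_em(dataset: GLDataset, tol: float = 1e-6,
                    max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Per-site maximum-likelihood allele frequency under HWE, by EM.

    Returns ``(f, flagged)`` where ``flagged`` marks all-missing sites whose
    frequency is undefined (left at the initial value).
    """
    gl = dataset.likelihoods
    covered = ~dataset.missing_mask()
    n_cov = covered.sum(axis=1)
    f = np.full(dataset.n_markers, 0.25)
    g = np.arange(3)[None, None, :]
    active = np.where(n_cov > 0)[0]            # converged sites drop out
    for _ in range(max_iter):
        if active.size == 0:
            break
        fa = f[active]
        prior = hwe_prior(fa)[:, None, :]
        w = gl[active] * prior
        post = w / w.sum(axis=2, keepdims=True)
        e = (post * g).sum(axis=2)               # E[genotype | GL, f]
        f_new = np.clip((e * covered[active]).sum(axis=1) / (2 * n_cov[active]),
                        1e-8, 1 - 1e-8)
        delta = np.abs(f_new - fa)
        f[active] = f_new
        active = active[delta >= tol]
    return f, n_cov == 0


def posterior_dosages(dataset: GLDataset, f: np.ndarray | None = None,
                      pi: np.ndarray | None = None) -> np.ndarray:
    """Posterior-mean genotypes E[g | GL, HWE prior] (markers x individuals).

    The prior uses per-individual frequencies ``pi`` when given, else the
    per-site frequency ``f``.  A missing (flat) triplet yields the prior mean,
    i.e. the dosage shrinks fully to 2f.
    """
    if f is None and pi is None:
        f, _ = estimate_maf_em(dataset)
    prior = hwe_prior(pi) if pi is not None else hwe_prior(f)[:, None, :]
    w = dataset.likelihoods * prior
    post = w / w.sum(axis=2, keepdims=True)
    return (post * np.arange(3)[None, None, :]).sum(axis=2)


@dataclass
class PCAModel:
    f: np.ndarray                 # (M,) site frequencies
    pi: np.ndarray                # (M, N) individual allele frequencies
    cov: np.ndarray               # (N, N)
    eigenvalues: np.ndarray       # (N,) non-increasing
    eigenvectors: np.ndarray      # (N, N), columns
    k: int                        # rank used during fitting
    k_star: int                   # chosen axis count
    std_genotypes: np.ndarray = field(repr=False, default=None)  # (M, N)
    n_iter: int = 0

    def scores(self, n_axes: int | None = None) -> np.ndarray:
        n_axes = n_axes or self.k_star
        return self.eigenvectors[:, :n_axes] * np.sqrt(
            np.maximum(self.eigenvalues[:n_axes], 0.0))


def pcangsd_fit(dataset: GLDataset, k: int = 2, tol: float = 1e-5,
                max_iter: int = 100) -> PCAModel:
    """Iterative genotype-likelihood PCA (individual allele frequencies).

    Convergence is declared when the RMS change of the individual-frequency
    matrix drops below ``tol``.
    """
    n = dataset.n_individuals
    if k >= n:
        raise ValueError("k must be < number of individuals")
    gl = dataset.likelihoods
    m = dataset.n_markers
    f, _ = estimate_maf_em(dataset)
    f = np.clip(f, 1e-4, 1 - 1e-4)
    denom = np.sqrt(2 * f * (1 - f))[:, None]
    pi = np.tile(f[:, None], (1, n))
    g_idx = np.arange(3)[None, None, :]
    x = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        prior = hwe_prior(pi)
        w = gl * prior
        e = (w * g_idx).sum(axis=2) / w.sum(axis=2)
        x = (e - 2 * f[:, None]) / denom
        # economy SVD through the small Gram matrix
        gram = x.T @ x
        vals, vecs = np.linalg.eigh(gram)
        order = np.argsort(vals)[::-1][:k]
        v_k = vecs[:, order]
        recon = (x @ v_k) @ v_k.T
        pi_new = (recon * denom + 2 * f[:, None]) / 2.0
        pi_new = np.clip(pi_new, 1e-4, 1 - 1e-4)
        delta = np.sqrt(np.mean((pi_new - pi) ** 2))
        pi = pi_new
        if delta < tol:
            break
    cov = (x.T @ x) / m
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    eigenvalues, eigenvectors = vals[order], vecs[:, order]
    k_star = choose_axes(eigenvalues)
    return PCAModel(f=f, pi=pi, cov=cov, eigenvalues=eigenvalues,
                    eigenvectors=eigenvectors, k=k, k_star=k_star,
                    std_genotypes=x, n_iter=n_iter)


def choose_axes(eigenvalues: np.ndarray, override: int | None = None) -> int:
    """Elbow rule: K* maximises the second difference of the scree curve."""
    if override is not None:
        return int(override)
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        return 1
    second = lam[:-2] - 2 * lam[1:-1] + lam[2:]
    return int(np.argmax(second)) + 1


@dataclass
class SelectionScan:
    axes: list[int]               # 1-based axis numbers
    stats: np.ndarray             # (M, A)
    pvalues: np.ndarray           # (M, A)
    qvalues: np.ndarray           # (M, A)
    outliers: np.ndarray          # (M, A) bool, q < q_cut
    q_cut: float = 0.01


def fastpca_scan(model: PCAModel, axes: list[int] | None = None,
                 q_cut: float = 0.01) -> SelectionScan:
    """PCA-based selection scan: s_jk = (x_j . u_k)^2 / lambda_k ~ chi2(1)."""
    if axes is None:
        axes = list(range(1, model.k_star + 1))
    if max(axes) > model.k_star:
        raise ValueError(f"requested axis {max(axes)} > chosen K*={model.k_star}")
    x = model.std_genotypes
    stats_ = np.empty((x.shape[0], len(axes)))
    for a, axis in enumerate(axes):
        u = model.eigenvectors[:, axis - 1]
        lam = model.eigenvalues[axis - 1]
        proj = x @ u
        stats_[:, a] = proj ** 2 / lam if lam > 0 else 0.0
    p = stats.chi2.sf(stats_, df=1)
    # guard against underflow to exactly 0 for extreme statistics
    p = np.clip(p, 1e-300, 1.0)
    q = np.column_stack([qvalues(p[:, a]) for a in range(len(axes))])
    return SelectionScan(axes=list(axes), stats=stats_, pvalues=p, qvalues=q,
                         outliers=q < q_cut, q_cut=q_cut)


def qvalues(p: np.ndarray) -> np.ndarray:
    """Storey q-values with cubic-smoother pi0; falls back to pi0 = 1 (BH)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
    try:
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, lam[-1]))
    except np.linalg.LinAlgError:       # pragma: no cover - degenerate fit
        pi0 = 1.0
    if not (0.0 < pi0 <= 1.0):
        pi0 = 1.0
    order = np.argsort(p)
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def ld_r2(dataset: GLDataset, max_dist: int = 200_000,
          f: np.ndarray | None = None, min_shared: int = 10) -> pd.DataFrame:
    """Pairwise r^2 of posterior-mean dosages for same-chromosome pairs.

    Missing observations are excluded pairwise; pairs with fewer than
    ``min_shared`` jointly covered individuals, and pairs involving a
    monomorphic dosage vector, are skipped.
    """
    if f is None:
        f, _ = estimate_maf_em(dataset)
    dose = posterior_dosages(dataset, f)
    covered = ~dataset.missing_mask()
    rows = []
    chroms, pos = dataset.chroms, dataset.positions
    for c in pd.unique(chroms):
        idx = np.where(chroms == c)[0]
        for a in range(len(idx)):
            i = idx[a]
            for b in range(a + 1, len(idx)):
                j = idx[b]
                d = pos[j] - pos[i]
                if d > max_dist:
                    break
                shared = covered[i] & covered[j]
                if shared.sum() < min_shared:
                    warnings.warn(f"pair ({i},{j}) has <{min_shared} shared "
                                  "individuals; skipped")
                    continue
                xi, xj = dose[i, shared], dose[j, shared]
                if xi.std() == 0 or xj.std() == 0:
                    continue
                r = np.corrcoef(xi, xj)[0, 1]
                rows.append({"i": i, "j": j, "chrom": c, "pos_i": int(pos[i]),
                             "pos_j": int(pos[j]), "dist": int(d),
                             "r2": float(r * r)})
    return pd.DataFrame(rows, columns=["i", "j", "chrom", "pos_i", "pos_j",
                                       "dist", "r2"])


def ld_prune(dataset: GLDataset, r2_threshold: float = 0.075,
             max_dist: int = 200_000, f: np.ndarray | None = None,
             pairs: pd.DataFrame | None = None) -> np.ndarray:
    """Greedy LD pruning: drop the worst offender until no pair violates.

    The site participating in the most violating pairs is removed first; ties
    go to the lower-MAF site, then to the later position.  Returns the kept
    marker ordinals (sorted).
    """
    if f is None:
        f, _ = estimate_maf_em(dataset)
    maf = np.minimum(f, 1 - f)
    if pairs is None:
        pairs = ld_r2(dataset, max_dist=max_dist, f=f)
    bad = pairs[pairs["r2"] > r2_threshold]
    adj: dict[int, set[int]] = {}
    for i, j in zip(bad["i"], bad["j"]):
        adj.setdefault(int(i), set()).add(int(j))
        adj.setdefault(int(j), set()).add(int(i))
    removed: set[int] = set()
    while True:
        counts = {s: len(nb - removed) for s, nb in adj.items()
                  if s not in removed}
        counts = {s: c for s, c in counts.items() if c > 0}
        if not counts:
            break
        worst = sorted(counts,
                       key=lambda s: (-counts[s], maf[s], -int(dataset.positions[s])))[0]
        removed.add(worst)
    keep = np.setdiff1d(np.arange(dataset.n_markers), np.array(sorted(removed),
                                                               dtype=int))
    return keep
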