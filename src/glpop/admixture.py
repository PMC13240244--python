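"""Admixture-proportion estimation from genotype likelihoods (EM), plus the
cluster-count estimators and assignment rules applied downstream.

The model: individual i's allele frequency at site s is
h_is = sum_k q_ik f_ks; genotypes are Binomial(2, h) a priori and the data
enter through the genotype likelihoods.  Q and F are updated by EM
(expected minor/major allele counts attributed to clusters), giving a
monotone non-decreasing log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .gl_io import GLDataset
from .structure import estimate_maf_em


@dataclass
class AdmixtureFit:
    q: np.ndarray                  # (N, K) memberships, rows sum to 1
    f: np.ndarray                  # (M, K) cluster allele frequencies
    loglik: float
    loglik_path: list[float] = field(repr=False, default_factory=list)
    n_iter: int = 0
    k: int = 0
    seed: int = 0
    converged: bool = False


def admix_em(dataset: GLDataset, k: int, seed: int = 0, tol: float = 1e-5,
             maxiter: int = 2000) -> AdmixtureFit:
    """EM fit of admixture proportions Q and cluster frequencies F.

    Initialisation: F is the per-site MAF perturbed by seeded Uniform(+-0.05);
    Q rows are symmetric Dirichlet(1) draws.  Stops when the log-likelihood
    improves by less than ``tol``.
    """
    n = dataset.n_individuals
    if k < 1 or k > n:
        raise ValueError("K must be in [1, n individuals]")
    gl = dataset.likelihoods                       # (M, N, 3)
    m = dataset.n_markers
    rng = np.random.default_rng(seed)
    maf, _ = estimate_maf_em(dataset)
    f = np.clip(maf[:, None] + rng.uniform(-0.05, 0.05, size=(m, k)),
                1e-5, 1 - 1e-5)
    q = rng.dirichlet(np.ones(k), size=n)          # (N, K)
    if k == 1:
        q = np.ones((n, 1))
    path: list[float] = []
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        h = f @ q.T                                # (M, N)
        h = np.clip(h, 1e-9, 1 - 1e-9)
        prior = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h ** 2], axis=2)
        w = gl * prior
        lik = w.sum(axis=2)                        # (M, N)
        loglik = float(np.log(lik).sum())
        path.append(loglik)
        post = w / lik[..., None]
        a = post[..., 1] + 2 * post[..., 2]        # E[minor copies] (M, N)
        b = 2.0 - a
        # attribute expected allele copies to clusters
        af = a / h                                 # (M, N)
        bf = b / (1 - h)
        # a_isk = af_is * q_ik * f_sk ; b_isk = bf_is * q_ik * (1 - f_sk)
        num_f = (af @ q) * f                       # (M, K): sum_i a_isk
        den_f = num_f + (bf @ q) * (1 - f)
        f_new = np.clip(num_f / den_f, 1e-5, 1 - 1e-5)
        q_contrib = (af.T @ f) * q + (bf.T @ (1 - f)) * q   # (N, K)
        q_new = q_contrib / (2.0 * m)
        q_new = q_new / q_new.sum(axis=1, keepdims=True)
        f, q = f_new, (q if k == 1 else q_new)
        if len(path) > 1 and abs(path[-1] - path[-2]) < tol:
            converged = True
            break
    h = np.clip(f @ q.T, 1e-9, 1 - 1e-9)
    prior = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h ** 2], axis=2)
    final_ll = float(np.log((gl * prior).sum(axis=2)).sum())
    path.append(final_ll)
    return AdmixtureFit(q=q, f=f, loglik=final_ll, loglik_path=path,
                        n_iter=it, k=k, seed=seed, converged=converged)


def run_replicates(dataset: GLDataset, k_values, reps: int = 50,
                   seed: int = 0, tol: float = 1e-5, maxiter: int = 2000,
                   ) -> dict[int, list[AdmixtureFit]]:
    """Independent seeded fits per K; the best-likelihood fit leads each list."""
    rng = np.random.default_rng(seed)
    out: dict[int, list[AdmixtureFit]] = {}
    for k in k_values:
        seeds = rng.integers(0, 2 ** 31 - 1, size=reps)
        fits = [admix_em(dataset, k, seed=int(s), tol=tol, maxiter=maxiter)
                for s in seeds]
        fits.sort(key=lambda f: -f.loglik)
        out[k] = fits
    return out


def match_clusters(q_a: np.ndarray, q_b: np.ndarray) -> np.ndarray:
    """Column permutation of ``q_b`` best aligning it with ``q_a`` (Hungarian
    assignment on the column-correlation matrix)."""
    k = q_a.shape[1]
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            sa, sb = q_a[:, i].std(), q_b[:, j].std()
            corr[i, j] = (np.corrcoef(q_a[:, i], q_b[:, j])[0, 1]
                          if sa > 0 and sb > 0 else -np.abs(
                              q_a[:, i].mean() - q_b[:, j].mean()))
    _, cols = linear_sum_assignment(-corr)
    return cols


def puechmaille_k(fits: list[AdmixtureFit], site_labels,
                  thresholds=(0.5, 0.6, 0.7, 0.8)) -> pd.DataFrame:
    """Threshold-based cluster-count estimators (MedMedK/MedMeanK/MaxMedK/MaxMeanK).

    Per fit and sampling site, compute each cluster's mean and median
    membership; a cluster counts at a threshold when at least one site's
    mean (resp. median) membership reaches it.  Per-fit MeanK/MedK are then
    aggregated across replicate fits by median and maximum.
    """
    if site_labels is None:
        raise ValueError("site labels are required")
    site_labels = np.asarray(site_labels)
    sites = pd.unique(site_labels)
    rows = []
    for thr in thresholds:
        mean_ks, med_ks = [], []
        for fit in fits:
            site_mean = np.stack([fit.q[site_labels == s].mean(axis=0)
                                  for s in sites])          # (sites, K)
            site_med = np.stack([np.median(fit.q[site_labels == s], axis=0)
                                 for s in sites])
            mean_ks.append(int((site_mean.max(axis=0) >= thr).sum()))
            med_ks.append(int((site_med.max(axis=0) >= thr).sum()))
        rows.append({"threshold": thr,
                     "MedMedK": float(np.median(med_ks)),
                     "MedMeanK": float(np.median(mean_ks)),
                     "MaxMedK": int(np.max(med_ks)),
                     "MaxMeanK": int(np.max(mean_ks))})
    return pd.DataFrame(rows)


def reassign_f0_migrants(q: np.ndarray, site_labels, cutoff: float = 0.99,
                         ) -> tuple[np.ndarray, pd.DataFrame]:
    """Reassign putative first-generation migrants to their source cluster.

    Each site's dominant cluster is the one with the highest mean membership
    there.  An individual with membership strictly above ``cutoff`` to a
    cluster other than its site's dominant cluster is reassigned to that
    cluster.  Returns (per-individual cluster assignment, moves report).
    """
    site_labels = np.asarray(site_labels)
    sites = pd.unique(site_labels)
    dominant = {s: int(np.argmax(q[site_labels == s].mean(axis=0)))
                for s in sites}
    assign = np.array([dominant[s] for s in site_labels], dtype=int)
    moves = []
    for i in range(q.shape[0]):
        k_best = int(np.argmax(q[i]))
        if q[i, k_best] > cutoff and k_best != dominant[site_labels[i]]:
            moves.append({"individual": i, "site": site_labels[i],
                          "from_cluster": dominant[site_labels[i]],
                          "to_cluster": k_best, "q": float(q[i, k_best])})
            assign[i] = k_best
    return assign, pd.DataFrame(moves, columns=["individual", "site",
                                                "from_cluster", "to_cluster",
                                                "q"])


def flag_admixed(q: np.ndarray, cutoff: float = 0.8) -> np.ndarray:
    """Flag individuals whose maximum membership is below ``cutoff``."""
    return q.max(axis=1) < cutoff
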