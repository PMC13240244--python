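"""Site and sample quality-control filters with full bookkeeping.

Filter order follows the pipeline convention: site filters (MAF, coverage,
depth, paralog-like excess heterozygosity) first, then sample missingness,
then duplicate removal.  Each step returns a report so the counts at every
stage can be reconstructed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gl_io import GLDataset
from .structure import estimate_maf_em, hwe_prior, posterior_dosages


@dataclass
class SiteFilterConfig:
    min_maf: float = 0.05
    min_cover_frac: float = 0.75      # fraction of individuals covered >= 1x
    max_mean_depth: float = 10.0
    paralog_alpha: float = 0.001      # BH alpha for the excess-het filter


@dataclass
class SampleFilterConfig:
    missing_percentile: float = 95.0
    # threshold on standardised-dosage correlation; genotype-likelihood
    # shrinkage caps duplicate pairs near ~0.8 at 1.5x, while full sibs stay
    # below ~0.4, so 0.5 separates the two cleanly
    duplicate_r: float = 0.5


def filter_sites(dataset: GLDataset, depths: np.ndarray | None = None,
                 cfg: SiteFilterConfig | None = None,
                 f: np.ndarray | None = None,
                 ) -> tuple[GLDataset, pd.DataFrame]:
    """Apply MAF / coverage / mean-depth site filters; returns (kept, report)."""
    if dataset.n_markers == 0:
        raise ValueError("empty dataset")
    cfg = cfg or SiteFilterConfig()
    if f is None:
        f, _ = estimate_maf_em(dataset)
    maf = np.minimum(f, 1 - f)
    covered = ~dataset.missing_mask()
    cover_frac = covered.mean(axis=1)
    pass_maf = maf > cfg.min_maf
    pass_cover = cover_frac >= cfg.min_cover_frac
    if depths is not None:
        mean_depth = depths.mean(axis=1)
        pass_depth = mean_depth <= cfg.max_mean_depth
    else:
        warnings.warn("no depth sidecar provided; mean-depth filter skipped")
        mean_depth = np.full(dataset.n_markers, np.nan)
        pass_depth = np.ones(dataset.n_markers, dtype=bool)
    keep = pass_maf & pass_cover & pass_depth
    report = pd.DataFrame({
        "marker": dataset.marker_ids, "maf": maf, "cover_frac": cover_frac,
        "mean_depth": mean_depth, "pass_maf": pass_maf,
        "pass_cover": pass_cover, "pass_depth": pass_depth, "kept": keep})
    return dataset.subset_markers(np.where(keep)[0]), report


def sample_missingness(dataset: GLDataset) -> np.ndarray:
    """Per-sample fraction of sites with a flat (missing) likelihood triplet."""
    return dataset.missing_mask().mean(axis=0)


def filter_samples(dataset: GLDataset, cfg: SampleFilterConfig | None = None,
                   absolute_cutoff: float | None = None,
                   ) -> tuple[GLDataset, list[str], float]:
    """Remove samples whose missingness exceeds the cohort percentile cutoff.

    ``absolute_cutoff`` overrides the percentile with a fixed missing
    fraction (the cutoff actually applied is always returned, so percentile
    runs also report their absolute value).  Missingness is computed for all
    samples before any removal.
    """
    cfg = cfg or SampleFilterConfig()
    if dataset.n_individuals < 2:
        raise ValueError("cohort of size < 2: percentile undefined")
    miss = sample_missingness(dataset)
    cutoff = (absolute_cutoff if absolute_cutoff is not None
              else float(np.percentile(miss, cfg.missing_percentile)))
    removed = np.where(miss > cutoff)[0]
    removed_ids = [dataset.individuals[i] for i in removed]
    keep = np.setdiff1d(np.arange(dataset.n_individuals), removed)
    return dataset.subset_individuals(keep), removed_ids, cutoff


def detect_duplicates(dataset: GLDataset, threshold: float = 0.5,
                      f: np.ndarray | None = None, min_shared: int = 100,
                      ) -> tuple[list[tuple[str, str, float]], list[str]]:
    """Flag near-identical individuals by standardised-dosage correlation.

    Dosages are centred by the site mean 2f before correlating, so unrelated
    pairs sit near zero rather than at the baseline induced by shared allele
    frequencies.  Pairs with Pearson r >= ``threshold`` over jointly covered
    sites are flagged; the later-listed member of each pair is marked for
    removal.
    """
    if f is None:
        f, _ = estimate_maf_em(dataset)
    fc = np.clip(f, 1e-6, 1 - 1e-6)
    dose = ((posterior_dosages(dataset, f) - 2 * fc[:, None])
            / np.sqrt(2 * fc * (1 - fc))[:, None])
    covered = ~dataset.missing_mask()
    n = dataset.n_individuals
    flagged: list[tuple[str, str, float]] = []
    to_remove: list[str] = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = covered[:, i] & covered[:, j]
            if shared.sum() < min_shared:
                warnings.warn(f"pair ({i},{j}): <{min_shared} shared sites, skipped")
                continue
            xi, xj = dose[shared, i], dose[shared, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            if r >= threshold:
                flagged.append((dataset.individuals[i], dataset.individuals[j], r))
                if dataset.individuals[j] not in to_remove:
                    to_remove.append(dataset.individuals[j])
    return flagged, to_remove


def excess_het_filter(dataset: GLDataset, alpha: float = 0.001,
                      f: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag sites with significantly more heterozygotes than HWE predicts.

    A surrogate for read-level mismapping tests: paralog-collapsed sites show
    excess heterozygosity.  Hard calls by maximum posterior (HWE prior at the
    site MAF), one-sided exact binomial tail, BH adjustment across sites,
    adjusted p < alpha flagged.
    """
    if f is None:
        f, _ = estimate_maf_em(dataset)
    prior = hwe_prior(f)[:, None, :]
    post = dataset.likelihoods * prior
    calls = np.argmax(post, axis=2)
    covered = ~dataset.missing_mask()
    n_called = covered.sum(axis=1)
    n_het = ((calls == 1) & covered).sum(axis=1)
    maf = np.minimum(f, 1 - f)
    testable = (maf > 1e-6) & (n_called > 0)
    p_het = 2 * maf * (1 - maf)
    pvals = np.ones(dataset.n_markers)
    pvals[testable] = stats.binom.sf(n_het[testable] - 1, n_called[testable],
                                     p_het[testable])
    flags = np.zeros(dataset.n_markers, dtype=bool)
    if testable.sum():
        adj = np.ones_like(pvals)
        adj[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
        flags = testable & (adj < alpha)
    else:
        adj = np.ones_like(pvals)
    report = pd.DataFrame({"marker": dataset.marker_ids, "n_called": n_called,
                           "n_het": n_het, "p": pvals, "p_adj": adj,
                           "flagged": flags, "tested": testable})
    return flags, report


def filter_bookkeeping(missingness: np.ndarray, absolute_cutoff: float,
                       n_duplicates: int) -> dict[str, int]:
    """Cohort bookkeeping: total - high-missingness - duplicates = retained."""
    miss = np.asarray(missingness, dtype=float)
    n_total = miss.size
    n_missing = int((miss > absolute_cutoff).sum())
    return {"total": n_total, "removed_missingness": n_missing,
            "removed_duplicates": int(n_duplicates),
            "retained": n_total - n_missing - int(n_duplicates)}
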