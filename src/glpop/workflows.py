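"""End-to-end study workflows over the synthetic generator.

Each function simulates a dataset under documented study conditions, runs
the relevant slice of the pipeline, and returns the headline numbers as a
dict.  The analysis drivers, the test suite and the reproduction script all
call these, so the numbers they report come from one code path.

Problem sizes (SNP counts, deme sizes, depths) are chosen to give the
statistics enough resolution at desk scale; they are stated per workflow.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from . import admixture, divergence, diversity, inversions, scans, simdata, structure


def two_deme_fst_study(seed: int = 0, n_snps: int = 50_000,
                       n_per_deme: int = 30, f_edge: float = 0.05,
                       depth: float = 2.0) -> dict:
    """Genome-wide Hudson FST between two demes with drift F across one edge."""
    half = n_snps // 2
    cfg = simdata.SimConfig(
        n_demes=2, n_per_deme=n_per_deme, seed=seed,
        chrom_layout=(("chr1", half * 1000, half), ("chr2", half * 1000, half)),
        deme_graph=((0, 1, f_edge),), mean_depth=depth)
    res = simdata.simulate_dataset(cfg)
    pf = divergence.pop_allele_freqs(res.dataset, res.samples.sites())
    _, fst = divergence.hudson_fst(pf, "deme0", "deme1")
    return {"fst": fst, "expected_fst": f_edge, "n_snps": res.dataset.n_markers,
            "afd": divergence.afd(pf, "deme0", "deme1")}


def scan_null_study(seed: int = 0, n_snps: int = 20_000,
                    n_individuals: int = 100, depth: float = 1.5) -> dict:
    """FastPCA calibration on a panmictic cohort: the statistic should be
    chi-square(1) and the >= 10-outlier window rule should fire nowhere."""
    cfg = simdata.SimConfig(
        n_demes=1, n_per_deme=n_individuals, seed=seed, deme_graph=(),
        chrom_layout=(("chr1", n_snps * 1000, n_snps),), mean_depth=depth)
    res = simdata.simulate_dataset(cfg)
    # the scan operates on MAF-filtered data, as in any real pipeline:
    # near-monomorphic sites have unstable standardised genotypes
    from . import qc
    dataset, _ = qc.filter_sites(res.dataset, depths=res.depths)
    model = structure.pcangsd_fit(dataset, k=2)
    scan = structure.fastpca_scan(model, axes=[1])
    s = scan.stats[:, 0]
    ks = sstats.kstest(s, sstats.chi2(1).cdf).statistic
    windows = scans.make_snp_windows(dataset.chroms, dataset.positions, 1000)
    regions, _ = scans.call_outlier_regions(scan, windows)
    return {"stat_mean": float(s.mean()), "stat_median": float(np.median(s)),
            "ks_distance": float(ks), "n_outliers": int(scan.outliers.sum()),
            "n_regions": len(regions), "n_snps": dataset.n_markers}


def inversion_study(seed: int = 0, n_per_deme: int = 30,
                    inv_snps: int = 1500, delta: float = 0.8,
                    inv_freqs: tuple = (0.2, 0.4, 0.6),
                    depth: float = 1.5) -> dict:
    """Detect and characterise one simulated inversion among three demes.

    Two 10 Mb chromosomes with 10,000 SNPs each; the inversion occupies
    ``inv_snps`` consecutive SNPs on chr1.  Runs the full local-PCA/MDS
    scan, karyotyping, heterozygosity contrast, LD-block Z-test and
    boundary refinement, and scores each against the truth ledger.
    """
    inv_start, inv_end = 2_000_000, 2_000_000 + inv_snps * 1000
    cfg = simdata.SimConfig(
        n_demes=3, n_per_deme=n_per_deme, seed=seed,
        chrom_layout=(("chr1", 10_000_000, 10_000),
                      ("chr2", 10_000_000, 10_000)),
        deme_graph=((0, 1, 0.05), (1, 2, 0.05)),
        inversion=simdata.InversionSpec("chr1", inv_start, inv_end,
                                        deme_freqs=inv_freqs,
                                        divergent_fraction=0.5, delta=delta),
        mean_depth=depth)
    res = simdata.simulate_dataset(cfg)
    ds = res.dataset
    f, _ = structure.estimate_maf_em(ds)
    dose = structure.posterior_dosages(ds, f)

    windows = scans.make_snp_windows(ds.chroms, ds.positions, 100)
    summaries = scans.local_pca_windows(ds, windows, k=4, f=f, dosages=dose)
    dists = scans.window_distances(summaries)
    coords = scans.mds(dists, axes=5)
    regions, members = scans.mds_outlier_clusters(coords, windows)

    tc, ts, te = res.truth.inversion_span
    out = {"n_regions": len(regions), "jaccard": 0.0,
           "karyotype_accuracy": np.nan, "p_ab_gt_aa": np.nan,
           "p_ab_gt_bb": np.nan, "ld_z": np.nan, "ld_p": np.nan,
           "refined_start": np.nan, "refined_end": np.nan,
           "boundary_error_frac": np.nan, "true_span": (ts, te)}
    best = None
    for _, r in regions.table.iterrows():
        if r["chrom"] != tc:
            continue
        inter = max(0, min(te, r["end"]) - max(ts, r["start"]))
        union = max(te, r["end"]) - min(ts, r["start"])
        jac = inter / union
        if best is None or jac > best[0]:
            best = (jac, r)
    if best is None:
        return out
    out["jaccard"] = float(best[0])
    region = best[1]
    span_idx = np.where((ds.chroms == tc) & (ds.positions >= region["start"])
                        & (ds.positions <= region["end"]))[0]

    pc1 = inversions.region_pc1(ds, span_idx, f=f, dosages=dose)
    calls = inversions.karyotype_kmeans(pc1, seed=seed)
    pred = np.array([{"AA": 0, "AB": 1, "BB": 2}[l] for l in calls.labels])
    truth_k = res.truth.karyotypes
    out["karyotype_accuracy"] = float(max((pred == truth_k).mean(),
                                          ((2 - pred) == truth_k).mean()))

    het = inversions.region_het_test(ds, span_idx, calls, f=f)
    out["p_ab_gt_aa"] = het["p_ab_gt_aa"]
    out["p_ab_gt_bb"] = het["p_ab_gt_bb"]

    ld = inversions.ld_block_test(ds, tc, int(region["start"]),
                                  int(region["end"]), seed=seed, f=f,
                                  dosages=dose)
    out["ld_z"], out["ld_p"] = ld["z"], ld["p"]

    rb = inversions.refine_boundaries(ds, tc, int(region["start"]),
                                      int(region["end"]), f=f, dosages=dose)
    out["refined_start"], out["refined_end"] = rb["start"], rb["end"]
    true_len = te - ts
    out["boundary_error_frac"] = float(max(abs(rb["start"] - ts),
                                           abs(rb["end"] - te)) / true_len)
    return out


def inversion_replicate_passes(rep: dict) -> bool:
    """Criteria a single inversion replicate must meet to count as recovered."""
    return (rep["jaccard"] >= 0.5
            and rep["karyotype_accuracy"] >= 0.95
            and rep["p_ab_gt_aa"] < 0.01 and rep["p_ab_gt_bb"] < 0.01
            and rep["ld_p"] < 0.05
            and rep["boundary_error_frac"] <= 0.10)


def ibd_study(seed: int = 0, n_snps: int = 10_000, n_per_deme: int = 20,
              f_per_cell: float = 0.005, depth: float = 1.5,
              permutations: int = 9999) -> dict:
    """Isolation by distance: 4-deme stepping stone along a water corridor.

    Deme spacing along the corridor is uneven, and each edge's drift is
    proportional to its geographic length (``f_per_cell`` per corridor
    cell), so genetic distance genuinely tracks kilometres.  With even
    spacing (or spacing-independent drift) the order-reversing permutation
    leaves the distance relationship intact and the Mantel null acquires a
    built-in tie.
    """
    coords = ((2, 1), (2, 4), (2, 8), (2, 10))
    gaps = tuple(b[1] - a[1] for a, b in zip(coords[:-1], coords[1:]))
    edges = tuple((i, i + 1, f_per_cell * g) for i, g in enumerate(gaps))
    cfg = simdata.SimConfig(
        n_demes=4, n_per_deme=n_per_deme, seed=seed,
        chrom_layout=(("chr1", n_snps * 1000, n_snps),),
        deme_graph=edges, deme_coords=coords, mean_depth=depth)
    res = simdata.simulate_dataset(cfg)
    pf = divergence.pop_allele_freqs(res.dataset, res.samples.sites())
    mats = divergence.pairwise_matrices(pf)
    raster = simdata.corridor_raster(12, cellsize_km=10.0)
    geo = divergence.least_cost_distance(raster, coords)
    r, p = divergence.mantel(mats["linearized_fst"], geo,
                             permutations=permutations, seed=seed)
    return {"mantel_r": r, "mantel_p": p, "fst_matrix": mats["fst"],
            "geo_km": geo}


def diversity_neutral_study(seed: int = 0, n_sites: int = 100_000,
                            n_individuals: int = 30, subsample: int = 26,
                            depth: float = 1.5) -> dict:
    """Windowed thetas and Tajima's D under the neutral-SFS generator.

    Sites are dense (one per 20 bp over 2 Mb) so 25 kb windows clear the
    1000-site floor; most sites are monomorphic in the sample, as in
    all-sites diversity scans.
    """
    cfg = simdata.SimConfig(
        n_demes=1, n_per_deme=n_individuals, seed=seed, deme_graph=(),
        chrom_layout=(("chr1", n_sites * 20, n_sites),),
        neutral_sfs_mode=True, mean_depth=depth)
    res = simdata.simulate_dataset(cfg)
    counts, sfs = diversity.pop_sfs(res.dataset, np.arange(n_individuals),
                                    subsample=subsample, seed=seed)
    wt = diversity.window_thetas(counts)
    return {"mean_tajimas_d": float(wt["tajimas_d"].mean()),
            "theta_ratio": float(wt["theta_w_1000"].mean()
                                 / wt["theta_pi_1000"].mean()),
            "n_windows": len(wt), "sfs": sfs}


def admixture_study(seed: int = 0, n_snps: int = 5_000, n_pure: int = 90,
                    n_admixed: int = 10, f_edge: float = 0.05,
                    depth: float = 1.5, maxiter: int = 2000) -> dict:
    """K=2 admixture recovery with 10% half-admixed individuals."""
    n = n_pure + n_admixed
    q_true = np.zeros((n, 2))
    q_true[:n_pure // 2, 0] = 1.0
    q_true[n_pure // 2:n_pure, 1] = 1.0
    q_true[n_pure:] = 0.5
    cfg = simdata.SimConfig(
        n_demes=2, n_per_deme=0, seed=seed,
        chrom_layout=(("chr1", n_snps * 1000, n_snps),),
        deme_graph=((0, 1, f_edge),), individual_q=q_true, mean_depth=depth)
    res = simdata.simulate_dataset(cfg)
    fit = admixture.admix_em(res.dataset, 2, seed=seed, maxiter=maxiter)
    perm = admixture.match_clusters(q_true, fit.q)
    rmse = float(np.sqrt(np.mean((fit.q[:, perm] - q_true) ** 2)))
    diffs = np.diff(fit.loglik_path)
    monotone = bool(np.all(diffs >= -1e-6 * abs(fit.loglik)))
    return {"q_rmse": rmse, "loglik_monotone": monotone,
            "n_iter": fit.n_iter, "flagged_admixed":
            int(admixture.flag_admixed(fit.q).sum())}
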