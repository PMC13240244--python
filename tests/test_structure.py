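import numpy as np
import pandas as pd
import pytest

from glpop import simdata, structure

from conftest import gl_from_genotypes


class TestMafEM:
    def test_hard_genotype_counting(self):
        g = np.array([[0] * 30 + [1] * 15 + [2] * 5])
        ds = gl_from_genotypes(g)
        f, flagged = structure.estimate_maf_em(ds)
        assert f[0] == pytest.approx(0.25, abs=1e-6)
        assert not flagged[0]

    def test_all_missing_site_flagged(self):
        ds = gl_from_genotypes(np.full((3, 10), -1))
        f, flagged = structure.estimate_maf_em(ds)
        assert flagged.all()
        assert np.allclose(f, 0.25)  # untouched initial value

    def test_recovery_at_2x(self):
        cfg = simdata.SimConfig(n_demes=1, n_per_deme=40, seed=17,
                                chrom_layout=(("chr1", 10_000_000, 10_000),),
                                deme_graph=(), mean_depth=2.0)
        res = simdata.simulate_dataset(cfg)
        f, _ = structure.estimate_maf_em(res.dataset)
        # oracle: the realised sample frequency (what the reads derive from);
        # comparing to the population frequency would mostly measure the
        # binomial sampling floor sqrt(p(1-p)/2n)
        sample_f = res.truth.genotypes.mean(axis=1) / 2
        rmse = np.sqrt(np.mean((f - sample_f) ** 2))
        assert rmse < 0.05


class TestPCAngsd:
    def test_equals_direct_pca_on_hard_genotypes(self, rng):
        g = rng.binomial(2, rng.uniform(0.1, 0.5, size=(200, 1)),
                         size=(200, 50))
        g = g[g.std(axis=1) > 0]
        ds = gl_from_genotypes(g)
        model = structure.pcangsd_fit(ds, k=3)
        # direct PCA of the standardised genotype matrix
        f = g.mean(axis=1) / 2
        x = (g - 2 * f[:, None]) / np.sqrt(2 * f * (1 - f))[:, None]
        cov = x.T @ x / x.shape[0]
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        np.testing.assert_allclose(model.eigenvalues[:5], vals[order][:5],
                                   atol=1e-6)
        for a in range(3):
            u, v = model.eigenvectors[:, a], vecs[:, order[a]]
            assert min(np.abs(u - v).max(), np.abs(u + v).max()) < 1e-6

    def test_pc1_separates_two_demes(self, two_deme_sim):
        model = structure.pcangsd_fit(two_deme_sim.dataset, k=2)
        pc1 = model.eigenvectors[:, 0]
        labels = two_deme_sim.truth.deme_of_individual
        r = np.corrcoef(pc1, labels)[0, 1]
        assert abs(r) > 0.9

    def test_panmictic_leading_eigenvalue_is_nullish(self, rng):
        # permutation oracle: breaking individual linkage leaves the leading
        # eigenvalue within the null spread
        g = rng.binomial(2, rng.uniform(0.1, 0.5, size=(2000, 1)),
                         size=(2000, 40))
        g = g[g.std(axis=1) > 0]
        ds = gl_from_genotypes(g)
        model = structure.pcangsd_fit(ds, k=2)
        null_vals = []
        for _ in range(20):
            gp = np.take_along_axis(g, np.argsort(
                rng.random(g.shape), axis=1), axis=1)
            dsp = gl_from_genotypes(gp)
            null_vals.append(structure.pcangsd_fit(dsp, k=2).eigenvalues[0])
        mu, sd = np.mean(null_vals), np.std(null_vals)
        assert abs(model.eigenvalues[0] - mu) < 3 * sd

    def test_k_too_large_errors(self):
        ds = gl_from_genotypes(np.eye(4, dtype=int))
        with pytest.raises(ValueError):
            structure.pcangsd_fit(ds, k=4)


class TestChooseAxes:
    @pytest.mark.parametrize("eig,expected", [
        ((10, 1, 1, 1, 1), 1),
        ((10, 8, 1, 1, 1), 2),
        ((5, 4), 1),            # fewer than 3 eigenvalues
    ])
    def test_elbow_rule(self, eig, expected):
        assert structure.choose_axes(np.array(eig, dtype=float)) == expected

    def test_override(self):
        assert structure.choose_axes(np.array([10.0, 1, 1]), override=4) == 4


class TestFastPCA:
    def test_stat_mean_is_one_and_outlier_snp_ranks_high(self, two_deme_sim):
        model = structure.pcangsd_fit(two_deme_sim.dataset, k=2)
        scan = structure.fastpca_scan(model, axes=[1])
        assert scan.stats[:, 0].mean() == pytest.approx(1.0, abs=1e-6)
        assert np.all(scan.pvalues > 0) and np.all(scan.pvalues <= 1)

    def test_divergent_snp_in_top_ranks(self, rng):
        # one SNP at 0.1/0.9 between demes against a weakly structured rest
        n = 30
        p = rng.uniform(0.2, 0.4, size=500)
        g1 = rng.binomial(2, p[:, None], size=(500, n))
        g2 = rng.binomial(2, np.clip(p + rng.normal(0, 0.05, 500), 0.05,
                                     0.95)[:, None], size=(500, n))
        g = np.hstack([g1, g2])
        g[0, :n] = rng.binomial(2, 0.1, n)
        g[0, n:] = rng.binomial(2, 0.9, n)
        keep = g.std(axis=1) > 0
        idx0 = int(np.cumsum(keep)[0]) - 1
        ds = gl_from_genotypes(g[keep])
        model = structure.pcangsd_fit(ds, k=2)
        scan = structure.fastpca_scan(model, axes=[1])
        rank = (scan.stats[:, 0] >= scan.stats[idx0, 0]).sum()
        assert rank <= 10

    def test_axis_beyond_kstar_errors(self, two_deme_sim):
        model = structure.pcangsd_fit(two_deme_sim.dataset, k=2)
        with pytest.raises(ValueError):
            structure.fastpca_scan(model, axes=[model.k_star + 1])


class TestQvalues:
    def test_bh_arithmetic(self):
        q = structure.qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, 0.04)

    def test_all_ones(self):
        assert np.all(structure.qvalues(np.ones(10)) == 1.0)

    def test_null_uniform_yields_no_discoveries(self, rng):
        p = rng.uniform(size=10_000)
        q = structure.qvalues(p)
        assert (q < 0.01).mean() < 0.001
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            structure.qvalues(np.array([0.0, 0.5]))


class TestLD:
    def test_duplicated_site_r2_one(self):
        g = np.array([[0, 1, 2, 1, 0, 2, 1, 0, 1, 2, 0, 1]])
        ds = gl_from_genotypes(np.vstack([g, g]))
        pairs = structure.ld_r2(ds, max_dist=10_000, min_shared=5)
        assert pairs.iloc[0]["r2"] == pytest.approx(1.0)

    def test_independent_sites_r2_near_1_over_n(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, size=(60, n))
        g = g[g.std(axis=1) > 0]
        ds = gl_from_genotypes(g)
        pairs = structure.ld_r2(ds, max_dist=100_000)
        assert pairs["r2"].mean() == pytest.approx(1 / n, abs=3 / n)

    def test_inversion_span_elevates_r2(self, rng):
        from glpop.simdata import InversionSpec, SimConfig
        cfg = SimConfig(n_demes=1, n_per_deme=50, seed=23, deme_graph=(),
                        chrom_layout=(("chr1", 1_000_000, 1_000),),
                        inversion=InversionSpec("chr1", 100_000, 500_000,
                                                deme_freqs=(0.4,)))
        res = simdata.simulate_dataset(cfg)
        pairs = structure.ld_r2(res.dataset, max_dist=20_000)
        inside = pairs[(pairs["pos_i"] >= 100_000) & (pairs["pos_j"] <= 500_000)]
        outside = pairs[pairs["pos_i"] > 500_000]
        pooled_sd = np.sqrt(inside["r2"].var() / len(inside)
                            + outside["r2"].var() / len(outside))
        z = (inside["r2"].mean() - outside["r2"].mean()) / pooled_sd
        assert z > 3

    def test_prune_removes_one_of_perfect_pair(self):
        g = np.array([[0, 1, 2, 1, 0, 2, 1, 0, 1, 2, 0, 1]])
        ds = gl_from_genotypes(np.vstack([g, g]))
        kept = structure.ld_prune(ds, max_dist=10_000)
        assert len(kept) == 1

    def test_prune_chain_keeps_flanks(self):
        g = np.array([[0, 1, 2, 1, 0, 2, 1, 0, 1, 2, 0, 1]] * 3)
        ds = gl_from_genotypes(g)
        pairs = pd.DataFrame([
            {"i": 0, "j": 1, "chrom": "chr1", "pos_i": 1000, "pos_j": 2000,
             "dist": 1000, "r2": 0.5},
            {"i": 1, "j": 2, "chrom": "chr1", "pos_i": 2000, "pos_j": 3000,
             "dist": 1000, "r2": 0.5},
            {"i": 0, "j": 2, "chrom": "chr1", "pos_i": 1000, "pos_j": 3000,
             "dist": 2000, "r2": 0.0}])
        kept = structure.ld_prune(ds, pairs=pairs)
        assert list(kept) == [0, 2]

    def test_prune_idempotent_and_verified(self, two_deme_sim, rng):
        sub = two_deme_sim.dataset.subset_markers(np.arange(300))
        pairs = structure.ld_r2(sub, max_dist=200_000)
        kept = structure.ld_prune(sub, pairs=pairs)
        kept_set = set(kept)
        bad = pairs[(pairs["r2"] > 0.075) & pairs["i"].isin(kept_set)
                    & pairs["j"].isin(kept_set)]
        assert len(bad) == 0        # exhaustive pair check
        sub2 = sub.subset_markers(kept)
        kept2 = structure.ld_prune(sub2)
        assert len(kept2) == len(kept)
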