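import numpy as np
import pytest

from glpop import inversions, simdata

from conftest import gl_from_genotypes


class TestKaryotypeKmeans:
    def test_three_separated_blobs_exact(self, rng):
        pc1 = np.concatenate([rng.normal(-5, 0.1, 40), rng.normal(0, 0.1, 30),
                              rng.normal(5, 0.1, 20)])
        calls = inversions.karyotype_kmeans(pc1, seed=0)
        assert (calls.labels[:40] == "AA").all()     # larger extreme cluster
        assert (calls.labels[40:70] == "AB").all()   # middle on PC1
        assert (calls.labels[70:] == "BB").all()

    def test_aa_is_commoner_homozygote_regardless_of_side(self, rng):
        pc1 = np.concatenate([rng.normal(-5, 0.1, 10), rng.normal(0, 0.1, 30),
                              rng.normal(5, 0.1, 40)])
        calls = inversions.karyotype_kmeans(pc1, seed=0)
        assert (calls.labels[70:] == "AA").all()
        assert (calls.labels[:10] == "BB").all()

    def test_too_few_individuals_errors(self):
        with pytest.raises(ValueError):
            inversions.karyotype_kmeans(np.arange(5.0))

    def test_simulated_inversion_karyotypes_recovered(self):
        cfg = simdata.SimConfig(
            n_demes=1, n_per_deme=80, seed=13, deme_graph=(),
            chrom_layout=(("chr1", 2_000_000, 2_000),),
            inversion=simdata.InversionSpec("chr1", 200_000, 1_200_000,
                                            deme_freqs=(0.3,), delta=0.8))
        res = simdata.simulate_dataset(cfg)
        ds = res.dataset
        span = np.where((ds.positions >= 200_000)
                        & (ds.positions <= 1_200_000))[0]
        pc1 = inversions.region_pc1(ds, span)
        calls = inversions.karyotype_kmeans(pc1, seed=13)
        pred = np.array([{"AA": 0, "AB": 1, "BB": 2}[l] for l in calls.labels])
        truth = res.truth.karyotypes
        acc = max((pred == truth).mean(), ((2 - pred) == truth).mean())
        assert acc >= 0.95

    def test_fallback_reclustering_still_accurate(self, rng):
        # skewed/overlapping clusters: AB spread into two lobes triggers the
        # k=4..6 fallback path, merged back to three groups
        pc1 = np.concatenate([rng.normal(-4, 0.3, 40),
                              rng.normal(-0.8, 0.3, 15),
                              rng.normal(0.8, 0.3, 15),
                              rng.normal(4, 0.3, 20)])
        truth = np.array(["AA"] * 40 + ["AB"] * 30 + ["BB"] * 20)
        calls = inversions.karyotype_kmeans(pc1, seed=1)
        assert (calls.labels == truth).mean() >= 0.9


class TestRegionHetTest:
    def _inversion_sim(self, delta=1.0, frac=1.0, seed=29):
        cfg = simdata.SimConfig(
            n_demes=1, n_per_deme=60, seed=seed, deme_graph=(),
            chrom_layout=(("chr1", 1_000_000, 1_000),),
            inversion=simdata.InversionSpec("chr1", 200_000, 700_000,
                                            deme_freqs=(0.4,),
                                            divergent_fraction=frac,
                                            delta=delta))
        return simdata.simulate_dataset(cfg)

    def test_heterokaryotypes_have_elevated_het(self):
        res = self._inversion_sim()
        ds = res.dataset
        span = np.where((ds.positions >= 200_000)
                        & (ds.positions <= 700_000))[0]
        karyo = res.truth.karyotypes
        calls = inversions.KaryotypeCalls(
            labels=np.array(["AA", "AB", "BB"])[karyo], pc1=np.zeros(60),
            centers={})
        out = inversions.region_het_test(ds, span, calls)
        assert out["p_ab_gt_aa"] < 1e-4
        assert out["p_ab_gt_bb"] < 1e-4
        assert out["medians"]["AB"] > out["medians"]["AA"]

    def test_permuted_labels_not_significant(self, rng):
        res = self._inversion_sim()
        ds = res.dataset
        span = np.where((ds.positions >= 200_000)
                        & (ds.positions <= 700_000))[0]
        perm = rng.permutation(res.truth.karyotypes)
        calls = inversions.KaryotypeCalls(
            labels=np.array(["AA", "AB", "BB"])[perm], pc1=np.zeros(60),
            centers={})
        out = inversions.region_het_test(ds, span, calls)
        assert out["p_ab_gt_aa"] > 0.01

    def test_single_member_group_still_tested(self, rng):
        g = rng.binomial(2, 0.3, size=(200, 10))
        ds = gl_from_genotypes(g)
        labels = np.array(["AA"] * 9 + ["AB"])
        calls = inversions.KaryotypeCalls(labels=labels, pc1=np.zeros(10),
                                          centers={})
        out = inversions.region_het_test(ds, np.arange(200), calls)
        assert np.isfinite(out["p_ab_gt_aa"])
        assert "BB" in out["skipped"]


class TestLdBlockTest:
    def test_background_region_not_significant(self, rng):
        g = rng.binomial(2, rng.uniform(0.1, 0.5, size=(3000, 1)),
                         size=(3000, 40))
        g = np.where(g.std(axis=1)[:, None] > 0, g, 1)
        ds = gl_from_genotypes(g, positions=(np.arange(3000) + 1) * 100)
        ps = [inversions.ld_block_test(ds, "chr1", 30_000, 60_000,
                                       n_random=200, seed=s)["p"]
              for s in range(5)]
        assert 0.1 < np.mean(ps) < 0.9

    def test_inversion_region_significant(self):
        cfg = simdata.SimConfig(
            n_demes=1, n_per_deme=50, seed=37, deme_graph=(),
            chrom_layout=(("chr1", 2_000_000, 2_000),),
            inversion=simdata.InversionSpec("chr1", 500_000, 900_000,
                                            deme_freqs=(0.4,), delta=0.8))
        res = simdata.simulate_dataset(cfg)
        out = inversions.ld_block_test(res.dataset, "chr1", 500_000, 900_000,
                                       n_random=300, seed=5)
        assert out["p"] < 0.05
        assert out["z"] > 3

    def test_degenerate_null_errors(self):
        g = np.array([[0, 1, 2, 1, 0, 2, 1, 0, 1, 2]])
        ds = gl_from_genotypes(np.repeat(g, 50, axis=0))
        with pytest.raises(ValueError, match="degenerate"):
            inversions.ld_block_test(ds, "chr1", 10_000, 20_000,
                                     n_random=50, seed=0)


class TestRefineBoundaries:
    def _block_dataset(self, rng, m=1000, n=60, block=(400, 499)):
        # haplotype-block construction: sites inside the block track a latent
        # biallelic haplotype through HWE draws (within-block r^2 ~ 0.65).
        # Identical columns would make the block rank-1, letting any outside
        # site that chance-correlates with the haplotype outscore the true
        # boundary against every block site simultaneously.
        hap = rng.binomial(2, 0.5, size=n)
        g = rng.binomial(2, rng.uniform(0.2, 0.5, size=(m, 1)), size=(m, n))
        p_block = 0.01 + 0.49 * hap
        for s in range(block[0], block[1] + 1):
            g[s] = rng.binomial(2, p_block)
        g = np.where(g.std(axis=1)[:, None] > 0, g, 1)
        return gl_from_genotypes(g, positions=(np.arange(m) + 1) * 1000)

    def test_strong_block_edges_recovered(self, rng):
        ds = self._block_dataset(rng)
        out = inversions.refine_boundaries(ds, "chr1", 350_000, 550_000)
        assert not out["fallback"]
        # true block spans ordinals 400..499 -> positions 401000..500000
        assert abs(out["start"] - 401_000) <= 5_000
        assert abs(out["end"] - 500_000) <= 5_000

    def test_null_chromosome_falls_back(self, rng):
        g = rng.binomial(2, rng.uniform(0.2, 0.5, size=(800, 1)),
                         size=(800, 40))
        g = np.where(g.std(axis=1)[:, None] > 0, g, 1)
        ds = gl_from_genotypes(g, positions=(np.arange(800) + 1) * 1000)
        out = inversions.refine_boundaries(ds, "chr1", 300_000, 500_000)
        if out["fallback"]:
            assert (out["start"], out["end"]) == (300_000, 500_000)
        else:
            # noise links only: refined span must not beat the block case
            assert out["end"] > out["start"]


class TestLengthsAndFrequencies:
    @pytest.mark.parametrize("start,end,expected", [
        (64_780_347, 68_132_863, 3352.5),
        (69_422_725, 70_743_943, 1321.2),
        (170_278, 955_945, 785.7),
        (49_066_208, 49_309_591, 243.4),
        (100, 1100, 1.0),
    ])
    def test_length_kbp(self, start, end, expected):
        assert inversions.region_length_kbp(start, end) == expected

    def test_length_invalid(self):
        with pytest.raises(ValueError):
            inversions.region_length_kbp(100, 100)

    def test_karyotype_frequencies(self):
        labels = np.array(["AA"] * 50 + ["AB"] * 100 + ["BB"] * 50)
        calls = inversions.KaryotypeCalls(labels=labels, pc1=np.zeros(200),
                                          centers={})
        sites = np.array(["s1"] * 200)
        table = inversions.karyotype_frequencies(calls, sites)
        row = table.iloc[0]
        assert row["allele_freq"] == pytest.approx(0.5)
        assert row["f_AA"] + row["f_AB"] + row["f_BB"] == pytest.approx(1.0)

    def test_all_aa_site(self):
        labels = np.array(["AA"] * 10)
        calls = inversions.KaryotypeCalls(labels=labels, pc1=np.zeros(10),
                                          centers={})
        table = inversions.karyotype_frequencies(calls, np.array(["s"] * 10))
        assert table.iloc[0]["allele_freq"] == 0.0
        assert table.iloc[0]["f_AA"] == 1.0
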