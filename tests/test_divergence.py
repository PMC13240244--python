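import numpy as np
import pytest

from glpop import divergence, simdata
from glpop.divergence import PopFreqs
from glpop.gl_io import RasterMap

from conftest import gl_from_genotypes


def _popfreqs(p1, p2, n=1000):
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    nn = np.full_like(p1, float(n))
    return PopFreqs(groups=["a", "b"], freqs=np.vstack([p1, p2]),
                    n_chrom=np.vstack([nn, nn]))


class TestHudsonFst:
    def test_fixed_difference_approaches_one(self):
        _, fst = divergence.hudson_fst(_popfreqs([0.0] * 100, [1.0] * 100,
                                                 n=10_000), "a", "b")
        assert fst == pytest.approx(1.0, abs=1e-3)

    def test_identical_frequencies_small_negative(self, rng):
        # estimator bias: expected slightly below zero, bounded by sampling
        p = rng.uniform(0.1, 0.5, 2000)
        n = 60
        _, fst = divergence.hudson_fst(_popfreqs(p, p, n=n), "a", "b")
        assert fst <= 0
        assert abs(fst) < 2 / (n - 1)

    def test_label_swap_invariance(self, rng):
        p1, p2 = rng.uniform(0.1, 0.5, 500), rng.uniform(0.1, 0.5, 500)
        pf = _popfreqs(p1, p2)
        _, f_ab = divergence.hudson_fst(pf, "a", "b")
        _, f_ba = divergence.hudson_fst(pf, "b", "a")
        assert f_ab == pytest.approx(f_ba)

    def test_two_deme_recovery(self, two_deme_sim):
        pf = divergence.pop_allele_freqs(two_deme_sim.dataset,
                                         two_deme_sim.samples.sites())
        _, fst = divergence.hudson_fst(pf, "deme0", "deme1")
        assert 0.03 < fst < 0.07

    def test_ratio_of_averages_vs_per_site_oracle(self, rng):
        # brute-force per-site check of the hard-genotype component formulas
        p1, p2 = rng.uniform(0.1, 0.9, 300), rng.uniform(0.1, 0.9, 300)
        n = 50
        pf = _popfreqs(p1, p2, n=n)
        per_site, fst = divergence.hudson_fst(pf, "a", "b")
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n - 1) - p2 * (1 - p2) / (n - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        np.testing.assert_allclose(per_site["num"], num)
        assert fst == pytest.approx(num.sum() / den.sum())
        # ratio of averages >= average of ratios under positive denominators
        assert fst >= np.mean(num / den) - 1e-12 or fst == pytest.approx(
            np.mean(num / den), abs=0.05)


class TestAfdAndLinearisation:
    def test_afd_hand_example(self):
        pf = _popfreqs([0.1, 0.3], [0.2, 0.1])
        assert divergence.afd(pf, "a", "b") == pytest.approx(0.15)

    def test_afd_symmetric_and_zero_for_identical(self):
        pf = _popfreqs([0.2, 0.4], [0.2, 0.4])
        assert divergence.afd(pf, "a", "b") == 0.0
        pf2 = _popfreqs([0.1, 0.5], [0.3, 0.2])
        assert divergence.afd(pf2, "a", "b") == divergence.afd(pf2, "b", "a")

    @pytest.mark.parametrize("f,expected", [
        (0.0, 0.0), (0.5, 1.0), (0.048, 0.048 / 0.952)])
    def test_linearize(self, f, expected):
        assert divergence.linearize_fst(f) == pytest.approx(expected)

    def test_linearize_rejects_one(self):
        with pytest.raises(ValueError):
            divergence.linearize_fst(1.0)

    def test_differentiation_increases_with_drift(self):
        fsts, afds = [], []
        for f_edge in (0.01, 0.05, 0.1):
            cfg = simdata.SimConfig(n_demes=2, n_per_deme=25, seed=5,
                                    chrom_layout=(("chr1", 5_000_000, 5_000),),
                                    deme_graph=((0, 1, f_edge),),
                                    mean_depth=2.0)
            res = simdata.simulate_dataset(cfg)
            pf = divergence.pop_allele_freqs(res.dataset, res.samples.sites())
            fsts.append(divergence.hudson_fst(pf, "deme0", "deme1")[1])
            afds.append(divergence.afd(pf, "deme0", "deme1"))
        assert fsts[0] < fsts[1] < fsts[2]
        assert afds[0] < afds[1] < afds[2]


class TestLeastCost:
    def test_straight_corridor(self):
        grid = np.ones((3, 12), dtype=int)
        grid[1, 1:11] = 0
        raster = RasterMap(grid, 0, 0, 1.0)
        d = divergence.least_cost_distance(raster, [(1, 1), (1, 10)])
        assert d[0, 1] == pytest.approx(9.0)

    def test_u_shaped_detour(self):
        # water wraps around a land block; straight line is blocked
        grid = np.ones((5, 5), dtype=int)
        grid[0, :] = 0
        grid[:, 0] = 0
        grid[:, 4] = 0
        raster = RasterMap(grid, 0, 0, 1.0)
        d = divergence.least_cost_distance(raster, [(4, 0), (4, 4)])
        # down col0 to row0 (4 steps) + across (with diagonals) + down col4:
        # brute-force oracle below confirms
        import networkx as nx
        g = nx.Graph()
        water = [(r, c) for r in range(5) for c in range(5) if grid[r, c] == 0]
        for r, c in water:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr or dc) and (r + dr, c + dc) in water:
                        g.add_edge((r, c), (r + dr, c + dc),
                                   weight=np.sqrt(2) if dr and dc else 1.0)
        expected = nx.dijkstra_path_length(g, (4, 0), (4, 4))
        assert d[0, 1] == pytest.approx(expected)

    def test_disconnected_basins_infinite(self):
        grid = np.ones((3, 5), dtype=int)
        grid[1, 0] = 0
        grid[1, 4] = 0
        raster = RasterMap(grid, 0, 0, 1.0)
        d = divergence.least_cost_distance(raster, [(1, 0), (1, 4)])
        assert np.isinf(d[0, 1])

    def test_outside_grid_errors(self):
        raster = RasterMap(np.zeros((2, 2), dtype=int), 0, 0, 1.0)
        with pytest.raises(ValueError):
            divergence.least_cost_distance(raster, [(0, 0), (5, 0)])

    def test_random_rasters_match_networkx_oracle(self, rng):
        import networkx as nx
        for _ in range(5):
            grid = (rng.random((8, 8)) < 0.3).astype(int)
            grid[0, 0] = grid[7, 7] = 0
            raster = RasterMap(grid, 0, 0, 1.0)
            d = divergence.least_cost_distance(raster, [(0, 0), (7, 7)])
            g = nx.Graph()
            water = {(r, c) for r in range(8) for c in range(8)
                     if grid[r, c] == 0}
            g.add_nodes_from(water)
            for r, c in water:
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if (dr or dc) and (r + dr, c + dc) in water:
                            g.add_edge((r, c), (r + dr, c + dc),
                                       weight=np.sqrt(2) if dr and dc else 1.0)
            try:
                expected = nx.dijkstra_path_length(g, (0, 0), (7, 7))
            except nx.NetworkXNoPath:
                expected = np.inf
            assert d[0, 1] == pytest.approx(expected)


class TestMantel:
    def test_affine_relation_gives_r_one_min_p(self, rng):
        x = rng.random((6, 6))
        a = x + x.T
        np.fill_diagonal(a, 0)
        b = 2 * a + 3
        np.fill_diagonal(b, 0)
        r, p = divergence.mantel(a, b, permutations=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 2 / (999 + 1) + 0.05   # identity-permutation ties only

    def test_against_skbio_oracle(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel
        x, y = rng.random((7, 7)), rng.random((7, 7))
        a, b = x + x.T, y + y.T
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        r, _ = divergence.mantel(a, b, permutations=99, seed=1)
        r_sk, _, _ = sk_mantel(DistanceMatrix(a), DistanceMatrix(b),
                               method="pearson", permutations=0,
                               alternative="greater")
        assert r == pytest.approx(r_sk, abs=1e-12)

    def test_null_p_uniformish(self, rng):
        ps = []
        for _ in range(100):
            x, y = rng.random((8, 8)), rng.random((8, 8))
            a, b = x + x.T, y + y.T
            np.fill_diagonal(a, 0)
            np.fill_diagonal(b, 0)
            _, p = divergence.mantel(a, b, permutations=99, seed=7)
            ps.append(p)
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            divergence.mantel(np.zeros((3, 3)), np.zeros((4, 4)))
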