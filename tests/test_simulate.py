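"""Generative benchmark: map, genotypes, networks, precisions, expression."""

import numpy as np
import pytest

from jcggm.io import GeneticMap
from jcggm.simulate import (CASE1_COEFFS, build_precision, default_map,
                            haldane, make_case1_B, make_case2_B, run_scenario,
                            simulate_backcross, simulate_expression,
                            simulate_scale_free, simulate_scenario)


class TestMapAndBackcross:
    def test_default_map_equally_spaced(self):
        gmap = default_map()
        pos = np.array([m[2] for m in gmap.markers])
        assert len(pos) == 10
        np.testing.assert_allclose(np.diff(pos), 1000 / 9)

    def test_haldane_closed_form(self):
        assert haldane(0.0) == 0.0
        assert haldane(100.0) == pytest.approx(0.5 * (1 - np.exp(-2)))
        assert haldane(1e6) == pytest.approx(0.5)

    def test_zero_distance_duplicates_column(self, rng):
        gmap = GeneticMap([("a", "1", 0.0), ("b", "1", 0.0)])
        X = simulate_backcross(200, gmap, rng)
        np.testing.assert_array_equal(X[:, 0], X[:, 1])

    def test_flip_frequency_matches_haldane(self, rng):
        d = 100.0
        gmap = GeneticMap([("a", "1", 0.0), ("b", "1", d)])
        n = 100_000
        X = simulate_backcross(n, gmap, rng)
        flips = np.mean(X[:, 0] != X[:, 1])
        r = haldane(d)
        se = np.sqrt(r * (1 - r) / n)
        assert abs(flips - r) < 3 * se

    def test_column_means_near_half(self, rng):
        for n in (30, 100):
            X = simulate_backcross(n, default_map(), rng)
            assert np.all(np.abs(X.mean(axis=0) - 0.5) < 3 * np.sqrt(0.25 / n))

    def test_empty_map_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_backcross(5, GeneticMap([]), rng)


class TestScaleFree:
    def test_edge_counts_and_superset(self):
        common, adjs = simulate_scale_free(30, seed=0)
        M = common.sum() // 2
        assert M == 29  # 6 seed edges + 23 attachment edges
        for adj in adjs:
            assert np.all(adj[common])  # superset of the common structure
            extra = adj.sum() // 2 - M
            assert extra == 3  # round(0.1 * 29)

    def test_common_graph_connected(self):
        import networkx as nx
        common, _ = simulate_scale_free(30, seed=1)
        g = nx.from_numpy_array(common)
        assert nx.is_connected(g)

    def test_heavier_tail_than_erdos_renyi(self, rng):
        # preferential attachment produces larger hubs than a density-
        # matched ER graph in the vast majority of paired draws
        import networkx as nx
        wins = 0
        for i in range(100):
            common, _ = simulate_scale_free(30, seed=1000 + i)
            max_ba = common.sum(axis=0).max()
            g = nx.gnm_random_graph(30, int(common.sum() // 2),
                                    seed=int(rng.integers(2**31)))
            max_er = max(dict(g.degree).values())
            wins += max_ba >= max_er
        assert wins >= 90


class TestBuildPrecision:
    def test_support_and_diagonal_rule(self, rng):
        _, adjs = simulate_scale_free(30, seed=3)
        om = build_precision(adjs[0], rng)
        off = ~np.eye(30, dtype=bool)
        assert np.array_equal(np.abs(om) > 0, adjs[0] | np.eye(30, dtype=bool))
        mags = np.abs(om[adjs[0]])
        assert np.all((mags >= 0.5) & (mags <= 1.0))
        np.testing.assert_allclose(np.diag(om),
                                   np.abs(om * off).sum(axis=1))
        assert np.linalg.eigvalsh(om).min() > 1e-8

    def test_two_node_graph_always_singular(self, rng):
        # equality-dominant 2x2 matrices have a zero eigenvalue, so every
        # draw is rejected and the resampling loop must give up
        adj = np.array([[False, True], [True, False]])
        with pytest.raises(RuntimeError, match="positive definite"):
            build_precision(adj, rng, max_tries=50)

    def test_isolated_node_gets_unit_variance(self, rng):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        adj[0, 2] = adj[2, 0] = True  # triangle + isolated node 3
        om = build_precision(adj, rng)
        assert om[3, 3] == 1.0

    def test_invalid_adjacency_rejected(self, rng):
        with pytest.raises(ValueError):
            build_precision(np.zeros((3, 3), dtype=bool), rng)  # no edges
        bad = np.zeros((3, 3), dtype=bool)
        bad[0, 1] = True  # asymmetric
        with pytest.raises(ValueError):
            build_precision(bad, rng)


class TestExpression:
    def test_deterministic_given_seed(self):
        X = np.ones((5, 2))
        B = np.zeros((3, 2))
        om = np.eye(3)
        a = simulate_expression(X, B, om, np.random.default_rng(42))
        b = simulate_expression(X, B, om, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_identity_precision_unit_variance(self, rng):
        Y = simulate_expression(np.zeros((50_000, 1)), np.zeros((4, 1)),
                                np.eye(4), rng)
        cov = np.cov(Y.T)
        assert np.abs(cov - np.eye(4)).max() < 0.05

    def test_sample_covariance_matches_inverse_precision(self, rng):
        _, adjs = simulate_scale_free(10, seed=5)
        om = build_precision(adjs[0], rng)
        target = np.linalg.inv(om)
        Y = simulate_expression(np.zeros((100_000, 1)), np.zeros((10, 1)),
                                om, rng)
        emp = np.cov(Y.T)
        rel = np.linalg.norm(emp - target) / np.linalg.norm(target)
        assert rel < 0.02

    def test_non_pd_precision_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_expression(np.zeros((5, 1)), np.zeros((2, 1)),
                                np.diag([1.0, -1.0]), rng)


class TestCoefficients:
    def test_case1_positions_and_values(self):
        Bs = make_case1_B()
        assert len(Bs) == 3
        for B, coeffs in zip(Bs, CASE1_COEFFS):
            assert np.count_nonzero(B) == 3
            assert B[0, 0] == coeffs[0]
            assert B[1, 3] == coeffs[1]
            assert B[2, 7] == coeffs[2]
        assert Bs[0][0, 0] == -0.09

    def test_case1_deterministic(self):
        a, b = make_case1_B(), make_case1_B()
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_case2_block_structure(self, rng):
        Bs = make_case2_B(rng)
        for B in Bs:
            assert np.count_nonzero(B) == 30  # every gene on one marker
            assert np.count_nonzero(B[:18, 0]) == 18
            assert np.count_nonzero(B[18:25, 3]) == 7
            assert np.count_nonzero(B[25:, 7]) == 5
            # genes 19..25 load on marker 4 only
            assert np.count_nonzero(B[18:25, [0, 1, 2, 4, 5, 6, 7, 8, 9]]) == 0

    def test_case2_perturbation_centered_on_case1(self):
        # averaged over seeds the block-1 condition-2 coefficients
        # concentrate on 1.361 with sd 0.1
        vals = []
        for seed in range(20):
            Bs = make_case2_B(np.random.default_rng(seed))
            vals.extend(Bs[1][:18, 0])
        m = np.mean(vals)
        assert abs(m - 1.361) < 3 * 0.1 / np.sqrt(len(vals))


class TestScenarios:
    def test_same_seed_identical_stream(self):
        a = list(run_scenario("case1", 30, 2, seed=5))
        b = list(run_scenario("case1", 30, 2, seed=5))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.X, sb.X)
            for ya, yb in zip(sa.Ys, sb.Ys):
                np.testing.assert_array_equal(ya, yb)

    def test_truth_structure(self):
        scn = simulate_scenario("case2", 100, seed=9)
        assert scn.T == 3 and scn.p == 30
        assert scn.X.shape == (100, 10)
        M = scn.common_adjacency.sum() // 2
        for adj, om in zip(scn.true_adjacencies, scn.true_omegas):
            assert adj.sum() // 2 - M == 3
            assert np.linalg.eigvalsh(om).min() > 1e-8
            offsup = np.abs(om) > 0
            np.fill_diagonal(offsup, False)
            assert np.array_equal(offsup, adj)

    @pytest.mark.parametrize("n", [30, 100])
    def test_supported_sample_sizes(self, n):
        scn = simulate_scenario("case1", n, seed=1)
        assert all(Y.shape == (n, 30) for Y in scn.Ys)

    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError):
            simulate_scenario("case3", 30, seed=0)
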