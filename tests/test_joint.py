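"""Joint truncated-log estimation: penalty, weights, LLA fit, BIC."""

import numpy as np
import pytest

from jcggm.joint import (FitConfig, PenaltySpec, PrecisionSet, bic_score,
                         default_lambda_grid, fit_jcggm, initialize_omegas,
                         lla_weights, select_lambda, truncated_log_penalty)
from jcggm.wglasso import WGlassoProblem, solve_wglasso


def _random_cov(rng, p, n=None):
    A = rng.standard_normal((n or 4 * p, p))
    return A.T @ A / A.shape[0]


class TestTruncatedLogPenalty:
    def test_boundary_value_both_branches_equal_one(self):
        eps = 1e-3
        a = np.full((3, 3), eps)
        np.fill_diagonal(a, 0.0)
        assert truncated_log_penalty(a, eps) == pytest.approx(6.0)

    def test_zero_sums_give_zero(self):
        assert truncated_log_penalty(np.zeros((4, 4)), 1e-3) == 0.0

    def test_single_pair_log_branch(self):
        eps = 1e-3
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = np.e * eps
        # log(e*eps) - log(eps) + 1 = 2 per ordered pair
        assert truncated_log_penalty(a, eps) == pytest.approx(4.0)

    def test_continuity_at_epsilon(self):
        # machine-precision agreement of the two branches at a = eps
        eps = 1e-3
        for delta in (0.0, 1e-15, -1e-15):
            a = np.zeros((2, 2))
            a[0, 1] = a[1, 0] = eps + delta
            below = 2 * (eps + delta) / eps
            above = 2 * (np.log(eps + delta) - np.log(eps) + 1.0)
            got = truncated_log_penalty(a, eps)
            assert abs(got - below) < 1e-12 or abs(got - above) < 1e-12
        assert abs(2 * 1.0 - truncated_log_penalty(
            np.array([[0.0, eps], [eps, 0.0]]), eps)) < 1e-14

    def test_negative_entries_rejected(self):
        a = np.zeros((2, 2))
        a[0, 1] = a[1, 0] = -0.1
        with pytest.raises(ValueError):
            truncated_log_penalty(a, 1e-3)


class TestLLAWeights:
    def test_zero_estimates_hit_cap(self):
        zeta = lla_weights([np.zeros((4, 4))], 1e-3)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(zeta[off], 1000.0)
        np.testing.assert_allclose(np.diag(zeta), 0.0)

    def test_reciprocal_of_cross_condition_sum(self):
        om1 = np.zeros((3, 3))
        om1[0, 1] = om1[1, 0] = 0.5
        om2 = np.zeros((3, 3))
        om2[0, 1] = om2[1, 0] = -0.5
        om3 = np.zeros((3, 3))
        om3[0, 1] = om3[1, 0] = 1.0
        zeta = lla_weights([om1, om2, om3], 1e-3)
        assert zeta[0, 1] == pytest.approx(0.5)  # 1/(0.5+0.5+1)
        assert zeta[0, 2] == pytest.approx(1000.0)

    def test_pair_with_sum_two(self):
        om = np.zeros((2, 2))
        om[0, 1] = om[1, 0] = 2.0
        assert lla_weights([om], 1e-3)[0, 1] == pytest.approx(0.5)


class TestInitializeOmegas:
    def test_identity_untouched(self):
        out = initialize_omegas([np.eye(4)])
        np.testing.assert_allclose(out[0], np.eye(4))

    def test_ill_conditioned_gets_repeated_ridge(self):
        sigma = np.diag([1.0, 1e-9])
        out = initialize_omegas([sigma], delta_ridge=1e-3, cond_threshold=1e3)
        # smallest k with (1 + k*delta)/(1e-9 + k*delta) <= 1e3 is k = 2
        expected = np.diag([1.0 / (1.0 + 2e-3), 1.0 / (1e-9 + 2e-3)])
        np.testing.assert_allclose(out[0], expected, rtol=1e-10)

    def test_singular_rank_one_becomes_pd(self):
        v = np.array([1.0, 2.0, -1.0])
        sigma = np.outer(v, v)
        out = initialize_omegas([sigma])
        assert np.linalg.eigvalsh(out[0]).min() > 0


class TestFitJCGGM:
    def test_vanishing_penalty_recovers_inverse(self, rng):
        S = _random_cov(rng, 5)
        fit = fit_jcggm([S], [40], PenaltySpec(1e-3, 1e-8))
        np.testing.assert_allclose(fit.omegas[0], np.linalg.inv(S), atol=1e-4)

    def test_identical_conditions_give_identical_estimates(self, rng):
        S = _random_cov(rng, 6)
        fit = fit_jcggm([S, S], [50, 50], PenaltySpec(1e-3, 5.0))
        np.testing.assert_allclose(fit.omegas[0], fit.omegas[1], atol=1e-12)

    def test_epsilon_cap_reduces_to_scalar_glasso(self, rng):
        # eps larger than any reachable sum(|omega|): weights are constant
        # 1/eps at every iteration, i.e. a scalar-penalty glasso at lam/eps
        S = _random_cov(rng, 5)
        eps, lam, n = 1e6, 2e6, 50
        fit = fit_jcggm([S], [n], PenaltySpec(eps, lam))
        W = np.ones((5, 5)) - np.eye(5)
        ref, _ = solve_wglasso(WGlassoProblem(S, W, lam / (eps * n), tol=1e-8))
        np.testing.assert_allclose(fit.omegas[0], ref, atol=1e-5)

    def test_objective_path_non_increasing(self, rng):
        S1, S2 = _random_cov(rng, 8), _random_cov(rng, 8)
        fit = fit_jcggm([S1, S2], [60, 60], PenaltySpec(1e-3, 10.0))
        path = np.array(fit.objective_path)
        assert np.all(np.diff(path) <= 1e-6 * (1 + np.abs(path[:-1])))

    def test_lam_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_jcggm([np.eye(3)], [10], PenaltySpec(1e-3, 0.0))

    def test_joint_sparsity_coupling(self):
        # two conditions; the pair (0,1) is supported in both, the pair
        # (2,3) only in condition 1, at equal marginal strength.  The
        # shared edge must survive to a larger lambda than the isolated
        # one because its cross-condition sum keeps its LLA weight low.
        def cov_with(pairs, p=4, rho=0.45):
            om = np.eye(p)
            for i, j in pairs:
                om[i, j] = om[j, i] = rho
            return np.linalg.inv(om)

        S_both = cov_with([(0, 1), (2, 3)])
        S_only01 = cov_with([(0, 1)])
        n = 200
        grid = np.geomspace(200.0, 0.2, 25)
        died_common = died_isolated = None
        for lam in grid[::-1]:  # ascending in sparsity
            fit = fit_jcggm([S_both, S_only01], [n, n], PenaltySpec(1e-3, lam))
            adj = fit.adjacency()
            if adj[0][0, 1] or adj[1][0, 1]:
                died_common = lam
            if adj[0][2, 3]:
                died_isolated = lam
        assert died_common is not None and died_isolated is not None
        assert died_common > died_isolated


class TestBIC:
    def test_identity_fit_value(self):
        fit = PrecisionSet([np.eye(3)], lam=1.0)
        got = bic_score(fit, [np.eye(3)], [30])
        assert got == pytest.approx(3.0 + 3 * np.log(30) / 30)

    def test_df_counts_diagonal(self, rng):
        p = 4
        om = np.diag(rng.uniform(0.5, 2.0, p))
        fit = PrecisionSet([om], lam=1.0)
        s = np.diag(1.0 / np.diag(om))
        # df = p diagonal entries
        expected = (-np.linalg.slogdet(om)[1] + p + np.log(25) * p / 25)
        assert bic_score(fit, [s], [25]) == pytest.approx(expected)

    def test_df_term_decreases_with_n(self):
        fit = PrecisionSet([np.eye(3)], lam=1.0)
        assert bic_score(fit, [np.eye(3)], [60]) < bic_score(fit, [np.eye(3)], [30])

    def test_non_pd_estimate_rejected(self):
        fit = PrecisionSet([np.diag([1.0, -1.0])], lam=1.0)
        with pytest.raises(np.linalg.LinAlgError):
            bic_score(fit, [np.eye(2)], [10])


class TestSelectLambda:
    def test_single_lambda_grid(self, rng):
        S = _random_cov(rng, 4)
        cfg = FitConfig(lam_grid=np.array([3.0]))
        lam, fit, path = select_lambda([S], [40], PenaltySpec(), cfg)
        assert lam == 3.0
        assert len(path) == 1

    def test_path_covers_grid_without_early_stop(self, rng):
        S = _random_cov(rng, 4)
        cfg = FitConfig(n_lambdas=8, bic_patience=None)
        lam, fit, path = select_lambda([S], [40], PenaltySpec(), cfg)
        assert len(path) == 8
        bics = [r["bic"] for r in path if np.isfinite(r["bic"])]
        assert min(bics) == pytest.approx(
            [r["bic"] for r in path if r["lam"] == lam][0])

    def test_empty_grid_rejected(self, rng):
        cfg = FitConfig(lam_grid=np.array([]))
        with pytest.raises(ValueError):
            select_lambda([np.eye(3)], [10], PenaltySpec(), cfg)

    def test_default_grid_descending_positive(self, rng):
        S = _random_cov(rng, 5)
        grid = default_lambda_grid([S], [30], PenaltySpec())
        assert np.all(grid > 0)
        assert grid[0] == pytest.approx(30 * np.abs(
            S - np.diag(np.diag(S))).max())
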