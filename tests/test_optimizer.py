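"""GP surrogate, acquisition functions, NSGA-II and hypervolume."""

import numpy as np
import pytest
from scipy.linalg import cho_solve
from scipy.stats import norm

from reactbo import (
    expected_improvement,
    fit_gp,
    hypervolume,
    non_dominated_mask,
    non_dominated_sort,
    nsga2,
    suggest_ei,
    suggest_tsemo,
    thompson_sample,
)
from reactbo.gp import log_marginal_likelihood_oracle
from reactbo.moo import crowding_distance, dominates
from reactbo.optimizer import hypervolume_improvement


@pytest.fixture(scope="module")
def gp2d():
    rng = np.random.default_rng(3)
    X = rng.random((20, 2))
    y = np.sin(4 * X[:, 0]) + (X[:, 1] - 0.3) ** 2
    return fit_gp(X, y, seed=0)


class TestGP:
    def test_interpolates_training_data(self, gp2d):
        mu = gp2d.predict(gp2d.X, return_std=False)
        assert np.max(np.abs(mu - gp2d.y)) < 1e-5

    def test_posterior_variance_small_at_training_points(self, gp2d):
        _, sd = gp2d.predict(gp2d.X)
        noise_sd = np.sqrt(gp2d.noise_variance + 1e-8) * gp2d.y_std
        assert np.all(sd <= noise_sd + 1e-4)

    def test_reverts_to_prior_far_away(self, gp2d):
        mu, sd = gp2d.predict(np.array([[50.0, -50.0]]))
        assert mu[0] == pytest.approx(gp2d.y_mean, abs=1e-3)
        assert sd[0] == pytest.approx(np.sqrt(gp2d.signal_variance) * gp2d.y_std, rel=0.05)

    def test_log_marginal_likelihood_matches_cholesky_oracle(self, gp2d):
        assert gp2d.log_marginal_likelihood() == pytest.approx(
            log_marginal_likelihood_oracle(gp2d), abs=1e-6)

    def test_degenerate_design_rejected(self):
        X = np.tile([0.5, 0.5], (5, 1))
        with pytest.raises(ValueError, match="degenerate|identical"):
            fit_gp(X, np.arange(5.0))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X, y = rng.random((15, 3)), rng.random(15)
        a = fit_gp(X, y, seed=7)
        b = fit_gp(X, y, seed=7)
        assert np.allclose(a.length_scales, b.length_scales)
        assert a.log_marginal_likelihood() == b.log_marginal_likelihood()


class TestExpectedImprovement:
    def test_nonnegative_everywhere(self, gp2d, rng):
        X = rng.random((200, 2))
        assert np.all(expected_improvement(gp2d, X, best=float(gp2d.y.max())) >= 0)

    def test_vanishes_at_incumbent_training_point(self, gp2d):
        # sigma -> 0 and mu -> f_best there, so EI -> 0 (within the jitter floor)
        i = int(np.argmax(gp2d.y))
        ei = expected_improvement(gp2d, gp2d.X[i][None, :], best=float(gp2d.y.max()))
        away = expected_improvement(gp2d, np.array([[0.5, 0.9]]), best=float(gp2d.y.max()))
        assert ei[0] < 1e-4
        assert ei[0] < away[0]

    def test_closed_form_matches_monte_carlo(self, gp2d, rng):
        """EI closed form vs 1e6-draw Monte-Carlo at random probe points."""
        best = float(gp2d.y.max())
        X = rng.random((20, 2))
        mu, sd = gp2d.predict(X)
        ei = expected_improvement(gp2d, X, best)
        draws = rng.standard_normal(10**6)
        for j in range(len(X)):
            samples = np.maximum(mu[j] + sd[j] * draws - best, 0.0)
            mc, se = samples.mean(), samples.std() / 1000.0
            assert abs(ei[j] - mc) <= 3 * se + 1e-12

    def test_suggest_ei_stays_in_unit_cube_and_deterministic(self, gp2d):
        a = suggest_ei(gp2d, 2, best=float(gp2d.y.max()), seed=5)
        b = suggest_ei(gp2d, 2, best=float(gp2d.y.max()), seed=5)
        assert np.array_equal(a, b)
        assert np.all((a >= 0) & (a <= 1))

    def test_ei_loop_finds_quadratic_optimum(self):
        """Noiseless 1-D quadratic maximization located within 1e-2 in <= 25
        evaluations (sanity convergence of the EI loop)."""
        f = lambda x: -((x - 0.62) ** 2)
        rng = np.random.default_rng(0)
        X = list(rng.random(4))
        y = [float(f(x)) for x in X]
        for it in range(21):
            gp = fit_gp(np.array(X)[:, None], np.array(y), seed=it, n_restarts=2)
            xn = float(suggest_ei(gp, 1, best=max(y), seed=100 + it)[0])
            X.append(xn)
            y.append(float(f(xn)))
            if abs(X[int(np.argmax(y))] - 0.62) < 1e-2:
                break
        assert abs(X[int(np.argmax(y))] - 0.62) < 1e-2


@pytest.fixture(scope="module")
def gp1d_noisy():
    # smooth 1-D target with observation noise: a well-conditioned posterior
    rng = np.random.default_rng(7)
    X = np.linspace(0, 1, 25)[:, None]
    y = np.sin(3 * X[:, 0]) + 0.2 * X[:, 0] + 0.05 * rng.standard_normal(25)
    return fit_gp(X, y, seed=0)


class TestThompsonSampling:
    def test_seeded_determinism(self, gp2d, rng):
        probe = rng.random((100, 2))
        f1 = thompson_sample(gp2d, n_features=300, seed=9)
        f2 = thompson_sample(gp2d, n_features=300, seed=9)
        assert np.array_equal(f1(probe), f2(probe))
        f3 = thompson_sample(gp2d, n_features=300, seed=10)
        assert not np.allclose(f1(probe), f3(probe))

    def test_sample_mean_converges_to_posterior_mean(self, gp1d_noisy, rng):
        """Average of many sampled paths approaches the posterior mean:
        tightly against the spectral model's analytic mean (pure Monte-Carlo
        error), and against the exact GP mean with a small allowance for the
        finite-feature approximation."""
        gp = gp1d_noisy
        probe = rng.random((20, 1))
        n_samp = 500
        vals = np.empty((n_samp, len(probe)))
        mean_fns = []
        for s in range(n_samp):
            ts, mean_fn, _ = thompson_sample(gp, n_features=400, seed=1000 + s,
                                             _return_posterior=True)
            vals[s] = ts(probe)
            mean_fns.append(mean_fn(probe))
        mc_mean = vals.mean(axis=0)
        analytic_mean = np.mean(mean_fns, axis=0)
        mu, sd = gp.predict(probe)
        mc_band = 3 * sd / np.sqrt(n_samp)
        assert np.all(np.abs(mc_mean - analytic_mean) <= mc_band + 1e-9)
        assert np.all(np.abs(mc_mean - mu) <= mc_band + 0.02)

    def test_sample_variance_matches_analytic_posterior(self, gp1d_noisy, rng):
        """Variance across draws matches the spectral posterior by the law of
        total variance (weight-posterior variance averaged over frequency
        draws plus the variance of the per-draw means)."""
        from scipy.linalg import cho_solve as _cho_solve

        gp = gp1d_noisy
        probe = rng.random((12, 1))
        n_samp = 500
        vals = np.empty((n_samp, len(probe)))
        mean_Ws = np.empty((n_samp, len(probe)))
        var_Ws = np.empty((n_samp, len(probe)))
        for s in range(n_samp):
            ts, mean_fn, (cf, _noise) = thompson_sample(
                gp, n_features=400, seed=2000 + s, _return_posterior=True)
            vals[s] = ts(probe)
            mean_Ws[s] = mean_fn(probe)
            Phi_p = ts.features(probe)
            var_Ws[s] = np.sum(Phi_p * _cho_solve(cf, Phi_p.T).T, axis=1) * gp.y_std**2
        emp_var = vals.var(axis=0)
        predicted = var_Ws.mean(axis=0) + mean_Ws.var(axis=0)
        rel = np.abs(emp_var - predicted) / predicted
        assert np.max(rel) < 0.35
        assert np.median(rel) < 0.15

    def test_min_feature_count_enforced(self, gp2d):
        with pytest.raises(ValueError):
            thompson_sample(gp2d, n_features=1)


class TestNSGA2:
    def test_convex_toy_front(self):
        res = nsga2([lambda X: X[:, 0], lambda X: 1 - X[:, 0]], dim=1,
                    pop_size=40, generations=40, seed=0)
        assert np.max(np.abs(res.F.sum(axis=1) - 1)) < 1e-6

    def test_output_is_non_dominated_and_deterministic(self):
        fns = [lambda X: X[:, 0] ** 2 + X[:, 1],
               lambda X: (1 - X[:, 0]) ** 2 + X[:, 1] ** 2]
        a = nsga2(fns, dim=2, pop_size=30, generations=25, seed=4)
        b = nsga2(fns, dim=2, pop_size=30, generations=25, seed=4)
        assert np.array_equal(a.X, b.X)
        assert np.all(non_dominated_mask(a.F))

    def test_single_point_population_is_front(self):
        res = nsga2([lambda X: X[:, 0]], dim=1, pop_size=1, generations=0, seed=0)
        assert len(res.F) == 1

    def test_sorting_matches_bruteforce_dominance_oracle(self, rng):
        for _ in range(20):
            F = rng.random((20, rng.integers(2, 4)))
            fronts = non_dominated_sort(F)
            # oracle: rank by repeatedly stripping brute-force minima
            remaining = list(range(len(F)))
            rank_oracle = {}
            level = 0
            while remaining:
                front = [i for i in remaining
                         if not any(dominates(F[j], F[i]) for j in remaining if j != i)]
                for i in front:
                    rank_oracle[i] = level
                remaining = [i for i in remaining if i not in front]
                level += 1
            for lvl, front in enumerate(fronts):
                for i in front:
                    assert rank_oracle[i] == lvl

    def test_crowding_boundary_points_infinite(self, rng):
        F = rng.random((8, 2))
        mask = non_dominated_mask(F)
        d = crowding_distance(F[mask])
        if mask.sum() >= 3:
            assert np.isinf(d).sum() >= 2


class TestHypervolume:
    def test_unit_box(self):
        assert hypervolume(np.array([[0.0, 0.0]]), np.array([1.0, 1.0])) == 1.0

    def test_two_point_staircase(self):
        front = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert hypervolume(front, np.array([2.0, 2.0])) == pytest.approx(3.0)

    def test_matches_monte_carlo_box_oracle(self, rng):
        front = rng.random((6, 3))
        ref = np.array([1.5, 1.5, 1.5])
        exact = hypervolume(front, ref)
        pts = rng.random((200_000, 3)) * ref
        dominated = np.zeros(len(pts), dtype=bool)
        for f in front:
            dominated |= np.all(pts >= f, axis=1)
        mc = dominated.mean() * ref.prod()
        assert exact == pytest.approx(mc, rel=0.01)

    def test_dominated_point_changes_nothing(self):
        front = np.array([[0.0, 1.0], [1.0, 0.0]])
        with_dom = np.vstack([front, [1.5, 1.5]])
        ref = np.array([2.0, 2.0])
        assert hypervolume(with_dom, ref) == hypervolume(front, ref)

    def test_point_outside_reference_rejected(self):
        with pytest.raises(ValueError):
            hypervolume(np.array([[3.0, 0.0]]), np.array([2.0, 2.0]))


class TestTSEMO:
    def test_single_objective_reduces_to_thompson_maximization(self, gp2d):
        x = suggest_tsemo([gp2d], gp2d.y[:, None], dim=2, seed=3,
                          n_features=200, pop_size=30, generations=20)
        assert x.shape == (2,) and np.all((x >= 0) & (x <= 1))

    def test_deterministic_given_seed_and_history(self, gp2d):
        rng = np.random.default_rng(8)
        y2 = rng.random(len(gp2d.y))
        gp_b = fit_gp(gp2d.X, y2, seed=1)
        F = np.column_stack([gp2d.y, y2])
        a = suggest_tsemo([gp2d, gp_b], F, dim=2, seed=42, n_features=200,
                          pop_size=30, generations=20)
        b = suggest_tsemo([gp2d, gp_b], F, dim=2, seed=42, n_features=200,
                          pop_size=30, generations=20)
        assert np.array_equal(a, b)

    def test_hvi_selection_beats_all_other_candidates(self, rng):
        """The chosen candidate's hypervolume improvement is maximal over the
        candidate front (exhaustive scan)."""
        observed = rng.random((15, 2))
        candidates = rng.random((25, 2)) * 0.8
        ref = np.full(2, 1.6)
        hvi = hypervolume_improvement(candidates, observed, ref)
        best = int(np.argmax(hvi))
        assert np.all(hvi[best] >= hvi)
        assert np.all(hvi >= 0)

    def test_dominated_candidate_has_zero_improvement(self):
        observed = np.array([[0.1, 0.1]])
        candidates = np.array([[0.5, 0.5], [0.05, 0.05]])
        hvi = hypervolume_improvement(candidates, observed, np.array([1.0, 1.0]))
        assert hvi[0] == 0.0
        assert hvi[1] > 0.0
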