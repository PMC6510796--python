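"""Ridge regression: closed form, CV selection, noise equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from motiondecomp import (
    NoiseModel,
    noise_equivalence_check,
    predict,
    prediction_error,
    ridge_fit,
    select_lambda_cv,
)
from motiondecomp.ridge import default_lambda_grid, ridge_cost


class TestRidgeFit:
    def test_extreme_shrinkage_kills_weights(self, rng):
        z = rng.normal(size=(12, 4))
        d = rng.normal(size=12)
        w = ridge_fit(z, d, 1e12).w
        assert np.linalg.norm(w) < 1e-6

    def test_orthonormal_design_closed_form(self):
        # Z^T Z = I: the fit shrinks the true coordinate by 1/(1+lam)
        z = np.eye(4)
        d = z[:, 0].copy()
        for lam in (0.0, 0.5, 3.0):
            w = ridge_fit(z, d, lam).w
            np.testing.assert_allclose(
                w, [1 / (1 + lam), 0, 0, 0], atol=1e-12)

    @pytest.mark.parametrize("t,d,lam", [(6, 3, 0.7), (10, 4, 0.01),
                                         (5, 9, 2.0)])
    def test_matches_numerical_minimizer(self, rng, t, d, lam):
        # oracle: generic quasi-Newton minimization of the penalized cost
        z = rng.normal(size=(t, d))
        dv = rng.normal(size=t)
        w = ridge_fit(z, dv, lam).w
        res = minimize(ridge_cost, np.zeros(d), args=(z, dv, lam),
                       method="BFGS", options={"gtol": 1e-12})
        np.testing.assert_allclose(w, res.x, atol=1e-6)

    def test_rank_deficient_at_zero_lambda_advises_regularization(self, rng):
        z = rng.normal(size=(6, 3))
        z = np.hstack([z, z[:, :1]])  # duplicated column
        with pytest.raises(np.linalg.LinAlgError, match="lambda > 0"):
            ridge_fit(z, rng.normal(size=6), 0.0)

    def test_push_through_identity(self, rng):
        # primal D x D and dual T x T solutions agree for lam > 0
        for t, d in [(20, 7), (7, 20)]:
            z = rng.normal(size=(t, d))
            dv = rng.normal(size=t)
            lam = 0.3
            g = z.T @ z + lam * np.eye(d)
            w_primal = np.linalg.solve(g, z.T @ dv)
            gd = z @ z.T + lam * np.eye(t)
            w_dual = z.T @ np.linalg.solve(gd, dv)
            np.testing.assert_allclose(w_primal, w_dual, atol=1e-9)
            np.testing.assert_allclose(ridge_fit(z, dv, lam).w, w_primal,
                                       atol=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_shrinkage_monotone_in_lambda(self, seed):
        g = np.random.default_rng(seed)
        z = g.normal(size=(15, 5))
        d = g.normal(size=15)
        norms = [np.linalg.norm(ridge_fit(z, d, lam).w)
                 for lam in (0.01, 0.1, 1.0, 10.0, 100.0)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestPredictAndError:
    def test_zero_weights_predict_zero(self, rng):
        z = rng.normal(size=(8, 3))
        np.testing.assert_array_equal(predict(np.zeros(3), z).values, 0.0)

    def test_single_feature_product(self):
        h = predict(np.array([2.0]), np.array([[1.0], [-1.0]]))
        np.testing.assert_allclose(h.values, [2.0, -2.0])

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="feature count"):
            predict(np.zeros(3), rng.normal(size=(5, 4)))

    def test_perfect_prediction_scores_zero(self, rng):
        d = rng.normal(size=10)
        assert prediction_error(d, d) == 0.0

    def test_mean_predictor_scores_one(self, rng):
        d = rng.normal(size=50)
        d = (d - d.mean()) / d.std()
        assert prediction_error(d, np.zeros(50)) == pytest.approx(1.0)

    def test_half_amplitude_scores_quarter(self):
        d = np.array([1.0, -1.0])
        assert prediction_error(d, 0.5 * d) == pytest.approx(0.25)

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            prediction_error(np.zeros(4), np.ones(4))


class TestLambdaSelection:
    def test_pure_noise_selects_heavy_shrinkage(self):
        # no signal: expected held-out error is minimized by shrinking to
        # the zero predictor, so the selected lambda sits in the top grid
        # decade essentially always and at the grid maximum in the majority
        grid = default_lambda_grid()
        picks = []
        for s in range(50):
            g = np.random.default_rng(100 + s)
            x = g.normal(size=(100, 10))
            d = g.normal(size=100)
            picks.append(select_lambda_cv(x, d, seed=s).lam)
        picks = np.asarray(picks)
        assert (picks >= 1e3).mean() >= 0.95
        assert (picks == grid[-1]).mean() > 0.5

    def test_noiseless_planted_signal_selects_grid_minimum(self, rng):
        x = rng.normal(size=(60, 5))
        d = x @ rng.normal(size=5)
        model = select_lambda_cv(x, d, seed=0)
        assert model.lam == default_lambda_grid()[0]
        assert model.cv_error < 1e-10

    def test_duplicate_grid_entries_equivalent_to_deduplicated(self, rng):
        x = rng.normal(size=(40, 4))
        d = x @ rng.normal(size=4) + rng.normal(size=40)
        m1 = select_lambda_cv(x, d, grid=[0.1, 1.0, 10.0], seed=3)
        m2 = select_lambda_cv(x, d, grid=[0.1, 1.0, 1.0, 10.0, 0.1], seed=3)
        assert m1.lam == m2.lam
        np.testing.assert_allclose(m1.w, m2.w)

    def test_too_few_trials_for_folds(self, rng):
        with pytest.raises(ValueError, match="smaller k"):
            select_lambda_cv(rng.normal(size=(5, 2)), rng.normal(size=5),
                             k=10)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(30, 3))
        d = rng.normal(size=30)
        m1 = select_lambda_cv(x, d, seed=11)
        m2 = select_lambda_cv(x, d, seed=11)
        assert m1.lam == m2.lam
        np.testing.assert_array_equal(m1.w, m2.w)

    def test_parameter_recovery_planted_weights(self, rng):
        # T=500, D=32, |w_true|=1, noise sd 0.1: direction recovered
        t, d = 500, 32
        z = rng.normal(size=(t, d))
        w_true = rng.normal(size=d)
        w_true /= np.linalg.norm(w_true)
        y = z @ w_true + 0.1 * rng.normal(size=t)
        model = select_lambda_cv(z, y, seed=0)
        cos = model.w @ w_true / np.linalg.norm(model.w)
        assert cos >= 0.99


class TestNoiseEquivalence:
    def test_zero_noise_degenerates_to_fitting_term(self, rng):
        z = rng.normal(size=(10, 3))
        d = rng.normal(size=10)
        res = noise_equivalence_check(z, d, NoiseModel(0.0, 10, 0), 1.0)
        assert res.mc_cost == res.analytic_cost
        w = ridge_fit(z, d, 1.0).w
        r = d - z @ w
        assert res.mc_cost == pytest.approx(0.5 * r @ r)

    def test_monte_carlo_matches_closed_form_within_3se(self, rng):
        z = rng.normal(size=(20, 4))
        d = rng.normal(size=20)
        res = noise_equivalence_check(
            z, d, NoiseModel(sigma_o=0.5, n_draws=100_000, seed=1), 1.0)
        assert abs(res.mc_cost - res.analytic_cost) < 3 * res.mc_se

    def test_performance_noise_reading_adds_constant_only(self, rng):
        # perturbing d leaves no weight-dependent term, only +T sigma^2/2
        z = rng.normal(size=(15, 3))
        d = rng.normal(size=15)
        res = noise_equivalence_check(
            z, d, NoiseModel(0.4, 50_000, 2), 1.0, noise_on="performance")
        assert abs(res.mc_cost - res.analytic_cost) < 3 * res.mc_se

    def test_se_shrinks_with_sqrt_draws(self, rng):
        z = rng.normal(size=(10, 3))
        d = rng.normal(size=10)
        se1 = noise_equivalence_check(
            z, d, NoiseModel(0.5, 20_000, 0), 1.0).mc_se
        se2 = noise_equivalence_check(
            z, d, NoiseModel(0.5, 40_000, 0), 1.0).mc_se
        assert se2 / se1 == pytest.approx(1 / np.sqrt(2), rel=0.1)
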