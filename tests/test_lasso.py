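"""Weighted-LASSO core: cost function, thresholding, solver optimality."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from sklearn.linear_model import Lasso

from sepsismet.lasso import (
    LassoFit,
    PenalizedProblem,
    coef_raw_scale,
    cost,
    kkt_violation,
    lambda_max,
    lasso_fit,
    lasso_fit_logistic,
    lasso_path,
    soft_threshold,
)


def _manual_problem(X, y, v=None):
    """Build a problem from already-prepared (not re-standardised) arrays."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    p = X.shape[1]
    v = np.ones(p) if v is None else np.asarray(v, float)
    return PenalizedProblem(
        X=X, y=y, v=v, feature_names=[f"x{j}" for j in range(p)],
        x_mean=np.zeros(p), x_scale=np.ones(p), y_mean=0.0,
    )


def random_problem(seed, n=10, p=4):
    rng = np.random.default_rng(seed)
    return PenalizedProblem.from_raw(
        rng.standard_normal((n, p)), rng.standard_normal(n)
    )


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z, gamma, expected",
        [(0.8, 0.5, 0.3), (-0.8, 0.5, -0.3), (0.3, 0.5, 0.0), (-0.2, 0.2, 0.0)],
    )
    def test_formula(self, z, gamma, expected):
        assert soft_threshold(z, gamma) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(-1e6, 1e6), st.floats(0, 1e6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_shrinks_toward_zero_preserving_sign(self, z, gamma):
        s = soft_threshold(z, gamma)
        assert abs(s) <= abs(z)
        assert s == 0 or np.sign(s) == np.sign(z)

    def test_zero_threshold_is_identity(self):
        assert soft_threshold(1.7, 0.0) == 1.7

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestCost:
    def test_zero_coefficients(self):
        prob = _manual_problem([[1.0], [-1.0]], [1.0, -1.0])
        for lam in (0.0, 0.5, 7.0):
            assert cost(prob, np.zeros(1), lam) == pytest.approx(0.5)

    def test_exact_fit_no_penalty(self):
        prob = _manual_problem([[1.0], [-1.0]], [1.0, -1.0])
        assert cost(prob, np.array([1.0]), 0.0) == pytest.approx(0.0)

    def test_hand_evaluated_value(self):
        # N=2, y=(1,-1), x=(1,-1), w=0.5, lam=0.1: (1/4)(0.5) + 0.1*0.5
        prob = _manual_problem([[1.0], [-1.0]], [1.0, -1.0])
        assert cost(prob, np.array([0.5]), 0.1) == pytest.approx(0.175)

    def test_negative_lambda_rejected(self):
        prob = random_problem(0)
        with pytest.raises(ValueError):
            cost(prob, np.zeros(prob.p), -0.1)


class TestLambdaMax:
    def test_zero_response(self):
        prob = _manual_problem([[1.0], [-1.0]], [0.0, 0.0])
        assert lambda_max(prob) == 0.0

    def test_hand_evaluated(self):
        prob = _manual_problem([[1.0], [-1.0]], [2.0, -2.0])
        assert lambda_max(prob) == pytest.approx(2.0)

    def test_just_above_lambda_max_gives_empty_support(self):
        prob = random_problem(1, n=30, p=6)
        fit = lasso_fit(prob, 1.0001 * lambda_max(prob))
        assert np.all(fit.w == 0.0)

    def test_all_zero_penalty_weights_rejected(self):
        prob = _manual_problem([[1.0], [-1.0]], [2.0, -2.0], v=[0.0])
        with pytest.raises(ValueError):
            lambda_max(prob)


class TestSolver:
    def test_orthonormal_closed_form(self):
        # columns with x_j'x_k = N*delta_jk: solution is soft-thresholded OLS
        rng = np.random.default_rng(3)
        N, p = 40, 2
        Q, _ = np.linalg.qr(rng.standard_normal((N, p)))
        X = Q * np.sqrt(N)
        ols = np.array([0.8, -0.2])
        y = X @ ols
        prob = _manual_problem(X, y)
        fit = lasso_fit(prob, 0.5)
        np.testing.assert_allclose(fit.w, [0.3, 0.0], atol=1e-10)

    def test_matches_sklearn(self):
        prob = random_problem(7, n=25, p=6)
        fit = lasso_fit(prob, 0.07)
        sk = Lasso(alpha=0.07, fit_intercept=False, tol=1e-14, max_iter=10**6)
        sk.fit(prob.X, prob.y)
        np.testing.assert_allclose(fit.w, sk.coef_, atol=1e-8)

    def test_matches_convex_oracle_and_beats_perturbations(self):
        prob = random_problem(10, n=10, p=4)
        lam = 0.1
        fit = lasso_fit(prob, lam)
        # split w = w+ - w- turns the cost into a smooth bound-constrained QP
        def obj(z):
            w = z[:4] - z[4:]
            return cost(prob, w, 0.0) + lam * float(prob.v @ z[:4] + prob.v @ z[4:])
        res = minimize(obj, np.zeros(8), bounds=[(0, None)] * 8,
                       method="L-BFGS-B", options={"ftol": 1e-16, "gtol": 1e-12,
                                                   "maxiter": 10**5})
        np.testing.assert_allclose(fit.w, res.x[:4] - res.x[4:], atol=1e-5)
        rng = np.random.default_rng(0)
        W = fit.w + rng.uniform(-0.05, 0.05, size=(10_000, 4))
        resid = prob.y[None, :] - W @ prob.X.T
        costs = (resid**2).sum(axis=1) / (2 * prob.N) + lam * np.abs(W).sum(axis=1)
        assert cost(prob, fit.w, lam) <= costs.min() + 1e-12

    def test_kkt_conditions(self):
        for seed in range(5):
            prob = random_problem(seed, n=20, p=8)
            fit = lasso_fit(prob, 0.05)
            assert fit.converged
            assert kkt_violation(prob, fit) < 1e-6

    def test_cost_nonincreasing_every_sweep(self):
        prob = random_problem(4, n=15, p=6)
        lam = 0.02
        costs = [cost(prob, lasso_fit(prob, lam, tol=0.0, max_sweeps=k).w, lam)
                 for k in range(1, 12)]
        assert all(a >= b - 1e-12 for a, b in zip(costs, costs[1:]))

    def test_warm_path_matches_cold_starts(self):
        prob = random_problem(5, n=30, p=8)
        grid = lambda_max(prob) * 0.001 ** (np.arange(12) / 11)
        W = lasso_path(prob, grid)
        for k, lam in enumerate(grid):
            cold = lasso_fit(prob, lam)
            np.testing.assert_allclose(W[k], cold.w, atol=1e-6)

    def test_support_weakly_decreasing_with_lambda(self):
        prob = random_problem(6, n=40, p=10)
        grid = lambda_max(prob) * 0.001 ** (np.arange(20) / 19)
        sizes = [int(np.sum(w != 0)) for w in lasso_path(prob, grid)]
        # grid is decreasing, so support sizes should be weakly increasing
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_lambda_zero_matches_least_squares(self):
        prob = random_problem(8, n=30, p=5)
        fit = lasso_fit(prob, 0.0)
        beta, *_ = np.linalg.lstsq(prob.X, prob.y, rcond=None)
        np.testing.assert_allclose(fit.w, beta, atol=1e-6)

    def test_penalty_weights_respected(self):
        prob = random_problem(9, n=30, p=4)
        v = np.array([1.0, 1.0, 1e6, 1.0])
        prob.v = v
        fit = lasso_fit(prob, 0.01)
        assert fit.w[2] == 0.0
        assert kkt_violation(prob, fit) < 1e-6

    def test_nonfinite_input_rejected(self):
        X = np.ones((4, 2)); X[0, 0] = np.nan
        with pytest.raises(ValueError):
            PenalizedProblem.from_raw(X, np.ones(4))


class TestScaling:
    def test_from_raw_standardisation(self):
        prob = random_problem(12, n=50, p=6)
        assert np.all(np.abs(prob.X.mean(axis=0)) < 1e-10)
        np.testing.assert_allclose(prob.X.std(axis=0, ddof=1), 1.0)

    def test_raw_scale_backtransform_reproduces_predictions(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(1, 5, size=(30, 4))
        y = rng.standard_normal(30)
        prob = PenalizedProblem.from_raw(X, y)
        fit = lasso_fit(prob, 0.05)
        beta, b0 = coef_raw_scale(fit, prob)
        pred_std = fit.intercept + prob.X @ fit.w
        np.testing.assert_allclose(b0 + X @ beta, pred_std, atol=1e-10)


class TestLogisticVariant:
    def test_recovers_signs_and_zeroes_at_high_lambda(self):
        rng = np.random.default_rng(0)
        n, p = 300, 5
        X = rng.standard_normal((n, p))
        eta = 1.5 * X[:, 0] - 1.5 * X[:, 1]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        prob = PenalizedProblem.from_raw(X, y)
        fit = lasso_fit_logistic(prob, 0.02)
        assert fit.w[0] > 0 and fit.w[1] < 0
        heavy = lasso_fit_logistic(prob, 5.0)
        assert np.all(heavy.w == 0.0)
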