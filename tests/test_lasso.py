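"""The coordinate-descent Lasso solver against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

from gaclock.lasso import (
    cv_lasso,
    default_lambda_grid,
    fit_lasso,
    kkt_max_violation,
    lambda_max,
    lasso_objective,
    lasso_path,
)


def _orthonormal_design(n=100, p=5, seed=0):
    """Centered design with (1/n) X'X = I."""
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    X = Q[:, :p] * np.sqrt(n)
    X = X - X.mean(axis=0)
    Q2, _ = np.linalg.qr(X)
    return Q2 * np.sqrt(n)


class TestFitLasso:
    def test_null_model_at_lambda_max(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (60, 30))
        y = rng.normal(280, 12, 60)
        lmax = lambda_max(X, y)
        for lam in (lmax, lmax * 1.5):
            fit = fit_lasso(X, y, lam)
            assert np.count_nonzero(fit.coef) == 0
            assert fit.intercept == pytest.approx(y.mean(), abs=1e-12)

    def test_soft_threshold_on_orthonormal_design(self):
        X = _orthonormal_design(seed=4)
        rng = np.random.default_rng(5)
        y = rng.normal(0, 3, X.shape[0])
        lam = 0.4
        b = X.T @ (y - y.mean()) / X.shape[0]
        expected = np.sign(b) * np.maximum(np.abs(b) - lam, 0.0)
        fit = fit_lasso(X, y, lam, standardize=False)
        np.testing.assert_allclose(fit.coef, expected, atol=1e-6)

    def test_objective_matches_convex_solver(self):
        """L-BFGS-B on the split b = b+ - b- reformulation is a
        general-purpose convex oracle for the same objective."""
        rng = np.random.default_rng(11)
        n, p = 200, 50
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:5] = [2, -1, 0.5, 1, -2]
        y = X @ beta + rng.normal(size=n)
        lam = 0.1

        fit = fit_lasso(X, y, lam, standardize=False)
        mine = lasso_objective(X, y, fit.intercept, fit.coef, lam)

        Xc = X - X.mean(axis=0)
        yc = y - y.mean()

        def obj(v):
            b = v[:p] - v[p:]
            r = yc - Xc @ b
            return 0.5 * np.mean(r**2) + lam * v.sum()

        def grad(v):
            b = v[:p] - v[p:]
            g = -Xc.T @ (yc - Xc @ b) / n
            return np.concatenate([g + lam, -g + lam])

        res = minimize(
            obj, np.zeros(2 * p), jac=grad, method="L-BFGS-B",
            bounds=[(0, None)] * (2 * p),
            options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
        )
        assert mine <= res.fun * (1 + 1e-6) + 1e-12
        assert abs(mine - res.fun) / max(res.fun, 1e-12) < 1e-6

    def test_kkt_conditions_at_tolerance(self):
        rng = np.random.default_rng(21)
        X = rng.uniform(0, 1, (150, 80))
        y = X[:, 0] * 20 + rng.normal(280, 5, 150)
        for lam, standardize in [(0.05, True), (0.05, False), (0.5, True)]:
            fit = fit_lasso(X, y, lam, standardize=standardize)
            assert kkt_max_violation(X, y, fit, standardize=standardize) < 1e-6

    def test_objective_non_increasing_across_sweeps(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(80, 40))
        y = X[:, :3] @ [1.0, -2.0, 0.5] + rng.normal(size=80)
        fit = fit_lasso(X, y, 0.05, trace=True)
        tr = np.array(fit.objective_trace)
        assert len(tr) >= 1
        assert (np.diff(tr) <= 1e-12).all()

    def test_non_finite_input_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_lasso(X, np.zeros(10), 0.1)

    def test_warm_started_path_matches_cold_fits(self):
        rng = np.random.default_rng(41)
        X = rng.uniform(0, 1, (60, 25))
        y = X[:, 0] * 15 + rng.normal(280, 4, 60)
        grid = default_lambda_grid(X, y, n_lambda=10, min_ratio=0.05)
        intercepts, coefs = lasso_path(X, y, grid, tol=1e-10)
        for k in (0, 4, 9):
            cold = fit_lasso(X, y, grid[k])
            np.testing.assert_allclose(coefs[k], cold.coef, atol=1e-6)
            assert intercepts[k] == pytest.approx(cold.intercept, abs=1e-6)


class TestCrossValidation:
    def test_curve_spans_grid_and_errors_nonnegative(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (50, 20))
        y = X[:, 0] * 10 + rng.normal(280, 3, 50)
        grid = default_lambda_grid(X, y, n_lambda=25)
        res = cv_lasso(X, y, lambdas=grid, n_folds=5, seed=0)
        assert len(res.mean_error) == len(grid)
        assert (res.mean_error >= 0).all()
        assert res.lambda_selected in grid

    def test_pure_noise_selects_sparse_model(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, (100, 50))
        y = rng.normal(280, 10, 100)
        res = cv_lasso(X, y, n_folds=10, seed=11)
        fit = fit_lasso(X, y, res.lambda_selected)
        assert np.count_nonzero(fit.coef) <= 2

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (60, 15))
        y = X[:, 1] * 12 + rng.normal(280, 3, 60)
        a = cv_lasso(X, y, n_folds=5, seed=9)
        b = cv_lasso(X, y, n_folds=5, seed=9)
        assert a.lambda_selected == b.lambda_selected
        np.testing.assert_array_equal(a.mean_error, b.mean_error)

    def test_one_se_rule_selects_larger_penalty(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 1, (80, 30))
        y = X[:, 0] * 10 + X[:, 1] * 5 + rng.normal(280, 3, 80)
        lam_min = cv_lasso(X, y, n_folds=5, seed=1, lambda_rule="min").lambda_selected
        lam_1se = cv_lasso(X, y, n_folds=5, seed=1, lambda_rule="1se").lambda_selected
        assert lam_1se >= lam_min

    def test_constant_target_rejected(self):
        X = np.random.default_rng(0).uniform(0, 1, (30, 5))
        with pytest.raises(ValueError, match="constant"):
            cv_lasso(X, np.full(30, 280.0))
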