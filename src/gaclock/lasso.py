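"""L1-penalised least squares by pathwise active-set coordinate descent.

Solves

    min_{b0, b}  (1/2n) * sum_i (y_i - b0 - x_i' b)^2  +  lam * sum_j |b_j|

with the intercept unpenalised. Predictors are centred, and optionally
scaled to unit (population) standard deviation, before the penalty is
applied; coefficients are reported on the original scale. The solver runs
coordinate descent on the current active set until the coefficients are
stationary, then makes a full Karush-Kuhn-Tucker (KKT) pass over all
features to admit violators, repeating until no feature violates. Warm
starts along a decreasing lambda path make cross-validation cheap.

``lambda_max = max_j |<x_j, y - ybar>| / n`` (on the working scale) is the
smallest penalty at which the null model is optimal; any ``lam >=
lambda_max`` yields all-zero coefficients and intercept = mean(y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LassoFit",
    "CVResult",
    "fit_lasso",
    "lasso_path",
    "lambda_max",
    "default_lambda_grid",
    "cv_lasso",
    "kkt_max_violation",
    "lasso_objective",
]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (samples x features)")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values; impute before fitting")
    return X


def _as_target(y, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != n:
        raise ValueError("y length does not match X")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    return y


def _working_scale(X: np.ndarray, standardize: bool):
    xm = X.mean(axis=0)
    Xw = X - xm
    if standardize:
        xs = Xw.std(axis=0)
        xs = np.where(xs > 0, xs, 1.0)
        Xw = Xw / xs
    else:
        xs = np.ones(X.shape[1])
    # column curvature (1/n)||x_j||^2; zero for constant columns
    z = np.einsum("ij,ij->j", Xw, Xw) / X.shape[0]
    return np.asfortranarray(Xw), xm, xs, z


@dataclass
class LassoFit:
    """Solution of one L1 problem, on the original predictor scale."""

    intercept: float
    coef: np.ndarray
    lam: float
    n_sweeps: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)

    def support(self) -> np.ndarray:
        return np.flatnonzero(self.coef)

    def predict(self, X) -> np.ndarray:
        return self.intercept + _as_matrix(X) @ self.coef


def lasso_objective(X, y, intercept: float, coef, lam: float) -> float:
    """(1/2n)*RSS + lam*||coef||_1 evaluated on the given (original-scale) fit."""
    X = _as_matrix(X)
    y = _as_target(y, X.shape[0])
    r = y - intercept - X @ np.asarray(coef, float)
    return float(0.5 * np.mean(r**2) + lam * np.abs(coef).sum())


def lambda_max(X, y, standardize: bool = True) -> float:
    """Smallest penalty for which the all-zero solution is optimal."""
    X = _as_matrix(X)
    y = _as_target(y, X.shape[0])
    Xw, _, _, _ = _working_scale(X, standardize)
    yc = y - y.mean()
    return float(np.max(np.abs(Xw.T @ yc)) / X.shape[0])


def default_lambda_grid(
    X, y, n_lambda: int = 100, min_ratio: float = 1e-3, standardize: bool = True
) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to min_ratio*lambda_max."""
    lmax = lambda_max(X, y, standardize)
    if lmax == 0:
        raise ValueError("lambda_max is 0; y carries no signal in X")
    return np.geomspace(lmax, min_ratio * lmax, n_lambda)


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


try:  # jitted kernel for the hot loop; the pure-Python path remains for tracing
    from numba import njit

    @njit(cache=True)
    def _cd_kernel(Xw, yc, z, lam, b, tol, max_sweeps):  # pragma: no cover
        n, p = Xw.shape
        r = yc - Xw @ b
        active = b != 0.0
        total = 0
        kkt_eps = lam * 1e-9 + 1e-12
        for _outer in range(100):
            idx = np.flatnonzero(active & (z > 0.0))
            for _sweep in range(max_sweeps):
                total += 1
                max_delta = 0.0
                for t in range(idx.shape[0]):
                    j = idx[t]
                    rho = 0.0
                    for i in range(n):
                        rho += Xw[i, j] * r[i]
                    rho = rho / n + z[j] * b[j]
                    if rho > lam:
                        bn = (rho - lam) / z[j]
                    elif rho < -lam:
                        bn = (rho + lam) / z[j]
                    else:
                        bn = 0.0
                    d = bn - b[j]
                    if d != 0.0:
                        for i in range(n):
                            r[i] -= d * Xw[i, j]
                        b[j] = bn
                        if abs(d) > max_delta:
                            max_delta = abs(d)
                if max_delta <= tol:
                    break
            g = Xw.T @ r
            added = False
            for j in range(p):
                if (not active[j]) and z[j] > 0.0 and abs(g[j]) / n > lam + kkt_eps:
                    active[j] = True
                    added = True
            if not added:
                return total, True
        return total, False

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _cd_solve(
    Xw: np.ndarray,
    yc: np.ndarray,
    z: np.ndarray,
    lam: float,
    b: np.ndarray,
    tol: float,
    max_sweeps: int,
    trace: list[float] | None = None,
) -> tuple[int, bool]:
    """Active-set coordinate descent on the working scale, in place."""
    if trace is None and _HAVE_NUMBA:
        return _cd_kernel(Xw, yc, z, lam, b, tol, max_sweeps)
    n = Xw.shape[0]
    r = yc - Xw @ b
    active = b != 0.0
    total_sweeps = 0
    kkt_eps = lam * 1e-9 + 1e-12
    for _outer in range(100):
        idx = np.flatnonzero(active & (z > 0))
        for _sweep in range(max_sweeps):
            total_sweeps += 1
            max_delta = 0.0
            for j in idx:
                xj = Xw[:, j]
                rho = (xj @ r) / n + z[j] * b[j]
                bn = _soft(rho, lam) / z[j]
                d = bn - b[j]
                if d != 0.0:
                    r -= d * xj
                    b[j] = bn
                    ad = abs(d)
                    if ad > max_delta:
                        max_delta = ad
            if trace is not None:
                trace.append(
                    float(0.5 * np.mean(r**2) + lam * np.abs(b).sum())
                )
            if max_delta <= tol:
                break
        g = np.abs(Xw.T @ r) / n
        viol = (g > lam + kkt_eps) & ~active & (z > 0)
        if not viol.any():
            return total_sweeps, True
        active |= viol
    return total_sweeps, False


def fit_lasso(
    X,
    y,
    lam: float,
    standardize: bool = True,
    tol: float = 1e-10,
    max_sweeps: int = 2000,
    warm_start: np.ndarray | None = None,
    trace: bool = False,
) -> LassoFit:
    """Solve one L1 problem at penalty ``lam``.

    Returns coefficients on the original predictor scale; entries that are
    exactly zero are outside the selected support. ``trace=True`` records
    the objective after every coordinate sweep (it is non-increasing).
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    X = _as_matrix(X)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    y = _as_target(y, n)
    Xw, xm, xs, z = _working_scale(X, standardize)
    yc = y - y.mean()
    b = np.zeros(X.shape[1]) if warm_start is None else np.asarray(warm_start, float).copy()
    tr: list[float] | None = [] if trace else None
    sweeps, ok = _cd_solve(Xw, yc, z, lam, b, tol, max_sweeps, tr)
    coef = b / xs
    intercept = float(y.mean() - coef @ xm)
    return LassoFit(
        intercept=intercept,
        coef=coef,
        lam=float(lam),
        n_sweeps=sweeps,
        converged=ok,
        objective_trace=tr or [],
    )


def kkt_max_violation(X, y, fit: LassoFit, standardize: bool = True) -> float:
    """Max KKT residual of a fit, on the working (penalised) scale.

    Zero at the optimum: active coordinates satisfy gradient = lam*sign(b),
    inactive ones |gradient| <= lam.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    y = _as_target(y, n)
    Xw, _, xs, z = _working_scale(X, standardize)
    b = fit.coef * xs
    g = Xw.T @ (y - y.mean() - Xw @ b) / n
    active = b != 0.0
    v_active = np.abs(g[active] - fit.lam * np.sign(b[active]))
    v_inactive = np.clip(np.abs(g[~active & (z > 0)]) - fit.lam, 0.0, None)
    out = 0.0
    if v_active.size:
        out = max(out, float(v_active.max()))
    if v_inactive.size:
        out = max(out, float(v_inactive.max()))
    return out


def lasso_path(
    X,
    y,
    lambdas,
    standardize: bool = True,
    tol: float = 1e-8,
    max_sweeps: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started fits along a decreasing lambda grid.

    Returns (intercepts of shape (L,), coefficients of shape (L, p)) on the
    original scale.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.ndim != 1 or len(lambdas) == 0:
        raise ValueError("lambdas must be a non-empty 1-d sequence")
    if len(lambdas) > 1 and not np.all(np.diff(lambdas) < 0):
        raise ValueError("lambda grid must be strictly decreasing")
    X = _as_matrix(X)
    n, p = X.shape
    y = _as_target(y, n)
    Xw, xm, xs, z = _working_scale(X, standardize)
    yc = y - y.mean()
    b = np.zeros(p)
    coefs = np.empty((len(lambdas), p))
    intercepts = np.empty(len(lambdas))
    for k, lam in enumerate(lambdas):
        _cd_solve(Xw, yc, z, float(lam), b, tol, max_sweeps)
        coefs[k] = b / xs
        intercepts[k] = y.mean() - coefs[k] @ xm
    return intercepts, coefs


@dataclass
class CVResult:
    """Cross-validation curve and the selected penalty."""

    lambda_selected: float
    lambdas: np.ndarray
    mean_error: np.ndarray  # mean over folds of held-out MSE, per lambda
    se_error: np.ndarray  # standard error over folds
    lambda_rule: str
    n_folds: int
    seed: int

    @property
    def index_selected(self) -> int:
        return int(np.argmin(np.abs(self.lambdas - self.lambda_selected)))


def cv_lasso(
    X,
    y,
    lambdas=None,
    n_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    lambda_rule: str = "min",
    tol: float = 1e-5,
) -> CVResult:
    """K-fold cross-validation over a lambda grid.

    Folds are a seeded random partition into near-equal parts. ``min``
    selects the lambda minimising the mean held-out MSE; ``1se`` the
    largest lambda whose mean error is within one standard error of that
    minimum.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    y = _as_target(y, n)
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to cross-validate")
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if n < n_folds:
        raise ValueError("need at least n_folds samples")
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    if lambdas is None:
        lambdas = default_lambda_grid(X, y, standardize=standardize)
    lambdas = np.asarray(lambdas, dtype=float)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)

    fold_mse = np.empty((n_folds, len(lambdas)))
    for k, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        intercepts, coefs = lasso_path(
            X[mask], y[mask], lambdas, standardize=standardize, tol=tol
        )
        pred = intercepts[:, None] + coefs @ X[test_idx].T  # (L, n_test)
        fold_mse[k] = np.mean((pred - y[test_idx][None, :]) ** 2, axis=1)

    mean_error = fold_mse.mean(axis=0)
    se_error = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean_error))
    if lambda_rule == "min":
        lam_sel = lambdas[i_min]
    else:
        cutoff = mean_error[i_min] + se_error[i_min]
        ok = np.flatnonzero(mean_error <= cutoff)
        lam_sel = lambdas[ok.min()]  # grid is decreasing: smallest index = largest lam
    return CVResult(
        lambda_selected=float(lam_sel),
        lambdas=lambdas,
        mean_error=mean_error,
        se_error=se_error,
        lambda_rule=lambda_rule,
        n_folds=n_folds,
        seed=seed,
    )
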