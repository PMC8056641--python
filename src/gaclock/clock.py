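"""Training and application of gestational-age clocks.

A GA clock is a sparse linear model: predicted GA (days) = intercept +
sum of coefficient * beta over the selected CpGs. Training is Lasso
(alpha = 1) with the penalty chosen by K-fold cross-validation on the
training samples; the conventional split is ~80% training, ~20% test.

:class:`GestationalAgeClock` is a scikit-learn estimator (``fit`` /
``predict`` / ``get_params``) over the in-package coordinate-descent
solver; the module-level functions (`train_clock`, `predict_ga`, ...) are
thin wrappers that speak the domain types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import lasso
from .io import BetaMatrix, ClockModel, SampleSheet, ValidationError
from .preprocess import impute_missing

__all__ = [
    "TrainConfig",
    "GestationalAgeClock",
    "split_train_test",
    "cross_validate_lambda",
    "train_clock",
    "predict_ga",
    "PredictionReport",
]


@dataclass
class TrainConfig:
    """Clock-training settings.

    ``alpha`` is the elastic-net mixing parameter, fixed at 1 (pure Lasso).
    The lambda grid defaults to ``n_lambda`` log-spaced values from
    lambda_max down to ``lambda_min_ratio * lambda_max``; ``lambda_rule``
    picks the CV-minimising lambda (``min``) or the largest lambda within
    one standard error of it (``1se``).
    """

    alpha: float = 1.0
    n_folds: int = 10
    lambda_grid: Sequence[float] | None = None
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    lambda_rule: str = "min"
    train_fraction: float = 0.8
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.alpha != 1.0:
            raise ValueError("only alpha=1 (Lasso) is supported")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if g.ndim != 1 or len(g) == 0 or (len(g) > 1 and not (np.diff(g) < 0).all()):
                raise ValueError("lambda_grid must be strictly decreasing")
            if (g <= 0).any():
                raise ValueError("lambda_grid must be positive")


def split_train_test(
    samples: Sequence[str], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded random split into disjoint, exhaustive train/test id lists."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    samples = list(samples)
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return train, test


def cross_validate_lambda(X, y, cfg: TrainConfig) -> lasso.CVResult:
    """K-fold CV of the penalty per the training config."""
    lambdas = cfg.lambda_grid
    if lambdas is None:
        lambdas = lasso.default_lambda_grid(
            X, y, n_lambda=cfg.n_lambda, min_ratio=cfg.lambda_min_ratio,
            standardize=cfg.standardize,
        )
    return lasso.cv_lasso(
        X,
        y,
        lambdas=lambdas,
        n_folds=cfg.n_folds,
        seed=cfg.seed,
        standardize=cfg.standardize,
        lambda_rule=cfg.lambda_rule,
    )


class GestationalAgeClock(RegressorMixin, BaseEstimator):
    """Lasso gestational-age clock with cross-validated penalty.

    Parameters
    ----------
    lam : float, optional
        Fixed penalty; when None (default) it is chosen by ``n_folds``-fold
        cross-validation on the training data.
    n_folds, lambda_rule, n_lambda, lambda_min_ratio, standardize
        See :class:`TrainConfig`.
    random_state : int
        Seeds the CV fold assignment.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
        Dense coefficients; the clock's CpGs are the non-zero entries.
    lambda_ : float
        The penalty used for the final fit.
    cv_result_ : CVResult or None
    training_medians_ : pandas.Series
        Per-probe training beta medians for the selected CpGs (imputation
        fallback at prediction time).
    feature_names_in_ : ndarray of probe ids (when fitted on a DataFrame)
    """

    def __init__(
        self,
        lam: float | None = None,
        n_folds: int = 10,
        lambda_rule: str = "min",
        n_lambda: int = 100,
        lambda_min_ratio: float = 1e-3,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.lam = lam
        self.n_folds = n_folds
        self.lambda_rule = lambda_rule
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            n_folds=self.n_folds,
            lambda_rule=self.lambda_rule,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            seed=self.random_state,
            standardize=self.standardize,
        )

    def fit(self, X, y):
        """Fit on samples x probes betas (DataFrame with probe columns, or array)."""
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            self.feature_names_in_ = np.asarray(
                [f"x{j}" for j in range(Xv.shape[1])], dtype=object
            )
        y = np.asarray(y, dtype=float).ravel()
        if np.isnan(Xv).any():
            med = np.nanmedian(Xv, axis=0)
            if np.isnan(med).any():
                bad = self.feature_names_in_[np.isnan(med)]
                raise ValidationError(
                    f"features with no observed values: {bad[:10].tolist()}"
                )
            ii, jj = np.nonzero(np.isnan(Xv))
            Xv = Xv.copy()
            Xv[ii, jj] = med[jj]
        self.n_features_in_ = Xv.shape[1]

        if self.lam is None:
            self.cv_result_ = cross_validate_lambda(Xv, y, self._config())
            self.lambda_ = self.cv_result_.lambda_selected
        else:
            self.cv_result_ = None
            self.lambda_ = float(self.lam)
        fit = lasso.fit_lasso(Xv, y, self.lambda_, standardize=self.standardize)
        self.intercept_ = fit.intercept
        self.coef_ = fit.coef
        support = fit.support()
        self.selected_probes_ = [str(self.feature_names_in_[j]) for j in support]
        self.training_medians_ = pd.Series(
            np.median(Xv[:, support], axis=0), index=self.selected_probes_, dtype=float
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            series = pd.Series(self.coef_, index=self.feature_names_in_)
            active = series[series != 0.0]
            cols = X.reindex(columns=active.index)
            vals = cols.to_numpy(dtype=float)
            if np.isnan(vals).any():
                med = np.nanmedian(vals, axis=0)
                fallback = self.training_medians_.reindex(active.index).to_numpy()
                med = np.where(np.isnan(med), fallback, med)
                ii, jj = np.nonzero(np.isnan(vals))
                vals[ii, jj] = med[jj]
            return self.intercept_ + vals @ active.to_numpy()
        Xv = np.asarray(X, dtype=float)
        if Xv.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch; pass a DataFrame to align by probe id")
        if np.isnan(Xv).any():
            med = np.nanmedian(Xv, axis=0)
            fallback = np.full(self.n_features_in_, np.nan)
            names = list(self.feature_names_in_)
            for p, m in self.training_medians_.items():
                fallback[names.index(p)] = m
            med = np.where(np.isnan(med), fallback, med)
            ii, jj = np.nonzero(np.isnan(Xv))
            Xv = Xv.copy()
            Xv[ii, jj] = med[jj]
        return self.intercept_ + Xv @ self.coef_

    def to_clock_model(self) -> ClockModel:
        check_is_fitted(self, "coef_")
        coefs = {
            p: float(self.coef_[j])
            for j, p in enumerate(self.feature_names_in_)
            if self.coef_[j] != 0.0
        }
        return ClockModel(
            intercept=float(self.intercept_),
            coefficients=coefs,
            alpha=1.0,
            lam=float(self.lambda_),
            n_folds=self.n_folds if self.lam is None else None,
            seed=self.random_state,
            training_medians={p: float(self.training_medians_[p]) for p in coefs},
        )


def train_clock(
    bm: BetaMatrix,
    sheet: SampleSheet,
    cfg: TrainConfig | None = None,
    ga_source: str = "ultrasound",
) -> ClockModel:
    """Impute, cross-validate the penalty, and fit the final clock.

    Trains on the samples present in both the beta matrix and the sample
    sheet, against the requested GA source. ``ga_source='etd'`` requires
    every training sample to carry an ETD-derived GA (i.e. ART samples run
    through ``annotate_etd`` first).
    """
    cfg = cfg or TrainConfig()
    ids = [s for s in bm.sample_ids if s in set(sheet.sample_ids)]
    if not ids:
        raise ValidationError("no samples shared between beta matrix and sample sheet")
    ga = sheet.ga(ga_source).reindex(ids)
    missing = ga.index[ga.isna()].tolist()
    if missing:
        raise ValidationError(
            f"samples without {ga_source} GA: {missing[:10]}"
        )
    X = impute_missing(bm).to_samples_by_probes().loc[ids]
    est = GestationalAgeClock(
        n_folds=cfg.n_folds,
        lambda_rule=cfg.lambda_rule,
        n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio,
        standardize=cfg.standardize,
        random_state=cfg.seed,
    )
    if cfg.lambda_grid is not None:
        cv = lasso.cv_lasso(
            X.to_numpy(float), ga.to_numpy(), lambdas=np.asarray(cfg.lambda_grid, float),
            n_folds=cfg.n_folds, seed=cfg.seed, standardize=cfg.standardize,
            lambda_rule=cfg.lambda_rule,
        )
        est.set_params(lam=cv.lambda_selected)
        est.fit(X, ga.to_numpy())
        est.cv_result_ = cv
    else:
        est.fit(X, ga.to_numpy())
    return est.to_clock_model()


@dataclass
class PredictionReport:
    """Bookkeeping of clock application to one dataset."""

    n_clock_probes: int
    n_absent: int
    absent_probe_ids: list[str]
    n_excluded: int
    excluded_probe_ids: list[str]


def predict_ga(
    bm: BetaMatrix, clock: ClockModel, with_report: bool = False
):
    """Apply a clock: intercept + sum(coefficient * beta) per sample.

    Clock CpGs absent from the matrix are imputed from the clock's training
    medians when available and excluded otherwise (as published clocks are
    applied when a platform lacks some of their CpGs). Missing cells of
    present CpGs are imputed from the dataset's per-probe median, falling
    back to the training median.
    """
    present = [p for p in clock.probe_ids if p in set(bm.probe_ids)]
    absent = [p for p in clock.probe_ids if p not in set(bm.probe_ids)]
    if clock.coefficients and not present:
        raise ValidationError("none of the clock's probes are present in the matrix")

    offset = 0.0
    excluded: list[str] = []
    for p in absent:
        if p in clock.training_medians:
            offset += clock.coefficients[p] * clock.training_medians[p]
        else:
            excluded.append(p)

    pred = np.full(len(bm.sample_ids), clock.intercept + offset)
    if present:
        vals = bm.values.loc[present].to_numpy(dtype=float)  # probes x samples
        if np.isnan(vals).any():
            med = np.nanmedian(vals, axis=1)
            fallback = np.array(
                [clock.training_medians.get(p, np.nan) for p in present]
            )
            med = np.where(np.isnan(med), fallback, med)
            if (np.isnan(med) & np.isnan(vals).all(axis=1)).any():
                bad = [p for p, m in zip(present, med) if np.isnan(m)]
                raise ValidationError(
                    f"clock probes with no data and no training median: {bad[:10]}"
                )
            ii, jj = np.nonzero(np.isnan(vals))
            vals[ii, jj] = med[ii]
        coef = np.array([clock.coefficients[p] for p in present])
        pred = pred + coef @ vals
    predictions = pd.Series(pred, index=bm.sample_ids, name="predicted_ga_days")
    if not with_report:
        return predictions
    report = PredictionReport(
        n_clock_probes=len(clock),
        n_absent=len(absent),
        absent_probe_ids=absent,
        n_excluded=len(excluded),
        excluded_probe_ids=excluded,
    )
    return predictions, report
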