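"""Clock evaluation: robust R^2 / SE / MAD, and paired-bootstrap comparison.

Predicted GA is regressed on clinically estimated GA with MM-type robust
regression. Precision is the proportion of variance explained (a robust
R^2 computed with the fit's final bisquare weights), SE is the robust
residual scale of the fit (days), and accuracy is the median absolute
deviation between observed and predicted GA in days — a plain median of
absolute errors, with no Gaussian consistency factor.

Two prediction sets for the same individuals are compared by a paired
bootstrap: each replicate resamples individuals once (with replacement)
and evaluates both prediction sets on that same resample, so the
difference in each metric is free of between-resample noise; prediction
models are never refit. 95% confidence intervals are empirical percentile
intervals of the replicate differences, and a difference is called
significant when its interval excludes zero.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .robust import RobustFit, mm_robust_fit

__all__ = ["EvalReport", "BootstrapComparison", "compute_metrics", "bootstrap_compare"]

_METRICS = ("r2", "se", "mad")


@dataclass
class EvalReport:
    """Precision/accuracy of one (observed, predicted) pairing."""

    r2: float
    se: float
    mad_days: float
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _weighted_r2(pred: np.ndarray, residuals: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    if sw <= 0:
        return 0.0
    mean_w = (w @ pred) / sw
    tot = w @ (pred - mean_w) ** 2
    if tot <= 0:
        return 1.0
    r2 = 1.0 - (w @ residuals**2) / tot
    return float(min(max(r2, 0.0), 1.0))


def compute_metrics(
    obs, pred, seed: int = 0, r2_method: str = "weighted",
    fit: RobustFit | None = None,
) -> EvalReport:
    """Evaluate predictions against clinical GA.

    ``r2_method='weighted'`` uses the robust weighted-variance formulation;
    ``'correlation'`` the plain squared Pearson correlation. A pre-computed
    MM fit of pred on obs may be passed to avoid refitting.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have the same length")
    n = obs.shape[0]
    if n < 5:
        raise ValueError("need at least 5 observations")
    if fit is None:
        fit = mm_robust_fit(obs, pred, seed=seed)
    if r2_method == "weighted":
        residuals = pred - fit.predict(obs)
        r2 = _weighted_r2(pred, residuals, fit.weights)
    elif r2_method == "correlation":
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    else:
        raise ValueError("r2_method must be 'weighted' or 'correlation'")
    mad = float(np.median(np.abs(pred - obs)))
    return EvalReport(r2=r2, se=float(fit.scale), mad_days=mad, n=n)


@dataclass
class BootstrapComparison:
    """Paired differences (a minus b) in R^2, SE and MAD with percentile CIs."""

    delta_r2: float
    delta_se: float
    delta_mad: float
    ci_r2: tuple[float, float]
    ci_se: tuple[float, float]
    ci_mad: tuple[float, float]
    significant_r2: bool
    significant_se: bool
    significant_mad: bool
    n_boot: int
    n_dropped: int
    seed: int
    ci_level: float = 0.95

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("ci_r2", "ci_se", "ci_mad"):
            d[k] = list(d[k])
        return d


def bootstrap_compare(
    obs,
    pred_a,
    pred_b,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    r2_method: str = "weighted",
) -> BootstrapComparison:
    """Compare two prediction sets for the same individuals.

    Point differences are computed on the full sample; CIs come from
    ``n_boot`` paired resamples. Replicates where the robust fit fails
    (e.g. a resample with constant clinical GA) are dropped and counted; a
    warning is emitted if more than 5% drop.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred_a = np.asarray(pred_a, dtype=float).ravel()
    pred_b = np.asarray(pred_b, dtype=float).ravel()
    if not (obs.shape == pred_a.shape == pred_b.shape):
        raise ValueError("obs, pred_a, pred_b must be aligned on the same individuals")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    n = obs.shape[0]
    rng = np.random.default_rng(seed)

    def _deltas(o, a, b, fit_seed):
        ma = compute_metrics(o, a, seed=fit_seed, r2_method=r2_method)
        mb = compute_metrics(o, b, seed=fit_seed, r2_method=r2_method)
        return (ma.r2 - mb.r2, ma.se - mb.se, ma.mad_days - mb.mad_days)

    point = _deltas(obs, pred_a, pred_b, fit_seed=int(rng.integers(2**31)))

    reps = np.empty((n_boot, 3))
    n_ok = 0
    n_dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        fit_seed = int(rng.integers(2**31))
        try:
            reps[n_ok] = _deltas(obs[idx], pred_a[idx], pred_b[idx], fit_seed)
            n_ok += 1
        except (ValueError, np.linalg.LinAlgError):
            n_dropped += 1
    reps = reps[:n_ok]
    if n_ok == 0:
        raise ValueError("all bootstrap replicates failed")
    if n_dropped > 0.05 * n_boot:
        warnings.warn(
            f"{n_dropped}/{n_boot} bootstrap replicates dropped", stacklevel=2
        )
    lo_q = 100 * (1.0 - ci_level) / 2
    cis = [
        (float(np.percentile(reps[:, j], lo_q)),
         float(np.percentile(reps[:, j], 100 - lo_q)))
        for j in range(3)
    ]
    sig = [not (lo <= 0.0 <= hi) for lo, hi in cis]
    return BootstrapComparison(
        delta_r2=float(point[0]),
        delta_se=float(point[1]),
        delta_mad=float(point[2]),
        ci_r2=cis[0],
        ci_se=cis[1],
        ci_mad=cis[2],
        significant_r2=sig[0],
        significant_se=sig[1],
        significant_mad=sig[2],
        n_boot=n_boot,
        n_dropped=n_dropped,
        seed=seed,
        ci_level=ci_level,
    )
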