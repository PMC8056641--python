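"""Gestational-age acceleration (GAA) and its association with ART.

GAA is the residual of DNAm-predicted GA regressed (ordinary least
squares, with intercept) on clinically estimated GA: positive GAA means a
newborn looks epigenetically "older" than the clinical estimate. The
association between GAA and a binary grouping (ART vs non-ART, IVF vs
ICSI, fresh vs frozen) is tested by a logistic regression of the group
label on GAA, with the Wald p-value of the GAA coefficient.

The GAA regression is deliberately ordinary least squares — not the
MM-robust fit used for clock evaluation — keeping the two analyses'
conventions distinct.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["GAAResult", "compute_gaa", "test_gaa_association"]


def compute_gaa(pred, clinical):
    """OLS residuals of predicted GA on clinical GA (days).

    Residuals are orthogonal to the clinical GA and the constant vector,
    so they sum to zero and adding a constant to ``pred`` leaves them
    unchanged.
    """
    index = pred.index if isinstance(pred, pd.Series) else None
    pred = np.asarray(pred, dtype=float).ravel()
    clinical = np.asarray(clinical, dtype=float).ravel()
    if pred.shape != clinical.shape:
        raise ValueError("pred and clinical must be aligned")
    if pred.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(clinical) == 0:
        raise ValueError("clinical GA is constant; residuals are not defined")
    A = np.column_stack([np.ones_like(clinical), clinical])
    coef, *_ = np.linalg.lstsq(A, pred, rcond=None)
    resid = pred - A @ coef
    if index is not None:
        return pd.Series(resid, index=index, name="gaa_days")
    return resid


@dataclass
class GAAResult:
    """Logistic association between GAA and a binary group."""

    gaa_days: np.ndarray
    group: np.ndarray
    logit_coef: float  # log-odds of group membership per day of GAA
    p_value: float  # Wald p; NaN when not estimable (separation)
    n_per_group: dict[str, int]
    separation: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gaa_days"] = np.asarray(self.gaa_days).tolist()
        d["group"] = np.asarray(self.group).astype(int).tolist()
        return d


def test_gaa_association(gaa, group) -> GAAResult:
    """Logistic regression of the binary group on GAA.

    ``group`` is coerced to 0/1 (True = ART or the subgroup of interest).
    Perfect separation is flagged and the p-value reported as NaN rather
    than raising.
    """
    gaa = np.asarray(gaa, dtype=float).ravel()
    group = np.asarray(group).ravel()
    if group.dtype != bool:
        group = group.astype(bool)
    if gaa.shape != group.shape:
        raise ValueError("gaa and group must be aligned")
    n = gaa.shape[0]
    if n < 20:
        raise ValueError("need at least 20 observations")
    n1 = int(group.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be present")

    X = sm.add_constant(gaa)
    yv = group.astype(float)
    coef = np.nan
    p = np.nan
    separation = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(yv, X).fit(disp=0, maxiter=100)
        coef = float(res.params[1])
        p = float(res.pvalues[1])
        if not res.mle_retvals.get("converged", True) or not np.isfinite(p):
            separation = True
            p = np.nan
    except Exception:
        separation = True
    return GAAResult(
        gaa_days=gaa,
        group=group,
        logit_coef=coef,
        p_value=p,
        n_per_group={"group": n1, "reference": n - n1},
        separation=separation,
    )


test_gaa_association.__test__ = False  # a library function, not a pytest case
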