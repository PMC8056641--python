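"""Simulation experiments that characterise the method end to end.

Each experiment generates its own data from :mod:`gaclock.simulate` under a
caller-supplied seed, runs the relevant part of the pipeline, and measures
the outcome against the simulation truth. They back both the test suite
and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .clock import TrainConfig, predict_ga, split_train_test, train_clock
from .evaluation import bootstrap_compare, compute_metrics
from .gaa import compute_gaa, test_gaa_association
from .io import BetaMatrix, SampleSheet
from .simulate import SimConfig, simulate_cohort

__all__ = [
    "support_recovery_experiment",
    "mm_contamination_experiment",
    "bootstrap_coverage_experiment",
    "gaa_null_rejection_experiment",
    "gaa_power_experiment",
]


def _subset(bm: BetaMatrix, sheet: SampleSheet, ids: list[str]):
    recs = {r.sample_id: r for r in sheet}
    return BetaMatrix(bm.values[ids]), SampleSheet([recs[s] for s in ids])


def support_recovery_experiment(
    seed: int = 3,
    n_samples: int = 800,
    n_probes: int = 5000,
    n_active: int = 30,
    signal_fraction: float = 0.8,
) -> dict:
    """Train a clock on a strong-signal cohort; measure support recovery and
    held-out precision/accuracy."""
    cfg = SimConfig.for_signal_fraction(
        signal_fraction,
        n_samples=n_samples,
        n_probes=n_probes,
        n_active=n_active,
        seed=seed,
    )
    bm, sheet, truth = simulate_cohort(cfg)
    train_ids, test_ids = split_train_test(list(bm.sample_ids), 0.8, seed)
    clock = train_clock(*_subset(bm, sheet, train_ids), TrainConfig(seed=seed))
    active = set(truth.active_probe_ids)
    recovered = len(active & set(clock.probe_ids)) / len(active)
    bm_test, sheet_test = _subset(bm, sheet, test_ids)
    pred = predict_ga(bm_test, clock)
    rep = compute_metrics(
        sheet_test.ga("ultrasound").to_numpy(), pred.to_numpy(), seed=seed
    )
    return {
        "signal_fraction": cfg.signal_fraction(),
        "support_recovery": recovered,
        "n_selected": len(clock),
        "test_r2": rep.r2,
        "test_se_days": rep.se,
        "test_mad_days": rep.mad_days,
        "n_train": len(train_ids),
        "n_test": len(test_ids),
    }


def mm_contamination_experiment(
    seed: int = 19,
    n: int = 500,
    outlier_fraction: float = 0.2,
    outlier_shift: float = 50.0,
    slope: float = 1.0,
    noise_sd: float = 3.0,
) -> dict:
    """MM vs least-squares slope under gross one-sided outliers."""
    from .robust import mm_robust_fit

    rng = np.random.default_rng(seed)
    x = rng.normal(281.0, 13.0, n)
    y = slope * x + rng.normal(0.0, noise_sd, n)
    y_cont = y.copy()
    k = int(round(outlier_fraction * n))
    # contamination at the highest x values, so it biases the LS slope
    y_cont[np.argsort(x)[-k:]] += outlier_shift
    mm = mm_robust_fit(x, y_cont, seed=seed)
    ls = np.polyfit(x, y_cont, 1)
    mm_clean = mm_robust_fit(x, y, seed=seed)
    ls_clean = np.polyfit(x, y, 1)
    return {
        "true_slope": slope,
        "mm_slope": mm.slope,
        "ls_slope": float(ls[0]),
        "mm_rel_error_pct": 100.0 * abs(mm.slope - slope) / abs(slope),
        "ls_rel_error_pct": 100.0 * abs(ls[0] - slope) / abs(slope),
        "mm_clean_slope": mm_clean.slope,
        "ls_clean_slope": float(ls_clean[0]),
        "n": n,
    }


def bootstrap_coverage_experiment(
    seed: int = 23,
    n_outer: int = 200,
    n_boot: int = 300,
    n: int = 150,
    error_sd: float = 3.0,
) -> dict:
    """Null coverage of the paired-bootstrap ΔMAD interval.

    Both prediction sets have the same error distribution, so the 95%
    percentile CI for their MAD difference should contain 0 in ~95% of
    independent replications.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for k in range(n_outer):
        x = rng.normal(281.0, 13.0, n)
        pred_a = x + rng.normal(0.0, error_sd, n)
        pred_b = x + rng.normal(0.0, error_sd, n)
        bc = bootstrap_compare(
            x, pred_a, pred_b, n_boot=n_boot, seed=int(rng.integers(2**31))
        )
        if bc.ci_mad[0] <= 0.0 <= bc.ci_mad[1]:
            covered += 1
    return {
        "coverage_pct": 100.0 * covered / n_outer,
        "n_outer": n_outer,
        "n_boot": n_boot,
        "n": n,
    }


def _base_gaa_config(seed: int, gaa_shift_days: float, n_samples: int) -> SimConfig:
    return SimConfig.for_signal_fraction(
        0.8,
        n_samples=n_samples,
        n_probes=2000,
        n_active=25,
        seed=seed,
        gaa_shift_days=gaa_shift_days,
    )


def _gaa_pvalue(bm, sheet, clock) -> float:
    pred = predict_ga(bm, clock)
    ga = sheet.ga("ultrasound").reindex(pred.index)
    gaa = compute_gaa(pred, ga)
    res = test_gaa_association(gaa.to_numpy(), sheet.art_mask().to_numpy())
    return res.p_value


def gaa_null_rejection_experiment(
    seed: int = 31,
    n_cohorts: int = 500,
    cohort_n: int = 300,
    train_n: int = 600,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the GAA-vs-ART logistic test under the simulator null.

    One clock is trained on a large null cohort; each further null cohort
    (same probe structure, fresh sampling noise) is predicted with it and
    tested for a GAA-ART association.
    """
    cfg = _base_gaa_config(seed, gaa_shift_days=0.0, n_samples=train_n)
    bm, sheet, _ = simulate_cohort(cfg, replicate=0)
    clock = train_clock(bm, sheet, TrainConfig(seed=seed))
    cfg_null = replace(cfg, n_samples=cohort_n)
    pvals = np.array(
        [
            _gaa_pvalue(*simulate_cohort(cfg_null, replicate=r)[:2], clock)
            for r in range(1, n_cohorts + 1)
        ]
    )
    ok = np.isfinite(pvals)
    return {
        "rejection_rate_pct": 100.0 * float(np.mean(pvals[ok] < alpha)),
        "n_cohorts": int(ok.sum()),
        "alpha": alpha,
        "p_values": pvals,
    }


def gaa_power_experiment(
    seed: int = 37,
    n_runs: int = 40,
    cohort_n: int = 800,
    shift_days: float = 5.0,
    p_threshold: float = 0.01,
) -> dict:
    """Power of the GAA test when ART samples carry an injected shift."""
    cfg = _base_gaa_config(seed, gaa_shift_days=0.0, n_samples=600)
    bm, sheet, _ = simulate_cohort(cfg, replicate=0)
    clock = train_clock(bm, sheet, TrainConfig(seed=seed))
    cfg_shift = replace(cfg, gaa_shift_days=shift_days, n_samples=cohort_n)
    pvals = np.array(
        [
            _gaa_pvalue(*simulate_cohort(cfg_shift, replicate=r)[:2], clock)
            for r in range(1, n_runs + 1)
        ]
    )
    ok = np.isfinite(pvals)
    return {
        "power_pct": 100.0 * float(np.mean(pvals[ok] < p_threshold)),
        "n_runs": int(ok.sum()),
        "p_threshold": p_threshold,
        "shift_days": shift_days,
    }
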