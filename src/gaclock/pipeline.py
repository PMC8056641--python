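"""End-to-end demo workflow on synthetic data.

Mirrors the study design: simulate a cohort with ART metadata, run probe
QC, split the non-ART samples ~80/20, train three clocks (ultrasound-GA
clock on non-ART training samples; a platform-overlap clock on the probes
shared with the older array; an ETD clock trained on ART samples against
their embryo-transfer-date GA), apply all three to the held-out non-ART
test set, evaluate with MM-robust metrics, compare clocks by paired
bootstrap, and test GAA against ART status on the full cohort.

Every JSON report embeds the config hash and seed, so two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .clock import TrainConfig, predict_ga, split_train_test, train_clock
from .etd import annotate_etd
from .evaluation import bootstrap_compare, compute_metrics
from .gaa import compute_gaa, test_gaa_association
from .io import (
    SampleSheet,
    write_beta_matrix,
    write_clock_file,
    write_sample_sheet,
)
from .preprocess import filter_probes, impute_missing, restrict_to_platform
from .robust import mm_robust_fit
from .simulate import SimConfig, make_probe_annotation, simulate_cohort

log = logging.getLogger("gaclock")

DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_samples": 600,
        "n_probes": 4000,
        "n_active": 30,
        "signal_fraction": 0.8,
        "noise_sd": 0.5,
        "missing_rate": 0.01,
        "seed": 42,
    },
    "annotation": {
        "frac_450k": 0.6,
        "frac_cross_reactive": 0.05,
        "frac_snp": 0.02,
        "frac_non_autosomal": 0.03,
    },
    "train": {"n_folds": 10, "train_fraction": 0.8, "lambda_rule": "min", "seed": 0},
    "evaluate": {"n_boot": 300, "seed": 0},
    "save_data": False,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sim_config(section: dict) -> SimConfig:
    section = dict(section)
    target = section.pop("signal_fraction", None)
    if target is not None:
        return SimConfig.for_signal_fraction(target, **section)
    return SimConfig(**section)


def validate_config(config: dict) -> dict:
    """Merge over defaults and fail fast on invalid settings."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    tf = cfg["train"].get("train_fraction", 0.8)
    if not 0.0 < tf < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {tf}")
    _sim_config(cfg["simulate"])  # raises on bad simulation settings
    if cfg["evaluate"].get("n_boot", 1) < 1:
        raise ValueError("n_boot must be positive")
    return cfg


def run_pipeline(config: dict | None, outdir: str | Path) -> dict:
    """Run the full synthetic workflow; write reports under ``outdir``."""
    cfg = validate_config(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": _config_hash(cfg), "seed": cfg["simulate"]["seed"]}

    def _dump(name: str, payload: dict) -> None:
        with open(outdir / name, "w") as fh:
            json.dump({**meta, **payload}, fh, indent=2, sort_keys=True)

    sim_cfg = _sim_config(cfg["simulate"])
    log.info("simulate: n=%d p=%d", sim_cfg.n_samples, sim_cfg.n_probes)
    bm, sheet, truth = simulate_cohort(sim_cfg)
    sheet, etd_report = annotate_etd(sheet)
    log.info("etd: annotated %d ART records", etd_report.n_annotated)
    if cfg.get("save_data"):
        write_beta_matrix(bm, outdir / "beta.tsv")
        write_sample_sheet(sheet, outdir / "samples.csv")

    ann = make_probe_annotation(
        list(bm.probe_ids), seed=sim_cfg.seed, **cfg["annotation"]
    )
    bm_f, filt = filter_probes(bm, ann, autosomal_only=True)
    log.info("filter: %d -> %d probes", filt.n_input, filt.n_output)
    _dump("filter_report.json", {"filter": filt.to_dict(),
                                 "etd": {"n_annotated": etd_report.n_annotated,
                                         "failures": len(etd_report.failures)}})

    tr = cfg["train"]
    train_cfg = TrainConfig(
        n_folds=tr["n_folds"],
        lambda_rule=tr["lambda_rule"],
        train_fraction=tr["train_fraction"],
        seed=tr["seed"],
    )
    art_mask = sheet.art_mask()
    non_art_ids = [s for s in bm_f.sample_ids if not art_mask[s]]
    art_ids = [s for s in bm_f.sample_ids if art_mask[s]]
    train_ids, test_ids = split_train_test(
        non_art_ids, train_cfg.train_fraction, train_cfg.seed
    )
    sub = {r.sample_id: r for r in sheet}
    sheet_train = SampleSheet([sub[s] for s in train_ids])
    sheet_art = SampleSheet([sub[s] for s in art_ids])

    bm_imp = impute_missing(bm_f)
    bm_train = _select_samples(bm_imp, train_ids)
    bm_test = _select_samples(bm_imp, test_ids)

    log.info("train: main clock on %d non-ART samples", len(train_ids))
    clock_main = train_clock(bm_train, sheet_train, train_cfg)
    platform = ann.index[ann["on_450k"]]
    log.info("train: overlap clock on %d shared probes", len(platform))
    clock_overlap = train_clock(
        restrict_to_platform(bm_train, platform), sheet_train, train_cfg
    )
    log.info("train: ETD clock on %d ART samples", len(art_ids))
    bm_art = _select_samples(bm_imp, art_ids)
    clock_etd = train_clock(bm_art, sheet_art, train_cfg, ga_source="etd")

    clocks = {"main": clock_main, "overlap": clock_overlap, "etd": clock_etd}
    for name, c in clocks.items():
        write_clock_file(c, outdir / f"clock_{name}.csv")
        _dump(
            f"clock_{name}_meta.json",
            {"n_cpgs": len(c), "lambda": c.lam, "alpha": c.alpha,
             "n_folds": c.n_folds},
        )

    ga_test = sheet.ga("ultrasound").reindex(test_ids)
    preds = {name: predict_ga(bm_test, c) for name, c in clocks.items()}
    ev = cfg["evaluate"]
    reports = {
        name: compute_metrics(ga_test, p, seed=ev["seed"]).to_dict()
        for name, p in preds.items()
    }
    log.info("evaluate: %s", {k: round(v["r2"], 3) for k, v in reports.items()})
    _dump("evaluation.json", {"test_n": len(test_ids), "metrics": reports})

    comparisons = {}
    for other in ("overlap", "etd"):
        comparisons[f"main_vs_{other}"] = bootstrap_compare(
            ga_test, preds["main"], preds[other],
            n_boot=ev["n_boot"], seed=ev["seed"],
        ).to_dict()
    _dump("comparisons.json", {"comparisons": comparisons})

    # GAA on the full cohort with the main clock
    ga_all = sheet.ga("ultrasound").reindex(bm_imp.sample_ids)
    pred_all = predict_ga(bm_imp, clock_main)
    gaa = compute_gaa(pred_all, ga_all)
    art = art_mask.reindex(bm_imp.sample_ids).to_numpy()
    assoc = test_gaa_association(gaa, art)
    _dump(
        "gaa.json",
        {
            "logit_coef": assoc.logit_coef,
            "p_value": assoc.p_value,
            "n_per_group": assoc.n_per_group,
            "separation": assoc.separation,
        },
    )

    try:
        from .plots import plot_gaa, plot_predicted_vs_clinical

        fit = mm_robust_fit(ga_test.to_numpy(), preds["main"].to_numpy(),
                            seed=ev["seed"])
        plot_predicted_vs_clinical(ga_test, preds["main"], fit,
                                   outdir / "predicted_vs_clinical.png")
        plot_gaa(ga_all, gaa, art, outdir / "gaa.png")
    except Exception as e:  # plotting must never sink the run
        log.warning("plotting failed: %s", e)

    summary = {
        "n_samples": sim_cfg.n_samples,
        "n_probes_after_qc": filt.n_output,
        "clocks": {k: len(v) for k, v in clocks.items()},
        "metrics": reports,
        "gaa_p_value": assoc.p_value,
        "support_recovery": _support_recovery(clock_main, truth),
    }
    _dump("summary.json", summary)
    return summary


def _select_samples(bm, sample_ids):
    from .io import BetaMatrix

    dp = None if bm.detection_p is None else bm.detection_p[sample_ids]
    return BetaMatrix(bm.values[sample_ids], dp)


def _support_recovery(clock, truth) -> float:
    active = set(truth.active_probe_ids)
    if not active:
        return float("nan")
    return len(active & set(clock.probe_ids)) / len(active)
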