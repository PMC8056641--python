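"""Synthetic cord-blood methylation cohorts with a known GA signal.

The generator emulates the statistical structure a gestational-age clock
assumes: a sparse set of CpGs whose methylation drifts linearly with
gestational age on the logit(beta) scale, embedded in a large background of
uninformative probes. Modelling on the logit scale keeps every beta value
strictly inside (0, 1) after the inverse-logit transform, while the clock is
fitted on the beta scale, as clocks are in practice.

Gestational age is drawn from a truncated normal (defaults: mean 281,
sd 13, range 216-301 days, the term-centred distribution of a birth
cohort). ART samples receive procedure metadata and laboratory dates that
are internally consistent, so the ETD rules recover the true GA exactly.
A gestational-age-acceleration effect can be injected for ART samples by
shifting the methylation-implied GA (``gaa_shift_days``) while the clinical
GA stays at truth — matching GAA's definition as a DNAm-vs-clinical
discrepancy.

Probe structure (which CpGs are active, their slopes and baselines) is a
function of ``seed`` alone; per-sample randomness additionally depends on
the ``replicate`` index, so one clock trained on replicate 0 can be applied
to many independent cohorts drawn from the same population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .io import BetaMatrix, SampleRecord, SampleSheet, make_annotation_frame

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "make_probe_annotation"]


@dataclass
class SimConfig:
    """Configuration of one simulated cohort.

    ``effect_sd`` is the magnitude of the per-CpG slope in logit-beta units
    per day of gestation (each active CpG gets slope +-effect_sd with random
    sign); ``noise_sd`` the per-probe logit-scale noise. The implied
    proportion of GA variance recoverable from the active probes is
    :meth:`signal_fraction`.
    """

    n_samples: int = 400
    n_probes: int = 2000
    n_active: int = 30
    effect_sd: float = 0.015
    noise_sd: float = 0.5
    baseline_sd: float = 1.0
    ga_mean_days: float = 281.0
    ga_sd_days: float = 13.0
    ga_min: float = 216.0
    ga_max: float = 301.0
    art_fraction: float = 0.45
    icsi_fraction: float = 0.5
    frozen_fraction: float = 0.25
    gaa_shift_days: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("art_fraction", "icsi_fraction", "frozen_fraction", "missing_rate"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if self.n_active > self.n_probes:
            raise ValueError("n_active cannot exceed n_probes")
        if not self.ga_min < self.ga_max:
            raise ValueError("ga_min must be below ga_max")

    def ga_variance(self) -> float:
        """Variance of the truncated-normal GA distribution, days^2."""
        if self.ga_sd_days == 0:
            return 0.0
        a = (self.ga_min - self.ga_mean_days) / self.ga_sd_days
        b = (self.ga_max - self.ga_mean_days) / self.ga_sd_days
        return float(truncnorm(a, b, loc=self.ga_mean_days, scale=self.ga_sd_days).var())

    def signal_fraction(self) -> float:
        """R^2 between GA and the optimal linear read-out of active-probe logits."""
        if self.n_active == 0:
            return 0.0
        if self.noise_sd == 0:
            return 1.0
        snr = self.ga_variance() * self.n_active * self.effect_sd**2 / self.noise_sd**2
        return snr / (1.0 + snr)

    @classmethod
    def for_signal_fraction(cls, target: float, **kwargs) -> "SimConfig":
        """Construct a config whose effect_sd realises the target signal fraction."""
        if not 0.0 < target < 1.0:
            raise ValueError("target signal fraction must be in (0, 1)")
        cfg = cls(**kwargs)
        if cfg.n_active == 0:
            raise ValueError("need n_active > 0 to carry signal")
        snr = target / (1.0 - target)
        effect_sd = float(
            np.sqrt(snr * cfg.noise_sd**2 / (cfg.n_active * cfg.ga_variance()))
        )
        return replace(cfg, effect_sd=effect_sd)


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort (oracle for recovery tests)."""

    active_probe_ids: list[str]
    true_effects: dict[str, float]
    true_ga_days: pd.Series
    true_gaa_shift: float
    baselines: dict[str, float] = field(default_factory=dict)


def _draw_ga(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if cfg.ga_sd_days == 0:
        return np.full(n, round(cfg.ga_mean_days))
    a = (cfg.ga_min - cfg.ga_mean_days) / cfg.ga_sd_days
    b = (cfg.ga_max - cfg.ga_mean_days) / cfg.ga_sd_days
    ga = truncnorm.rvs(
        a, b, loc=cfg.ga_mean_days, scale=cfg.ga_sd_days, size=n, random_state=rng
    )
    return np.clip(np.round(ga), cfg.ga_min, cfg.ga_max).astype(int)


def _art_dates(
    rec_ga: int, frozen: bool, birth: date, rng: np.random.Generator
) -> dict:
    """Laboratory dates consistent with the ETD rules and the true GA."""
    if frozen:
        k = int(rng.integers(2, 7))  # days in culture before freezing
        storage = int(rng.integers(30, 181))
        insertion = birth - timedelta(days=int(rec_ga) - 14 - k)
        freeze = insertion - timedelta(days=storage)
        retrieval = freeze - timedelta(days=k)
        return {
            "egg_retrieval_date": retrieval,
            "freeze_date": freeze,
            "embryo_insertion_date": insertion,
        }
    retrieval = birth - timedelta(days=int(rec_ga) - 14)
    insertion = retrieval + timedelta(days=2)
    out = {"egg_retrieval_date": retrieval, "embryo_insertion_date": insertion}
    if rng.random() < 0.3:
        # retrieval date unrecorded; the insertion-minus-two-days rule applies
        out["egg_retrieval_date"] = None
    return out


def simulate_cohort(
    cfg: SimConfig, replicate: int = 0
) -> tuple[BetaMatrix, SampleSheet, SimTruth]:
    """Simulate one cohort: beta matrix, sample sheet and ground truth."""
    if cfg.ga_sd_days == 0 and cfg.n_active > 0:
        warnings.warn(
            "ga_sd_days is 0: active probes carry no GA signal to recover",
            stacklevel=2,
        )
    rng_struct = np.random.default_rng([cfg.seed % (2**31), 101])
    rng = np.random.default_rng([cfg.seed % (2**31), 202, replicate % (2**31)])

    p, n = cfg.n_probes, cfg.n_samples
    probe_ids = [f"cg{i:08d}" for i in range(p)]
    sample_ids = [f"S{replicate}_{j:05d}" for j in range(n)]

    # population structure (seed only)
    active_idx = np.sort(rng_struct.choice(p, size=cfg.n_active, replace=False))
    signs = rng_struct.choice([-1.0, 1.0], size=cfg.n_active)
    slopes = signs * cfg.effect_sd
    baselines = rng_struct.normal(0.0, cfg.baseline_sd, size=p)

    # per-sample draws
    ga = _draw_ga(cfg, rng, n)
    n_art = int(np.floor(cfg.art_fraction * n + 0.5))
    art = np.zeros(n, dtype=bool)
    art[rng.choice(n, size=n_art, replace=False)] = True
    art_pos = np.flatnonzero(art)
    icsi = np.zeros(n, dtype=bool)
    frozen = np.zeros(n, dtype=bool)
    if n_art:
        n_icsi = int(np.floor(cfg.icsi_fraction * n_art + 0.5))
        n_froz = int(np.floor(cfg.frozen_fraction * n_art + 0.5))
        icsi[rng.choice(art_pos, size=n_icsi, replace=False)] = True
        frozen[rng.choice(art_pos, size=n_froz, replace=False)] = True

    # methylation-implied GA carries the injected acceleration for ART
    ga_methyl = ga + cfg.gaa_shift_days * art
    logits = baselines[:, None] + rng.normal(0.0, cfg.noise_sd, size=(p, n))
    logits[active_idx] += slopes[:, None] * (ga_methyl - cfg.ga_mean_days)[None, :]
    betas = expit(logits)

    if cfg.missing_rate > 0:
        betas[rng.random(size=(p, n)) < cfg.missing_rate] = np.nan

    values = pd.DataFrame(betas, index=probe_ids, columns=sample_ids)
    bm = BetaMatrix(values)

    anchor = date(2010, 1, 1)
    records = []
    for j, sid in enumerate(sample_ids):
        birth = anchor + timedelta(days=int(rng.integers(0, 365)))
        if art[j]:
            dates = _art_dates(int(ga[j]), bool(frozen[j]), birth, rng)
            rec = SampleRecord(
                sample_id=sid,
                ga_ultrasound_days=int(ga[j]),
                art=True,
                procedure="ICSI" if icsi[j] else "IVF",
                embryo_state="frozen" if frozen[j] else "fresh",
                birth_date=birth,
                **dates,
            )
        else:
            rec = SampleRecord(
                sample_id=sid,
                ga_ultrasound_days=int(ga[j]),
                art=False,
                birth_date=birth,
            )
        records.append(rec)
    sheet = SampleSheet(records)

    active_ids = [probe_ids[i] for i in active_idx]
    truth = SimTruth(
        active_probe_ids=active_ids,
        true_effects={pid: float(s) for pid, s in zip(active_ids, slopes)},
        true_ga_days=pd.Series(ga, index=sample_ids, dtype=float, name="true_ga"),
        true_gaa_shift=float(cfg.gaa_shift_days),
        baselines={pid: float(b) for pid, b in zip(probe_ids, baselines)},
    )
    return bm, sheet, truth


def make_probe_annotation(
    probes: SimConfig | list[str],
    frac_450k: float = 1.0,
    frac_cross_reactive: float = 0.0,
    frac_snp: float = 0.0,
    frac_non_autosomal: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded probe-annotation fixture with exact flag counts.

    Each flag is assigned to exactly ``round(frac * n_probes)`` probes,
    sampled independently.
    """
    if isinstance(probes, SimConfig):
        probe_ids = [f"cg{i:08d}" for i in range(probes.n_probes)]
    else:
        probe_ids = list(probes)
    for name, v in (
        ("frac_450k", frac_450k),
        ("frac_cross_reactive", frac_cross_reactive),
        ("frac_snp", frac_snp),
        ("frac_non_autosomal", frac_non_autosomal),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    n = len(probe_ids)
    rng = np.random.default_rng([seed % (2**31), 303])

    def _flag(frac: float) -> np.ndarray:
        k = int(np.floor(frac * n + 0.5))
        out = np.zeros(n, dtype=bool)
        out[rng.choice(n, size=k, replace=False)] = True
        return out

    return make_annotation_frame(
        probe_ids,
        on_450k=_flag(frac_450k),
        cross_reactive=_flag(frac_cross_reactive),
        snp_overlap=_flag(frac_snp),
        autosomal=~_flag(frac_non_autosomal),
    )
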