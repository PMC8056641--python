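"""Domain types and file formats.

Beta matrices are stored probes-as-rows (the series-matrix convention used
when array data are distributed); clock arithmetic transposes internally.
Clock coefficient files follow the Horvath-style CSV layout with an
``(Intercept)`` sentinel row, so published clock files can be read directly.
Dates are ISO-8601 strings on disk; all gestational-age arithmetic is in
whole days.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ClockModel",
    "SampleRecord",
    "SampleSheet",
    "ValidationError",
    "make_annotation_frame",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_clock_file",
    "write_clock_file",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_list",
    "write_probe_list",
]

ANNOTATION_COLUMNS = ("on_450k", "cross_reactive", "snp_overlap", "autosomal")


class ValidationError(ValueError):
    """Raised when a domain object or input file violates its invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups[:10]}")


@dataclass
class BetaMatrix:
    """Methylation beta values, probes x samples, values in [0, 1].

    Parameters
    ----------
    values : pandas.DataFrame
        Probes as rows (index = probe ids), samples as columns. Missing
        values are NaN.
    detection_p : pandas.DataFrame, optional
        Detection p-values on the same probe/sample grid.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "probe_id"
        self.values.columns.name = None
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        if self.detection_p is not None:
            dp = self.detection_p.astype(float)
            dp.index.name = "probe_id"
            dp.columns.name = None
            if dp.shape != self.values.shape or not (
                dp.index.equals(self.values.index)
                and dp.columns.equals(self.values.columns)
            ):
                raise ValidationError(
                    "detection_p grid does not match beta matrix axes"
                )
            dpa = dp.to_numpy()
            with np.errstate(invalid="ignore"):
                if ((dpa < 0) | (dpa > 1)).any():
                    raise ValidationError("detection p-values outside [0, 1]")
            self.detection_p = dp

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_samples_by_probes(self) -> pd.DataFrame:
        """Return the n-samples x p-probes orientation used for model fits."""
        return self.values.T

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        dp = None
        if self.detection_p is not None:
            dp = self.detection_p.loc[probe_ids]
        return BetaMatrix(self.values.loc[probe_ids], dp)

    def equals(self, other: "BetaMatrix") -> bool:
        same = self.values.equals(other.values)
        if self.detection_p is None or other.detection_p is None:
            return same and (self.detection_p is None) == (other.detection_p is None)
        return same and self.detection_p.equals(other.detection_p)


def read_beta_matrix(
    path: str | Path,
    orientation: str = "probes_rows",
    detection_p_path: str | Path | None = None,
) -> BetaMatrix:
    """Read a TSV beta matrix.

    ``orientation="probes_rows"`` expects probe ids in the first column and
    sample ids in the header; ``"samples_rows"`` the transpose. Empty cells
    are read as missing.
    """
    if orientation not in ("probes_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples_rows":
        df = df.T
    dp = None
    if detection_p_path is not None:
        dp = pd.read_csv(detection_p_path, sep="\t", index_col=0, float_precision="round_trip")
        dp.index = dp.index.astype(str)
        dp.columns = dp.columns.astype(str)
        if orientation == "samples_rows":
            dp = dp.T
    return BetaMatrix(df, dp)


def write_beta_matrix(
    bm: BetaMatrix,
    path: str | Path,
    detection_p_path: str | Path | None = None,
) -> None:
    bm.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")
    if detection_p_path is not None and bm.detection_p is not None:
        bm.detection_p.to_csv(detection_p_path, sep="\t", index_label="probe_id", float_format="%.17g")


def make_annotation_frame(
    probe_ids: Sequence[str],
    on_450k: Sequence[bool] | bool = True,
    cross_reactive: Sequence[bool] | bool = False,
    snp_overlap: Sequence[bool] | bool = False,
    autosomal: Sequence[bool] | bool = True,
) -> pd.DataFrame:
    """Build a probe-annotation table (one row per probe, boolean flags)."""
    _check_unique(probe_ids, "probe")
    n = len(probe_ids)

    def _col(v):
        return np.full(n, v, dtype=bool) if np.isscalar(v) else np.asarray(v, bool)

    return pd.DataFrame(
        {
            "on_450k": _col(on_450k),
            "cross_reactive": _col(cross_reactive),
            "snp_overlap": _col(snp_overlap),
            "autosomal": _col(autosomal),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


# ---------------------------------------------------------------------------
# Sample sheets


_DATE_FIELDS = (
    "birth_date",
    "egg_retrieval_date",
    "embryo_insertion_date",
    "freeze_date",
)


@dataclass
class SampleRecord:
    """One newborn's clinical record.

    ``ga_ultrasound_days`` is the clinically estimated gestational age from
    the routine ultrasound, in days. ART records carry the procedure (IVF or
    ICSI), whether the embryo was transferred fresh or after freezing, and
    the procedure dates from which an embryo-transfer-date (ETD) gestational
    age can be derived.
    """

    sample_id: str
    ga_ultrasound_days: int
    art: bool = False
    procedure: str = "none"
    embryo_state: str = "none"
    birth_date: date | None = None
    egg_retrieval_date: date | None = None
    embryo_insertion_date: date | None = None
    freeze_date: date | None = None
    ga_etd_days: int | None = None

    def __post_init__(self) -> None:
        if self.ga_ultrasound_days is not None and self.ga_ultrasound_days <= 0:
            raise ValidationError(
                f"{self.sample_id}: ga_ultrasound_days must be positive"
            )
        if self.procedure not in ("IVF", "ICSI", "none"):
            raise ValidationError(
                f"{self.sample_id}: procedure must be IVF, ICSI or none"
            )
        if self.embryo_state not in ("fresh", "frozen", "none"):
            raise ValidationError(
                f"{self.sample_id}: embryo_state must be fresh, frozen or none"
            )
        if not self.art:
            for f in ("egg_retrieval_date", "embryo_insertion_date", "freeze_date"):
                if getattr(self, f) is not None:
                    raise ValidationError(
                        f"{self.sample_id}: {f} set on a non-ART record"
                    )
            if self.procedure != "none" or self.embryo_state != "none":
                raise ValidationError(
                    f"{self.sample_id}: ART procedure fields set on a non-ART record"
                )
        # chronology: retrieval <= freeze <= insertion <= birth where present
        chain = [
            self.egg_retrieval_date,
            self.freeze_date,
            self.embryo_insertion_date,
            self.birth_date,
        ]
        present = [(i, d) for i, d in enumerate(chain) if d is not None]
        names = ["egg_retrieval_date", "freeze_date", "embryo_insertion_date", "birth_date"]
        for (i, a), (j, b) in zip(present, present[1:]):
            if a > b:
                raise ValidationError(
                    f"{self.sample_id}: {names[i]} ({a}) after {names[j]} ({b})"
                )


class SampleSheet:
    """Ordered collection of :class:`SampleRecord` with unique sample ids."""

    def __init__(self, records: Sequence[SampleRecord]):
        self.records = list(records)
        _check_unique([r.sample_id for r in self.records], "sample")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def ga(self, source: str = "ultrasound") -> pd.Series:
        """Gestational age per sample in days; NaN where unavailable."""
        if source == "ultrasound":
            vals = [r.ga_ultrasound_days for r in self.records]
        elif source == "etd":
            vals = [
                np.nan if r.ga_etd_days is None else r.ga_etd_days
                for r in self.records
            ]
        else:
            raise ValueError(f"unknown GA source {source!r}")
        return pd.Series(vals, index=self.sample_ids, dtype=float, name=f"ga_{source}")

    def art_mask(self) -> pd.Series:
        return pd.Series(
            [r.art for r in self.records], index=self.sample_ids, name="art"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = dataclasses.asdict(r)
            for f in _DATE_FIELDS:
                d[f] = "" if d[f] is None else d[f].isoformat()
            d["ga_etd_days"] = "" if d["ga_etd_days"] is None else d["ga_etd_days"]
            rows.append(d)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSheet":
        records = []
        for _, row in df.iterrows():
            kwargs = {
                "sample_id": str(row["sample_id"]),
                "ga_ultrasound_days": int(row["ga_ultrasound_days"]),
                "art": _parse_bool(row.get("art", False)),
                "procedure": str(row.get("procedure", "none") or "none"),
                "embryo_state": str(row.get("embryo_state", "none") or "none"),
            }
            for f in _DATE_FIELDS:
                v = row.get(f, "")
                kwargs[f] = None if _is_blank(v) else date.fromisoformat(str(v))
            v = row.get("ga_etd_days", "")
            kwargs["ga_etd_days"] = None if _is_blank(v) else int(float(v))
            records.append(SampleRecord(**kwargs))
        return cls(records)


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == ""


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1", "yes")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "ga_ultrasound_days" not in df.columns:
        raise ValidationError(
            "sample sheet must have sample_id and ga_ultrasound_days columns"
        )
    return SampleSheet.from_frame(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Clock coefficient files


INTERCEPT_TERM = "(Intercept)"


@dataclass
class ClockModel:
    """A sparse linear gestational-age clock.

    Predicted GA (days) = intercept + sum_j coefficient_j * beta_j over the
    clock's CpGs. ``training_medians`` (beta medians of the training data)
    back imputation when a clock CpG is absent from the target dataset; they
    may be empty for clocks read from files that do not ship them.
    """

    intercept: float
    coefficients: dict[str, float]
    alpha: float | None = None
    lam: float | None = None
    n_folds: int | None = None
    seed: int | None = None
    training_medians: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        zero = [p for p, c in self.coefficients.items() if c == 0.0]
        if zero:
            raise ValidationError(f"zero coefficients not allowed: {zero[:5]}")
        if self.training_medians:
            missing = set(self.coefficients) - set(self.training_medians)
            if missing:
                raise ValidationError(
                    f"training_medians missing for probes: {sorted(missing)[:5]}"
                )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)

    def __len__(self) -> int:
        return len(self.coefficients)


def read_clock_file(path: str | Path) -> ClockModel:
    """Read a clock coefficient CSV: columns term, coefficient[, median].

    The row whose term is ``(Intercept)`` holds the intercept. Rows with a
    zero coefficient are dropped (the clock is its non-zero support).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    if "term" not in cols or "coefficient" not in cols:
        raise ValidationError("clock file needs columns: term, coefficient")
    terms = df[cols["term"]].astype(str)
    try:
        coefs = df[cols["coefficient"]].astype(float)
    except (TypeError, ValueError) as e:
        raise ValidationError(f"non-numeric coefficient in clock file: {e}") from e
    is_int = terms == INTERCEPT_TERM
    if is_int.sum() != 1:
        raise ValidationError(
            f"clock file must contain exactly one {INTERCEPT_TERM} row"
        )
    intercept = float(coefs[is_int].iloc[0])
    medians: dict[str, float] = {}
    if "median" in cols:
        med = df[cols["median"]].astype(float)
        medians = {
            t: float(m)
            for t, m, i in zip(terms, med, is_int)
            if not i and np.isfinite(m)
        }
    coefficients = {
        t: float(c) for t, c, i in zip(terms, coefs, is_int) if not i and c != 0.0
    }
    medians = {t: medians[t] for t in coefficients if t in medians}
    return ClockModel(intercept=intercept, coefficients=coefficients,
                      training_medians=medians)


def write_clock_file(clock: ClockModel, path: str | Path) -> None:
    rows = [{"term": INTERCEPT_TERM, "coefficient": clock.intercept}]
    has_medians = bool(clock.training_medians)
    if has_medians:
        rows[0]["median"] = np.nan
    for p, c in clock.coefficients.items():
        row = {"term": p, "coefficient": c}
        if has_medians:
            row["median"] = clock.training_medians[p]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Probe lists


def read_probe_list(path: str | Path) -> list[str]:
    """Plain-text probe-id list, one id per line; blanks ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_probe_list(probe_ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probe_ids:
            fh.write(f"{p}\n")
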