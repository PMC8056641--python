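"""Gestational age from assisted-reproduction procedure dates (ETD).

The embryo-transfer-date estimate anchors conception at the known laboratory
dates instead of the ultrasound biometry:

* fresh transfer, egg-retrieval date known:
  GA = (birth - retrieval) + 14 days;
* fresh transfer, retrieval unknown: the insertion date minus two days
  stands in for retrieval, so GA = (birth - insertion) + 16 days;
* frozen transfer: GA = (birth - insertion) + 14 days plus the number of
  days the embryo developed before freezing, (freeze - retrieval).

The 14-day convention places the notional last menstrual period two weeks
before fertilisation, matching how ultrasound GA is reported. All
arithmetic is in whole days. Intrauterine-insemination conceptions are
treated as non-ART and rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import SampleRecord, SampleSheet, ValidationError

__all__ = ["compute_etd_ga", "annotate_etd", "EtdReport"]


def compute_etd_ga(rec: SampleRecord) -> int:
    """Derive the ETD gestational age in days for one ART record."""
    if not rec.art:
        raise ValidationError(f"{rec.sample_id}: ETD GA is defined for ART records only")
    if rec.birth_date is None:
        raise ValidationError(f"{rec.sample_id}: missing birth_date")
    if rec.embryo_state == "frozen":
        missing = [
            f
            for f in ("embryo_insertion_date", "freeze_date", "egg_retrieval_date")
            if getattr(rec, f) is None
        ]
        if missing:
            raise ValidationError(
                f"{rec.sample_id}: frozen transfer needs {', '.join(missing)}"
            )
        ga = (
            (rec.birth_date - rec.embryo_insertion_date).days
            + 14
            + (rec.freeze_date - rec.egg_retrieval_date).days
        )
    elif rec.egg_retrieval_date is not None:
        ga = (rec.birth_date - rec.egg_retrieval_date).days + 14
    elif rec.embryo_insertion_date is not None:
        # insertion is assumed to follow retrieval by two days
        ga = (rec.birth_date - rec.embryo_insertion_date).days + 16
    else:
        raise ValidationError(
            f"{rec.sample_id}: needs egg_retrieval_date or embryo_insertion_date"
        )
    if ga <= 0:
        raise ValidationError(f"{rec.sample_id}: non-positive ETD GA ({ga} days)")
    return int(ga)


@dataclass
class EtdReport:
    """Counts per ETD rule applied by :func:`annotate_etd`."""

    n_fresh_retrieval: int = 0
    n_fresh_insertion: int = 0
    n_frozen: int = 0
    n_non_art: int = 0
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def n_annotated(self) -> int:
        return self.n_fresh_retrieval + self.n_fresh_insertion + self.n_frozen


def annotate_etd(sheet: SampleSheet) -> tuple[SampleSheet, EtdReport]:
    """Fill ``ga_etd_days`` for every ART record with sufficient dates.

    Non-ART records are left untouched; per-record failures are collected in
    the report rather than raised.
    """
    report = EtdReport()
    out = []
    for rec in sheet:
        if not rec.art:
            report.n_non_art += 1
            out.append(rec)
            continue
        try:
            ga = compute_etd_ga(rec)
        except ValidationError as e:
            report.failures[rec.sample_id] = str(e)
            out.append(rec)
            continue
        if rec.embryo_state == "frozen":
            report.n_frozen += 1
        elif rec.egg_retrieval_date is not None:
            report.n_fresh_retrieval += 1
        else:
            report.n_fresh_insertion += 1
        out.append(
            SampleRecord(
                **{
                    **rec.__dict__,
                    "ga_etd_days": ga,
                }
            )
        )
    return SampleSheet(out), report
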