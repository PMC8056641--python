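"""Probe-level quality control and imputation for beta matrices.

Filters are applied in a fixed order — cross-reactive probes, detection
p-value failures, SNP-overlapping probes, non-autosomal probes — so the
per-stage removal counts are deterministic. The default detection rule
drops a probe if its detection p-value exceeds the threshold in *any*
sample; ``detp_fraction`` switches to the at-least-this-fraction-of-samples
dialect (e.g. 0.25).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Collection, Mapping

import numpy as np
import pandas as pd

from .io import ANNOTATION_COLUMNS, BetaMatrix, ValidationError

__all__ = ["FilterReport", "filter_probes", "restrict_to_platform", "impute_missing"]


@dataclass
class FilterReport:
    n_input: int
    removed_cross_reactive: int
    removed_detection_p: int
    removed_snp_overlap: int
    removed_non_autosomal: int
    n_output: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def filter_probes(
    bm: BetaMatrix,
    ann: pd.DataFrame | None = None,
    detection_p_threshold: float = 0.01,
    detp_fraction: float | None = None,
    drop_cross_reactive: bool = True,
    drop_snp_overlap: bool = True,
    autosomal_only: bool = False,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove low-quality probes; report the count removed at each stage.

    The annotation table must cover every probe in the matrix whenever an
    annotation-based filter is requested.
    """
    if not 0.0 < detection_p_threshold <= 1.0:
        raise ValueError("detection_p_threshold must be in (0, 1]")
    if detp_fraction is not None and not 0.0 < detp_fraction <= 1.0:
        raise ValueError("detp_fraction must be in (0, 1]")

    needs_ann = drop_cross_reactive or drop_snp_overlap or autosomal_only
    if needs_ann:
        if ann is None:
            raise ValidationError("annotation table required for requested filters")
        missing = bm.probe_ids.difference(ann.index)
        if len(missing):
            raise ValidationError(
                f"probes missing from annotation: {missing[:10].tolist()}"
            )
        ann = ann.loc[bm.probe_ids, list(ANNOTATION_COLUMNS)]

    keep = bm.probe_ids
    n_input = len(keep)

    def _drop(mask: pd.Series) -> int:
        nonlocal keep
        removed = keep[mask.loc[keep].to_numpy()]
        keep = keep[~mask.loc[keep].to_numpy()]
        return len(removed)

    n_cross = 0
    if drop_cross_reactive:
        n_cross = _drop(ann["cross_reactive"])

    n_detp = 0
    if bm.detection_p is not None:
        fail = bm.detection_p.to_numpy() > detection_p_threshold
        if detp_fraction is None:
            bad = fail.any(axis=1)
        else:
            bad = fail.mean(axis=1) >= detp_fraction
        n_detp = _drop(pd.Series(bad, index=bm.probe_ids))

    n_snp = 0
    if drop_snp_overlap:
        n_snp = _drop(ann["snp_overlap"])

    n_sex = 0
    if autosomal_only:
        n_sex = _drop(~ann["autosomal"])

    report = FilterReport(
        n_input=n_input,
        removed_cross_reactive=n_cross,
        removed_detection_p=n_detp,
        removed_snp_overlap=n_snp,
        removed_non_autosomal=n_sex,
        n_output=len(keep),
    )
    return bm.select_probes(keep), report


def restrict_to_platform(bm: BetaMatrix, probe_set: Collection[str]) -> BetaMatrix:
    """Keep only probes present on another array platform, preserving order."""
    probe_set = set(probe_set)
    keep = [p for p in bm.probe_ids if p in probe_set]
    if not keep:
        raise ValidationError("no probes in common with the platform probe set")
    return bm.select_probes(keep)


def impute_missing(
    bm: BetaMatrix, fallback_medians: Mapping[str, float] | None = None
) -> BetaMatrix:
    """Median-impute missing beta values per probe.

    Each missing cell becomes the median of that probe's observed values
    across samples. Probes with no observed value at all fall back to
    ``fallback_medians`` (typically a clock's training medians); without a
    fallback they are an error.
    """
    values = bm.values
    arr = values.to_numpy(copy=True)
    miss = np.isnan(arr)
    if not miss.any():
        return bm
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled below
        med = np.nanmedian(arr, axis=1)
    all_missing = np.flatnonzero(np.isnan(med))
    if len(all_missing):
        ids = values.index[all_missing]
        if fallback_medians is None:
            raise ValidationError(
                f"probes with no observed values and no fallback median: "
                f"{ids[:10].tolist()}"
            )
        unknown = [p for p in ids if p not in fallback_medians]
        if unknown:
            raise ValidationError(
                f"probes with no observed values and no fallback median: {unknown[:10]}"
            )
        med[all_missing] = [fallback_medians[p] for p in ids]
    rows = np.nonzero(miss)[0]
    arr[miss] = med[rows]
    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return BetaMatrix(out, bm.detection_p)
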