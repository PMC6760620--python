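"""Height-adjusted impedance vectors and quality-control filtering.

At 50 kHz the impedance vector splits into resistance R (fluid conduction)
and reactance Xc (cell-membrane capacitance). BIVA works with the
height-adjusted components R/H and Xc/H (ohm/m) and the phase angle
PA = arctan(Xc/R) in degrees. Instruments report R, Xc and PA in duplicate;
analyses use the duplicate means.

Plausibility and repeatability filters: averaged PA above 8 degrees is
physiologically implausible in healthy subjects (normal range roughly
5-7 degrees); duplicate disagreement above 0.5 degrees for PA, or at or
above 6 ohm/m for R/H or Xc/H, marks a technically unreliable measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .cohort_io import CohortTable, ParseReport, SubjectRecord
from .errors import DomainError, IncompleteRecordError

__all__ = [
    "BivaVector",
    "QCThresholds",
    "QCPartition",
    "compute_vector",
    "qc_filter",
    "REASON_PA_IMPLAUSIBLE",
    "REASON_PA_REPEAT",
    "REASON_RH_REPEAT",
    "REASON_XCH_REPEAT",
    "REASON_INCOMPLETE",
]

REASON_PA_IMPLAUSIBLE = "implausible PA"
REASON_PA_REPEAT = "PA repeatability"
REASON_RH_REPEAT = "R/H repeatability"
REASON_XCH_REPEAT = "Xc/H repeatability"
REASON_INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class BivaVector:
    """Height-adjusted vector components for one subject.

    ``pa`` is the instrument-reported phase angle (duplicate mean);
    ``pa_consistency`` is arctan(Xc/R) recomputed from the averaged
    readings, for internal cross-checking. ``z`` is |Z| = sqrt(R^2+Xc^2).
    """

    r_h: float  # ohm/m
    xc_h: float  # ohm/m
    pa: float  # degrees
    z: Optional[float] = None  # ohm
    pa_consistency: Optional[float] = None  # degrees


@dataclass(frozen=True)
class QCThresholds:
    pa_max: float = 8.0  # degrees, strict >
    pa_dup_max: float = 0.5  # degrees, strict >
    rh_dup_max: float = 6.0  # ohm/m, >= excludes
    xch_dup_max: float = 6.0  # ohm/m, >= excludes

    def __post_init__(self):
        if min(self.pa_max, self.pa_dup_max, self.rh_dup_max, self.xch_dup_max) <= 0:
            raise DomainError("QC thresholds must be positive")


@dataclass
class QCPartition:
    kept: CohortTable
    excluded: list[tuple[SubjectRecord, tuple[str, ...]]]

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.excluded)

    def reasons_count(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reasons in self.excluded:
            for r in reasons:
                counts[r] = counts.get(r, 0) + 1
        return counts


def compute_vector(record: SubjectRecord) -> BivaVector:
    """Average the duplicate readings and divide R, Xc by height."""
    for name, pair in (("R", record.r_dup), ("Xc", record.xc_dup), ("PA", record.pa_dup)):
        if pair is None or len(pair) != 2 or any(v is None for v in pair):
            raise IncompleteRecordError(f"{record.subject_id}: missing {name} duplicate")
        if any(not (v > 0) for v in pair):
            raise DomainError(f"{record.subject_id}: nonpositive {name} reading")
    if not (record.height > 0):
        raise DomainError(f"{record.subject_id}: nonpositive height")
    r = (record.r_dup[0] + record.r_dup[1]) / 2.0
    xc = (record.xc_dup[0] + record.xc_dup[1]) / 2.0
    pa = (record.pa_dup[0] + record.pa_dup[1]) / 2.0
    return BivaVector(
        r_h=r / record.height,
        xc_h=xc / record.height,
        pa=pa,
        z=math.hypot(r, xc),
        pa_consistency=math.degrees(math.atan2(xc, r)),
    )


def _record_reasons(record: SubjectRecord, thr: QCThresholds) -> tuple[str, ...]:
    reasons = []
    try:
        pa_mean = (record.pa_dup[0] + record.pa_dup[1]) / 2.0
        pa_gap = abs(record.pa_dup[0] - record.pa_dup[1])
        rh_gap = abs(record.r_dup[0] - record.r_dup[1]) / record.height
        xch_gap = abs(record.xc_dup[0] - record.xc_dup[1]) / record.height
    except (TypeError, IndexError, ZeroDivisionError):
        return (REASON_INCOMPLETE,)
    if pa_mean > thr.pa_max:
        reasons.append(REASON_PA_IMPLAUSIBLE)
    if pa_gap > thr.pa_dup_max:
        reasons.append(REASON_PA_REPEAT)
    if rh_gap >= thr.rh_dup_max:
        reasons.append(REASON_RH_REPEAT)
    if xch_gap >= thr.xch_dup_max:
        reasons.append(REASON_XCH_REPEAT)
    return tuple(reasons)


def qc_filter(table: CohortTable, thresholds: QCThresholds | None = None) -> QCPartition:
    """Partition a cohort into QC-kept and QC-excluded records.

    A record is excluded iff at least one rule fires; every exclusion
    carries exactly the reasons that fired. Kept and excluded sets are
    disjoint and together exhaust the input.
    """
    thr = thresholds or QCThresholds()
    kept: list[SubjectRecord] = []
    excluded: list[tuple[SubjectRecord, tuple[str, ...]]] = []
    for rec in table:
        reasons = _record_reasons(rec, thr)
        if reasons:
            excluded.append((rec, reasons))
        else:
            kept.append(rec)
    prov = ParseReport(source=f"qc_filter({table.provenance.source})", rows_read=len(table))
    prov.rejects = [(rec.subject_id, "; ".join(reasons)) for rec, reasons in excluded]
    return QCPartition(kept=CohortTable(records=kept, provenance=prov), excluded=excluded)
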