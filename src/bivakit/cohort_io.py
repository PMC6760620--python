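"""Cohort table I/O and the canonical subject record model.

A cohort is a flat CSV with one row per child carrying anthropometry,
duplicate 50 kHz impedance readings (resistance R, reactance Xc, phase
angle PA) and, optionally, the inputs to the 4-component body-composition
model (deuterium dilution space, body volume, bone mineral content).

Parsing never silently drops a row: every malformed row is recorded in the
parse report with the reason it was rejected, and ``rows_read`` always
equals kept + rejected.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, EmptyInputError

__all__ = [
    "Sex",
    "SubjectRecord",
    "ParseReport",
    "CohortTable",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


#: Canonical cohort CSV column order.
COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "age_y",
    "height_m",
    "weight_kg",
    "r1_ohm",
    "r2_ohm",
    "xc1_ohm",
    "xc2_ohm",
    "pa1_deg",
    "pa2_deg",
    "dilution_space_kg",
    "body_volume_l",
    "bmc_kg",
]

_MANDATORY = COHORT_COLUMNS[:11]
_OPTIONAL = COHORT_COLUMNS[11:]

#: Default decoding of the sex column; a user mapping overrides this.
DEFAULT_SEX_MAP: Mapping[str, Sex] = {
    "male": Sex.MALE,
    "m": Sex.MALE,
    "boy": Sex.MALE,
    "1": Sex.MALE,
    "female": Sex.FEMALE,
    "f": Sex.FEMALE,
    "girl": Sex.FEMALE,
    "2": Sex.FEMALE,
}

#: Age range (years) over which reference fitting is supported.
REFERENCE_AGE_RANGE = (4.0, 20.0)


@dataclass(frozen=True)
class SubjectRecord:
    """One child's raw measurements.

    Units: age in decimal years, height in metres, weight in kilograms,
    R/Xc in ohms, PA in degrees, dilution space and BMC in kilograms,
    body volume in litres. ``flags`` carries non-fatal annotations such as
    an age outside the reference-fitting range.
    """

    subject_id: str
    sex: Sex
    age: float
    height: float
    weight: float
    r_dup: tuple[float, float]
    xc_dup: tuple[float, float]
    pa_dup: tuple[float, float]
    dilution_space: Optional[float] = None
    body_volume: Optional[float] = None
    bmc: Optional[float] = None
    flags: tuple[str, ...] = ()

    def violations(self) -> list[str]:
        """Hard invariant violations that make the record unusable."""
        out = []
        if not (self.height > 0):
            out.append("nonpositive height")
        if not (self.weight > 0):
            out.append("nonpositive weight")
        for name, pair in (("R", self.r_dup), ("Xc", self.xc_dup), ("PA", self.pa_dup)):
            if any(not (v > 0) or math.isnan(v) for v in pair):
                out.append(f"nonpositive {name} reading")
        for name, v in (
            ("dilution space", self.dilution_space),
            ("body volume", self.body_volume),
            ("BMC", self.bmc),
        ):
            if v is not None and not (v > 0):
                out.append(f"nonpositive {name}")
        return out

    def age_flags(self) -> tuple[str, ...]:
        lo, hi = REFERENCE_AGE_RANGE
        if not (lo <= self.age <= hi):
            return ("age outside reference range",)
        return ()

    def has_4c_inputs(self) -> bool:
        return None not in (self.dilution_space, self.body_volume, self.bmc)


@dataclass
class ParseReport:
    source: str
    rows_read: int = 0
    rejects: list[tuple[str, str]] = field(default_factory=list)  # (row label, reason)

    @property
    def rows_kept(self) -> int:
        return self.rows_read - len(self.rejects)


@dataclass
class CohortTable:
    """Ordered collection of subject records plus parse provenance."""

    records: list[SubjectRecord]
    provenance: ParseReport

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "sex": r.sex.value,
                    "age_y": r.age,
                    "height_m": r.height,
                    "weight_kg": r.weight,
                    "r1_ohm": r.r_dup[0],
                    "r2_ohm": r.r_dup[1],
                    "xc1_ohm": r.xc_dup[0],
                    "xc2_ohm": r.xc_dup[1],
                    "pa1_deg": r.pa_dup[0],
                    "pa2_deg": r.pa_dup[1],
                    "dilution_space_kg": r.dilution_space,
                    "body_volume_l": r.body_volume,
                    "bmc_kg": r.bmc,
                }
            )
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def _clean_optional(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _row_to_record(row: Mapping, sex_map: Mapping[str, Sex]) -> SubjectRecord:
    sex_raw = str(row["sex"]).strip().lower()
    if sex_raw not in sex_map:
        raise ValueError(f"unrecognised sex code {row['sex']!r}")
    rec = SubjectRecord(
        subject_id=str(row["subject_id"]),
        sex=sex_map[sex_raw],
        age=float(row["age_y"]),
        height=float(row["height_m"]),
        weight=float(row["weight_kg"]),
        r_dup=(float(row["r1_ohm"]), float(row["r2_ohm"])),
        xc_dup=(float(row["xc1_ohm"]), float(row["xc2_ohm"])),
        pa_dup=(float(row["pa1_deg"]), float(row["pa2_deg"])),
        dilution_space=_clean_optional(row.get("dilution_space_kg")),
        body_volume=_clean_optional(row.get("body_volume_l")),
        bmc=_clean_optional(row.get("bmc_kg")),
    )
    return replace(rec, flags=rec.age_flags())


def read_cohort(
    path,
    schema_config: Optional[Mapping[str, str]] = None,
    sex_map: Optional[Mapping[str, Sex]] = None,
) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`.

    Parameters
    ----------
    path:
        CSV file with a header row; comma-separated, ``.`` decimals,
        missing optional values as empty cells.
    schema_config:
        Optional mapping from canonical column names (see
        :data:`COHORT_COLUMNS`) to the names actually used in the file.
    sex_map:
        Optional mapping from sex codes (matched case-insensitively) to
        :class:`Sex`; defaults accept male/m/boy/1 and female/f/girl/2.
    """
    schema = {c: c for c in COHORT_COLUMNS}
    if schema_config:
        unknown = set(schema_config) - set(COHORT_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown canonical columns in mapping: {sorted(unknown)}")
        schema.update(schema_config)
    smap = dict(DEFAULT_SEX_MAP)
    if sex_map:
        smap.update({str(k).strip().lower(): Sex(v) for k, v in sex_map.items()})

    try:
        raw = pd.read_csv(path, dtype={schema["subject_id"]: str, schema["sex"]: str})
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty cohort file") from None
    if raw.empty:
        raise EmptyInputError(f"{path}: cohort file has a header but no rows")

    missing = [c for c in _MANDATORY if schema[c] not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory columns {missing}")
    # Rename file columns back to canonical names; absent optionals stay absent.
    rename = {schema[c]: c for c in COHORT_COLUMNS if schema[c] in raw.columns}
    raw = raw.rename(columns=rename)
    for c in _OPTIONAL:
        if c not in raw.columns:
            raw[c] = None

    report = ParseReport(source=str(path), rows_read=len(raw))
    records: list[SubjectRecord] = []
    seen_ids: set[str] = set()
    for idx, row in raw.iterrows():
        label = str(row.get("subject_id", f"row {idx}"))
        try:
            rec = _row_to_record(row, smap)
        except (ValueError, TypeError, KeyError) as exc:
            report.rejects.append((label, f"malformed row: {exc}"))
            continue
        bad = rec.violations()
        if bad:
            report.rejects.append((label, "; ".join(bad)))
            continue
        if rec.subject_id in seen_ids:
            report.rejects.append((label, "duplicate subject_id"))
            continue
        seen_ids.add(rec.subject_id)
        records.append(rec)
    return CohortTable(records=records, provenance=report)


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort table to CSV; missing optionals become empty cells."""
    if not table.records:
        raise EmptyInputError("refusing to write an empty cohort table")
    frame = table.to_frame()
    frame.to_csv(path, index=False, float_format="%.10g")
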