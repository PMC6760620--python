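"""Four-component body composition: TBW, fat mass, fat-free mass, hydration.

Total body water (TBW) comes from the deuterium dilution space divided by
1.044, correcting the overestimate caused by proton exchange. Fat mass is
obtained from the 4-component partition of body weight into fat, water,
mineral and residual, using a linear combination of body volume (air
displacement plethysmography), TBW and bone mineral content (DXA):

    FM = c_bv * BV - c_tbw * TBW + c_bmc * BMC - c_wt * weight

with the Fuller-type coefficient set (2.747, 0.710, 1.460, 2.050) as the
default. FFM is the complement weight - FM, and the hydration of fat-free
mass is H_FFM = TBW / FFM, typically 0.70-0.80 in healthy children and
declining with chemical maturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .biva_core import compute_vector
from .cohort_io import CohortTable, SubjectRecord
from .errors import DomainError

__all__ = [
    "DEUTERIUM_PROTON_EXCHANGE",
    "HYDRATION_PLAUSIBLE_RANGE",
    "FourComponentCoefficients",
    "FULLER_4C",
    "BodyComposition",
    "tbw_from_dilution",
    "four_component",
    "hydration",
    "body_mass_index",
    "compose_record",
    "compose_table",
]

#: Dilution-space overestimation factor for deuterium proton exchange.
DEUTERIUM_PROTON_EXCHANGE = 1.044

#: Plausibility band for FFM hydration in healthy children (flag outside).
HYDRATION_PLAUSIBLE_RANGE = (0.70, 0.80)


@dataclass(frozen=True)
class FourComponentCoefficients:
    """Coefficients of the linear 4C fat-mass equation (BV litres, masses kg)."""

    body_volume: float = 2.747
    tbw: float = -0.710
    bmc: float = 1.460
    weight: float = -2.050
    name: str = "fuller-type"


FULLER_4C = FourComponentCoefficients()


@dataclass(frozen=True)
class BodyComposition:
    """Per-subject composition outputs with quality flags.

    ``flags`` marks physiologically impossible or implausible combinations
    (fm outside [0, weight], hydration outside the healthy band); flagged
    results are returned, not raised, so cohort runs can report them.
    """

    tbw: float  # kg
    fm: float  # kg
    ffm: float  # kg
    h_ffm: float  # fraction
    bmi: float  # kg/m^2
    coefficients: FourComponentCoefficients = FULLER_4C
    flags: tuple[str, ...] = ()


def tbw_from_dilution(dilution_space: float) -> float:
    """TBW (kg) from deuterium dilution space (kg)."""
    if not (dilution_space > 0):
        raise DomainError("dilution space must be positive")
    return dilution_space / DEUTERIUM_PROTON_EXCHANGE


def four_component(
    weight: float,
    body_volume: float,
    tbw: float,
    bmc: float,
    coefficients: FourComponentCoefficients = FULLER_4C,
) -> tuple[float, float, tuple[str, ...]]:
    """Fat and fat-free mass (kg) from the 4C model.

    Returns ``(fm, ffm, flags)``; a combination yielding fm < 0 or
    fm > weight is flagged (quality code), not rejected.
    """
    if min(weight, body_volume, tbw, bmc) <= 0:
        raise DomainError("all 4C inputs must be positive")
    if tbw >= weight:
        raise DomainError("TBW must be smaller than body weight")
    if bmc >= weight:
        raise DomainError("BMC must be smaller than body weight")
    c = coefficients
    fm = c.body_volume * body_volume + c.tbw * tbw + c.bmc * bmc + c.weight * weight
    ffm = weight - fm
    flags: tuple[str, ...] = ()
    if fm < 0:
        flags = ("negative fat mass",)
    elif fm > weight:
        flags = ("fat mass exceeds weight",)
    return fm, ffm, flags


def hydration(tbw: float, ffm: float) -> tuple[float, tuple[str, ...]]:
    """FFM hydration fraction TBW/FFM, flagged outside the healthy band."""
    if not (ffm > 0):
        raise DomainError("FFM must be positive")
    h = tbw / ffm
    lo, hi = HYDRATION_PLAUSIBLE_RANGE
    flags = () if lo <= h <= hi else ("hydration outside plausible band",)
    return h, flags


def body_mass_index(weight: float, height: float) -> float:
    if not (height > 0 and weight > 0):
        raise DomainError("weight and height must be positive")
    return weight / height**2


def compose_record(
    record: SubjectRecord,
    coefficients: FourComponentCoefficients = FULLER_4C,
) -> Optional[BodyComposition]:
    """4C composition for one record, or None when 4C inputs are absent."""
    if not record.has_4c_inputs():
        return None
    tbw = tbw_from_dilution(record.dilution_space)
    fm, ffm, flags = four_component(
        record.weight, record.body_volume, tbw, record.bmc, coefficients
    )
    h, hflags = hydration(tbw, ffm)
    return BodyComposition(
        tbw=tbw,
        fm=fm,
        ffm=ffm,
        h_ffm=h,
        bmi=body_mass_index(record.weight, record.height),
        coefficients=coefficients,
        flags=flags + hflags,
    )


def compose_table(
    table: CohortTable,
    coefficients: FourComponentCoefficients = FULLER_4C,
    include_vectors: bool = True,
) -> pd.DataFrame:
    """Per-subject composition (and optionally BIVA vector) data frame.

    Columns: subject_id, sex, age_y, then tbw_kg, fm_kg, ffm_kg, h_ffm,
    bmi, quality flags; with ``include_vectors`` also r_h, xc_h, pa.
    Subjects lacking 4C inputs get empty composition cells.
    """
    rows = []
    for rec in table:
        row: dict = {"subject_id": rec.subject_id, "sex": rec.sex.value, "age_y": rec.age}
        if include_vectors:
            vec = compute_vector(rec)
            row.update(rh=vec.r_h, xch=vec.xc_h, pa=vec.pa)
        comp = compose_record(rec, coefficients)
        if comp is not None:
            row.update(
                tbw_kg=comp.tbw,
                fm_kg=comp.fm,
                ffm_kg=comp.ffm,
                h_ffm=comp.h_ffm,
                bmi=comp.bmi,
                quality_flags="; ".join(comp.flags),
                coefficient_set=coefficients.name,
            )
        else:
            row.update(bmi=body_mass_index(rec.weight, rec.height))
        rows.append(row)
    return pd.DataFrame(rows)
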