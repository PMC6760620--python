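"""Synthetic paediatric BIVA cohorts with known ground truth.

Generates cohorts of 4-20-year-olds of both sexes with the statistical
structure the analysis assumes: height-adjusted resistance and reactance
declining with age in a curvilinear way, phase angle rising linearly,
FFM hydration declining with chemical maturation, and a specified
correlation structure between the seven trait SDS (phase angle, R/H,
Xc/H, BMI, FFM, FM, FFM hydration).

Each subject's seven SDS are drawn from a multivariate normal whose
correlation is the nearest positive-definite projection of the target
matrix, then back-transformed through per-sex median curves with
log-normal spreads (Box-Cox L = 0). Weight, height, dilution space, body
volume and bone mineral content are derived so the 4-component model
reproduces the intended fat mass, fat-free mass and hydration exactly;
duplicate instrument readings carry configurable noise, and a configurable
fraction of records violate the QC rules (for testing the filter).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from statsmodels.stats.correlation_tools import corr_nearest

from .body_composition import DEUTERIUM_PROTON_EXCHANGE, FULLER_4C, FourComponentCoefficients
from .cohort_io import CohortTable, ParseReport, Sex, SubjectRecord
from .cohort_analysis import FFM_SDS_SCHEME, HFFM_SDS_SCHEME, categorize
from .errors import DomainError

__all__ = [
    "TRAITS",
    "TABLE_SDS_CORRELATION",
    "GeneratorConfig",
    "SyntheticTruth",
    "nearest_pd",
    "default_config",
    "generate_cohort",
]

#: Trait order used everywhere: phase angle, R/H, Xc/H, BMI, FFM, FM, H_FFM.
TRAITS = ["pa", "rh", "xch", "bmi", "ffm", "fm", "hffm"]

#: Published whole-cohort SDS correlation structure between the seven
#: traits (order as in TRAITS). The printed, rounded values are not
#: positive definite; consumers project with :func:`nearest_pd`.
TABLE_SDS_CORRELATION = np.array(
    [
        #  pa     rh     xch    bmi    ffm    fm     hffm
        [1.00, -0.32, 0.40, 0.20, 0.29, 0.01, -0.07],
        [-0.32, 1.00, 0.73, -0.72, -0.89, -0.58, -0.32],
        [0.40, 0.73, 1.00, -0.55, -0.65, -0.54, -0.35],
        [0.20, -0.72, -0.55, 1.00, 0.74, 0.92, 0.45],
        [0.29, -0.89, -0.65, 0.74, 1.00, -0.61, 0.31],
        [0.01, -0.58, -0.54, 0.92, -0.61, 1.00, 0.52],
        [-0.07, -0.32, -0.35, 0.45, 0.31, 0.52, 1.00],
    ]
)

#: Median anchor points (ages 4, 12, 20 y) per trait and sex, plus the
#: log-normal coefficient of variation used for the SDS back-transform.
#: R/H and Xc/H decline curvilinearly, PA rises linearly within the
#: healthy 5-7 degree band, hydration declines with maturation; BMI, FFM
#: and FM sit on conventional paediatric scales chosen so the implied
#: median height runs from about 1.05 m at 4 y to about 1.70 m at 20 y.
DEFAULT_MEDIAN_ANCHORS: dict[str, dict] = {
    "pa": {"ages": (4.0, 12.0, 20.0), "male": (5.0, 5.75, 6.5), "female": (5.0, 5.65, 6.3), "cv": 0.08},
    "rh": {"ages": (4.0, 12.0, 20.0), "male": (600.0, 380.0, 300.0), "female": (620.0, 400.0, 330.0), "cv": 0.10},
    "xch": {"ages": (4.0, 12.0, 20.0), "male": (65.0, 45.0, 35.0), "female": (66.0, 47.0, 37.0), "cv": 0.12},
    "bmi": {"ages": (4.0, 12.0, 20.0), "male": (15.5, 18.0, 21.5), "female": (15.5, 18.5, 21.0), "cv": 0.12},
    "ffm": {"ages": (4.0, 12.0, 20.0), "male": (13.0, 33.0, 52.0), "female": (12.5, 31.0, 42.0), "cv": 0.13},
    "fm": {"ages": (4.0, 12.0, 20.0), "male": (3.5, 8.0, 10.0), "female": (3.8, 10.0, 16.0), "cv": 0.35},
    "hffm": {"ages": (4.0, 12.0, 20.0), "male": (0.765, 0.750, 0.735), "female": (0.765, 0.748, 0.732), "cv": 0.012},
}

DEFAULT_DUPLICATE_NOISE_SD = {"r": 2.0, "xc": 1.0, "pa": 0.1}  # ohm, ohm, degrees

#: BMC as a fraction of FFM (bone mineral is roughly 5% of FFM in children).
BMC_FFM_FRACTION = 0.052


def nearest_pd(matrix: np.ndarray, min_eigenvalue: float = 1e-8) -> tuple[np.ndarray, float]:
    """Nearest positive-definite correlation matrix.

    Returns ``(projected, max_abs_adjustment)``; the input is returned
    unchanged (adjustment 0) when its smallest eigenvalue is already at
    least ``min_eigenvalue``. Symmetric, unit-diagonal input required.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DomainError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise DomainError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        raise DomainError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(m).min() >= min_eigenvalue:
        return m, 0.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # Floor eigenvalues slightly above min_eigenvalue so the result
        # passes the "already PD" check and the operation is idempotent.
        projected = corr_nearest(m, threshold=min_eigenvalue * 10.0, n_fact=1000)
    projected = (projected + projected.T) / 2.0
    np.fill_diagonal(projected, 1.0)
    return projected, float(np.abs(projected - m).max())


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions the generator emulates; defaults are fixed."""

    n: int = 1000
    seed: int = 0
    sds_correlation: np.ndarray = field(default_factory=lambda: TABLE_SDS_CORRELATION.copy())
    median_anchors: Mapping[str, dict] = field(default_factory=lambda: dict(DEFAULT_MEDIAN_ANCHORS))
    duplicate_noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DUPLICATE_NOISE_SD))
    contamination: Mapping[str, float] = field(default_factory=dict)
    age_range: tuple[float, float] = (4.0, 20.0)
    coefficients: FourComponentCoefficients = FULLER_4C

    def __post_init__(self):
        if self.n <= 0:
            raise DomainError("cohort size must be positive")
        c = np.asarray(self.sds_correlation, dtype=float)
        if c.shape != (len(TRAITS), len(TRAITS)):
            raise DomainError(f"sds_correlation must be {len(TRAITS)}x{len(TRAITS)}")
        if not np.allclose(c, c.T, atol=1e-12) or np.any(np.abs(c) > 1 + 1e-12):
            raise DomainError("sds_correlation must be symmetric with entries in [-1, 1]")
        bad = [k for k, v in self.contamination.items() if not (0.0 <= v < 1.0)]
        if bad or sum(self.contamination.values()) >= 1.0:
            raise DomainError("contamination fractions must lie in [0, 1) and sum below 1")

    def config_hash(self) -> str:
        payload = {
            "n": self.n,
            "seed": self.seed,
            "corr": np.asarray(self.sds_correlation).round(12).tolist(),
            "anchors": {k: {kk: list(vv) if isinstance(vv, (tuple, list)) else vv for kk, vv in d.items()} for k, d in self.median_anchors.items()},
            "noise": dict(self.duplicate_noise_sd),
            "contamination": dict(self.contamination),
            "age_range": list(self.age_range),
            "coefficients": self.coefficients.name,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SyntheticTruth:
    """Ground truth rows matched one-to-one with the emitted records."""

    frame: pd.DataFrame
    config_hash: str
    seed: int
    correlation_pd: np.ndarray
    correlation_adjustment: float


def default_config(n: int = 1000, seed: int = 0, **overrides) -> GeneratorConfig:
    """Shipped defaults: published trait correlations, healthy-range medians."""
    return GeneratorConfig(n=n, seed=seed, **overrides)


def median_curve(config: GeneratorConfig, trait: str, sex: Sex):
    """Callable median-vs-age curve for one trait and sex."""
    spec = config.median_anchors[trait]
    return PchipInterpolator(np.asarray(spec["ages"], float), np.asarray(spec[sex.value], float))


_CONTAMINATION_KINDS = ("pa_implausible", "pa_repeat", "rh_repeat", "xch_repeat")


def generate_cohort(config: Optional[GeneratorConfig] = None) -> tuple[CohortTable, SyntheticTruth]:
    """Generate a cohort and its ground truth. Deterministic in config+seed."""
    cfg = config or default_config()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    corr_pd, adjustment = nearest_pd(np.asarray(cfg.sds_correlation, dtype=float))
    chol = np.linalg.cholesky(corr_pd)

    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    sex_codes = np.where(np.arange(n) % 2 == 0, Sex.MALE.value, Sex.FEMALE.value)
    z = rng.standard_normal((n, len(TRAITS))) @ chol.T

    raw = {}
    for j, trait in enumerate(TRAITS):
        cv = cfg.median_anchors[trait]["cv"]
        med = np.empty(n)
        for sex in (Sex.MALE, Sex.FEMALE):
            mask = sex_codes == sex.value
            med[mask] = median_curve(cfg, trait, sex)(ages[mask])
        raw[trait] = med * np.exp(cv * z[:, j])

    ffm, fm, hffm = raw["ffm"], raw["fm"], raw["hffm"]
    weight = ffm + fm
    height = np.sqrt(weight / raw["bmi"])
    tbw = hffm * ffm
    dilution = tbw * DEUTERIUM_PROTON_EXCHANGE
    bmc = BMC_FFM_FRACTION * ffm
    c = cfg.coefficients
    # Invert the 4C fat-mass equation for body volume so the pipeline's
    # composition stage reproduces fm/ffm/hydration exactly.
    body_volume = (fm - c.tbw * tbw - c.bmc * bmc - c.weight * weight) / c.body_volume

    r_true = raw["rh"] * height
    xc_true = raw["xch"] * height
    pa_true = raw["pa"].copy()

    noise = cfg.duplicate_noise_sd
    r_dup = r_true[:, None] + rng.normal(0.0, noise.get("r", 0.0), (n, 2))
    xc_dup = xc_true[:, None] + rng.normal(0.0, noise.get("xc", 0.0), (n, 2))
    pa_dup = pa_true[:, None] + rng.normal(0.0, noise.get("pa", 0.0), (n, 2))

    # Contamination: each subject receives at most one QC violation kind.
    kinds = [k for k in _CONTAMINATION_KINDS if cfg.contamination.get(k, 0.0) > 0]
    violation = np.full(n, "", dtype=object)
    if kinds:
        u = rng.uniform(size=n)
        lo = 0.0
        for k in kinds:
            hi = lo + cfg.contamination[k]
            violation[(u >= lo) & (u < hi)] = k
            lo = hi
        extra = rng.exponential(0.3, size=n)
        for i in np.flatnonzero(violation == "pa_implausible"):
            bad = 8.3 + extra[i]
            pa_dup[i] = bad + rng.normal(0.0, noise.get("pa", 0.0), 2)
        for i in np.flatnonzero(violation == "pa_repeat"):
            gap = 0.6 + extra[i]
            pa_dup[i] = (pa_true[i] + gap / 2.0, pa_true[i] - gap / 2.0)
        for i in np.flatnonzero(violation == "rh_repeat"):
            gap = (6.5 + extra[i]) * height[i]
            r_dup[i] = (r_true[i] + gap / 2.0, r_true[i] - gap / 2.0)
        for i in np.flatnonzero(violation == "xch_repeat"):
            gap = (6.5 + extra[i]) * height[i]
            xc_dup[i] = (xc_true[i] + gap / 2.0, xc_true[i] - gap / 2.0)

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:0{width}d}",
                sex=Sex(str(sex_codes[i])),
                age=float(ages[i]),
                height=float(height[i]),
                weight=float(weight[i]),
                r_dup=(float(r_dup[i, 0]), float(r_dup[i, 1])),
                xc_dup=(float(xc_dup[i, 0]), float(xc_dup[i, 1])),
                pa_dup=(float(pa_dup[i, 0]), float(pa_dup[i, 1])),
                dilution_space=float(dilution[i]),
                body_volume=float(body_volume[i]),
                bmc=float(bmc[i]),
            )
        )
    table = CohortTable(
        records=records,
        provenance=ParseReport(source=f"synthetic(seed={cfg.seed}, n={n})", rows_read=n),
    )

    truth = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "sex": sex_codes,
            "age_y": ages,
            **{f"{t}_sds": z[:, j] for j, t in enumerate(TRAITS)},
            "weight_kg": weight,
            "height_m": height,
            "fm_kg": fm,
            "ffm_kg": ffm,
            "tbw_kg": tbw,
            "h_ffm": hffm,
            "qc_violation": violation,
        }
    )
    truth["ffm_group"], _ = categorize(truth.rename(columns={"ffm_sds": "ffm_sds"}), FFM_SDS_SCHEME)
    truth["hffm_group"], _ = categorize(truth, HFFM_SDS_SCHEME)
    return table, SyntheticTruth(
        frame=truth,
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        correlation_pd=corr_pd,
        correlation_adjustment=adjustment,
    )
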