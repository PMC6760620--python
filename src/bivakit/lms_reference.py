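"""LMS (Box-Cox) age-and-sex reference curves and standard deviation scores.

The LMS method summarises how a positive measurement y varies with age by
three smooth curves: L(t), the Box-Cox power that removes skewness; M(t),
the median; and S(t), the coefficient of variation. Conditional on age t,

    z = ((y / M)^L - 1) / (L * S)        (L != 0)
    z = ln(y / M) / S                    (L -> 0 limit)

is standard normal, so z is the subject's standard deviation score (SDS)
and the p-th centile curve is M * (1 + L * S * z_p)^(1/L).

Curves are fitted by maximum likelihood with each of L, log M and log S
expanded on a spline basis in age. Complexity is counted in degrees of
freedom per curve (1 = constant, 2 = linear, 3 = quadratic, >= 4 = cubic
B-spline with that many basis functions) and selected by a BIC-type rule:
an extra degree of freedom is accepted only if it reduces the deviance by
more than ln(N). The two sexes are always fitted separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline, PchipInterpolator
from scipy.stats import norm

from .cohort_io import Sex
from .errors import ConvergenceError, DomainError, ExtrapolationError, ParseError

__all__ = [
    "LMSReference",
    "fit_lms",
    "fit_references",
    "to_sds",
    "centile_curve",
    "centile_table",
    "read_reference",
    "write_reference",
    "DEFAULT_EDF_RANGE",
]

#: Candidate degrees of freedom per curve for the greedy search.
DEFAULT_EDF_RANGE = (1, 2, 3, 4, 5, 6)

_L_EPS = 1e-8  # |L| below this uses the log-limit branch


# --------------------------------------------------------------------------
# spline basis


def _basis(u: np.ndarray, df: int, knots: Optional[np.ndarray]) -> np.ndarray:
    """Design matrix with ``df`` columns on standardised age ``u``."""
    u = np.asarray(u, dtype=float)
    if df == 1:
        return np.ones((u.size, 1))
    if df == 2:
        return np.column_stack([np.ones_like(u), u])
    if df == 3:
        return np.column_stack([np.ones_like(u), u, u * u])
    return BSpline.design_matrix(u, knots, 3, extrapolate=True).toarray()


def _knots_for(u: np.ndarray, df: int) -> Optional[np.ndarray]:
    if df < 4:
        return None
    lo, hi = float(u.min()), float(u.max())
    n_int = df - 4
    interior = (
        np.quantile(u, np.linspace(0, 1, n_int + 2)[1:-1]) if n_int > 0 else np.array([])
    )
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


# --------------------------------------------------------------------------
# likelihood


def _nll_and_grad(theta, lny, Bl, Bm, Bs):
    nl, nm = Bl.shape[1], Bm.shape[1]
    a, b, c = theta[:nl], theta[nl : nl + nm], theta[nl + nm :]
    L = Bl @ a
    lnM = Bm @ b
    lnS = np.clip(Bs @ c, -30.0, 30.0)
    S = np.exp(lnS)
    u = lny - lnM
    Lu = np.clip(L * u, -200.0, 200.0)
    eLu = np.exp(Lu)
    small = np.abs(L) < _L_EPS
    Lsafe = np.where(small, 1.0, L)
    z = np.where(small, u / S * (1.0 + Lu / 2.0), (eLu - 1.0) / (Lsafe * S))
    dz_dL = np.where(small, u * u / (2.0 * S), u * eLu / (Lsafe * S) - z / Lsafe)

    ll = -0.5 * z * z + L * u - lnS
    dl_dL = -z * dz_dL + u
    dl_dlnM = z * eLu / S - L
    dl_dlnS = z * z - 1.0

    nll = -float(np.sum(ll))
    grad = -np.concatenate([Bl.T @ dl_dL, Bm.T @ dl_dlnM, Bs.T @ dl_dlnS])
    if not np.isfinite(nll):
        nll = 1e12
        grad = np.zeros_like(grad)
    return nll, grad


def _fit_at_complexity(lny, u, edf, init_curves=None):
    """ML fit at fixed (edf_L, edf_M, edf_S); returns curves-evaluator + deviance."""
    dl, dm, ds = edf
    kl, km, ks = (_knots_for(u, d) for d in edf)
    Bl, Bm, Bs = _basis(u, dl, kl), _basis(u, dm, km), _basis(u, ds, ks)

    def proj(B, target):
        coef, *_ = np.linalg.lstsq(B, target, rcond=None)
        return coef

    if init_curves is None:
        b0 = proj(Bm, lny)
        resid = lny - Bm @ b0
        s0 = max(float(np.std(resid)), 1e-4)
        c0 = proj(Bs, np.full_like(lny, math.log(s0)))
        a0 = proj(Bl, np.ones_like(lny))  # Cole convention: start untransformed
    else:
        L_prev, lnM_prev, lnS_prev = init_curves
        a0, b0, c0 = proj(Bl, L_prev), proj(Bm, lnM_prev), proj(Bs, lnS_prev)
    theta0 = np.concatenate([a0, b0, c0])

    res = optimize.minimize(
        _nll_and_grad,
        theta0,
        args=(lny, Bl, Bm, Bs),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 400, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError(f"LMS fit diverged at edf={edf}", trace=res)
    nl, nm = Bl.shape[1], Bm.shape[1]
    a, b, c = res.x[:nl], res.x[nl : nl + nm], res.x[nl + nm :]

    def curves(u_query: np.ndarray):
        Blq = _basis(u_query, dl, kl)
        Bmq = _basis(u_query, dm, km)
        Bsq = _basis(u_query, ds, ks)
        return Blq @ a, Bmq @ b, Bsq @ c  # L, lnM, lnS

    deviance = 2.0 * float(res.fun)
    return curves, deviance, res


# --------------------------------------------------------------------------
# reference object


@dataclass
class LMSReference:
    """Per-sex, per-trait reference: L, M, S sampled on an age grid.

    Queries at arbitrary ages inside the grid use monotone (PCHIP)
    interpolation; extrapolation beyond the grid is refused.
    """

    trait: str
    sex: Sex
    age_grid: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if not np.all(np.diff(self.age_grid) > 0):
            raise DomainError("age grid must be strictly increasing")
        if np.any(self.M <= 0) or np.any(self.S <= 0):
            raise DomainError("M and S must be positive everywhere")
        self._interp = None

    @property
    def support(self) -> tuple[float, float]:
        return float(self.age_grid[0]), float(self.age_grid[-1])

    def curves_at(self, age):
        """(L, M, S) at ``age`` (scalar or array); refuses extrapolation."""
        age = np.asarray(age, dtype=float)
        lo, hi = self.support
        tol = 1e-6  # years; absorbs serialisation rounding at the boundary
        if np.any(age < lo - tol) or np.any(age > hi + tol):
            raise ExtrapolationError(
                f"age outside reference support [{lo:g}, {hi:g}] for {self.trait}/{self.sex.value}"
            )
        age = np.clip(age, lo, hi)
        if self._interp is None:
            self._interp = (
                PchipInterpolator(self.age_grid, self.L),
                PchipInterpolator(self.age_grid, self.M),
                PchipInterpolator(self.age_grid, self.S),
            )
        fl, fm, fs = self._interp
        return fl(age), fm(age), fs(age)


# --------------------------------------------------------------------------
# fitting with complexity selection


def _total_edf(edf) -> int:
    return int(sum(edf))


def fit_lms(
    values,
    ages,
    sex: Sex,
    trait: str = "trait",
    complexity_grid: Optional[Sequence[tuple[int, int, int]]] = None,
    edf_range: Sequence[int] = DEFAULT_EDF_RANGE,
    grid_points: int = 161,
    min_n: int = 50,
) -> LMSReference:
    """Fit an LMS reference for one trait in one sex.

    Parameters
    ----------
    values, ages:
        Positive trait measurements and decimal ages of one sex's sample.
    complexity_grid:
        Explicit candidate (edf_L, edf_M, edf_S) triples, walked in order
        with the ln(N)-per-unit deviance rule. When omitted, a greedy
        search grows M, then S, then L one degree of freedom at a time
        over ``edf_range``, accepting a step only if the deviance falls
        by more than ln(N).
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(ages, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise DomainError("values and ages must be equal-length 1-D arrays")
    if y.size < min_n:
        raise DomainError(f"need at least {min_n} observations, got {y.size}")
    if np.any(y <= 0):
        raise DomainError("Box-Cox LMS requires strictly positive values")
    n = y.size
    lny = np.log(y)
    t_mean, t_sd = float(t.mean()), float(t.std())
    t_sd = t_sd if t_sd > 0 else 1.0
    u = (t - t_mean) / t_sd
    ln_n = math.log(n)

    trace: list[dict] = []

    def fit(edf, init=None):
        curves, dev, res = _fit_at_complexity(lny, u, edf, init)
        return curves, dev, res

    if complexity_grid is not None:
        best = None
        for edf in complexity_grid:
            edf = tuple(int(d) for d in edf)
            curves, dev, _ = fit(edf)
            if best is None:
                accepted, why = True, "first candidate"
            else:
                d_complex = _total_edf(edf) - _total_edf(best[0])
                gain = best[1] - dev
                if d_complex > 0:
                    accepted = gain > ln_n * d_complex
                    why = f"deviance gain {gain:.2f} vs {ln_n * d_complex:.2f} required"
                else:
                    accepted = dev < best[1]
                    why = "lower deviance at no extra complexity"
            trace.append({"edf": edf, "deviance": dev, "accepted": accepted, "reason": why})
            if accepted:
                best = (edf, dev, curves)
        edf_sel, dev_sel, curves_sel = best
    else:
        edf_range = sorted(set(int(d) for d in edf_range))
        edf_cur = [edf_range[0]] * 3  # (L, M, S)
        curves_cur, dev_cur, _ = fit(tuple(edf_cur))
        trace.append(
            {"edf": tuple(edf_cur), "deviance": dev_cur, "accepted": True, "reason": "baseline"}
        )
        # Greedy growth: M (index 1) first, then S (2), then L (0).
        for idx in (1, 2, 0):
            for d in edf_range[1:]:
                cand = list(edf_cur)
                cand[idx] = d
                init = curves_cur(u)
                curves_new, dev_new, _ = fit(tuple(cand), init)
                gain = dev_cur - dev_new
                step = _total_edf(cand) - _total_edf(edf_cur)
                accepted = gain > ln_n * step
                trace.append(
                    {
                        "edf": tuple(cand),
                        "deviance": dev_new,
                        "accepted": accepted,
                        "reason": f"deviance gain {gain:.2f} vs {ln_n * step:.2f} required",
                    }
                )
                if not accepted:
                    break
                edf_cur, dev_cur, curves_cur = cand, dev_new, curves_new
        edf_sel, dev_sel, curves_sel = tuple(edf_cur), dev_cur, curves_cur

    grid_t = np.linspace(t.min(), t.max(), grid_points)
    grid_u = (grid_t - t_mean) / t_sd
    Lg, lnMg, lnSg = curves_sel(grid_u)
    ref = LMSReference(
        trait=trait,
        sex=sex,
        age_grid=grid_t,
        L=Lg,
        M=np.exp(lnMg),
        S=np.exp(lnSg),
        fit_meta={
            "n": n,
            "deviance": dev_sel,
            "edf": {"L": edf_sel[0], "M": edf_sel[1], "S": edf_sel[2]},
            "ln_n": ln_n,
            "trace": trace,
        },
    )
    # Self-calibration diagnostics on the fitting sample.
    z = to_sds(y, t, ref)
    ref.fit_meta["sample_z_mean"] = float(np.mean(z))
    ref.fit_meta["sample_z_sd"] = float(np.std(z, ddof=1))
    return ref


def fit_references(
    frame: pd.DataFrame,
    traits: Sequence[str],
    age_col: str = "age_y",
    sex_col: str = "sex",
    **fit_kwargs,
) -> dict[tuple[str, Sex], LMSReference]:
    """Fit per-sex references for each trait column of a tidy frame."""
    refs: dict[tuple[str, Sex], LMSReference] = {}
    for trait in traits:
        for sex in (Sex.MALE, Sex.FEMALE):
            sub = frame[frame[sex_col] == sex.value].dropna(subset=[trait, age_col])
            refs[(trait, sex)] = fit_lms(
                sub[trait].to_numpy(), sub[age_col].to_numpy(), sex, trait, **fit_kwargs
            )
    return refs


# --------------------------------------------------------------------------
# SDS and centiles


def to_sds(value, age, ref: LMSReference):
    """Standard deviation score of ``value`` at ``age`` under ``ref``.

    Continuous in L at 0 (log-limit branch). Scalar in, scalar out.
    """
    value = np.asarray(value, dtype=float)
    scalar = value.ndim == 0
    value = np.atleast_1d(value)
    if np.any(value <= 0):
        raise DomainError("SDS conversion requires positive values")
    L, M, S = (np.atleast_1d(c) for c in ref.curves_at(np.atleast_1d(np.asarray(age, float))))
    ratio = value / M
    small = np.abs(L) < _L_EPS
    Lsafe = np.where(small, 1.0, L)
    z = np.where(
        small,
        np.log(ratio) / S,
        (np.power(ratio, L) - 1.0) / (Lsafe * S),
    )
    return float(z[0]) if scalar else z


def centile_curve(ref: LMSReference, p: float, ages) -> np.ndarray:
    """Trait values of the p-th centile at ``ages``.

    Where the Box-Cox inverse is undefined (1 + L*S*z_p <= 0) the curve
    has a gap, returned as NaN rather than raising.
    """
    if not (0.0 < p < 100.0):
        raise DomainError("percentile must be in (0, 100)")
    zp = norm.ppf(p / 100.0)
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    L, M, S = (np.atleast_1d(c) for c in ref.curves_at(ages))
    small = np.abs(L) < _L_EPS
    Lsafe = np.where(small, 1.0, L)
    base = 1.0 + L * S * zp
    with np.errstate(invalid="ignore"):
        vals = np.where(
            small,
            M * np.exp(S * zp),
            np.where(base > 0, M * np.power(np.where(base > 0, base, 1.0), 1.0 / Lsafe), np.nan),
        )
    return vals


DEFAULT_CENTILES = (3, 10, 25, 50, 75, 90, 97)


def centile_table(ref: LMSReference, percentiles=DEFAULT_CENTILES) -> pd.DataFrame:
    """Tidy centile curves on the reference grid (columns age, p3..p97)."""
    out = {"age_y": ref.age_grid}
    for p in percentiles:
        out[f"p{p:g}"] = centile_curve(ref, p, ref.age_grid)
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# serialisation: CSV with columns trait, sex, age_y, L, M, S


def write_reference(refs, path) -> None:
    """Write one or several references to a single CSV table."""
    if isinstance(refs, LMSReference):
        refs = [refs]
    frames = []
    for ref in refs:
        frames.append(
            pd.DataFrame(
                {
                    "trait": ref.trait,
                    "sex": ref.sex.value,
                    "age_y": ref.age_grid,
                    "L": ref.L,
                    "M": ref.M,
                    "S": ref.S,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_reference(path) -> list[LMSReference]:
    """Read references from CSV; malformed tables raise ParseError."""
    frame = pd.read_csv(path)
    required = {"trait", "sex", "age_y", "L", "M", "S"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: reference table must have columns {sorted(required)}")
    refs = []
    for (trait, sex_code), grp in frame.groupby(["trait", "sex"], sort=False):
        grp = grp.reset_index()
        bad_rows = list(grp.index[np.r_[False, np.diff(grp["age_y"].to_numpy()) <= 0]])
        bad_rows += list(grp.index[(grp["M"] <= 0) | (grp["S"] <= 0)])
        if bad_rows:
            raise ParseError(
                f"{path}: non-monotone ages or nonpositive M/S for {trait}/{sex_code}",
                rows=sorted(set(int(i) for i in bad_rows)),
            )
        try:
            sex = Sex(str(sex_code))
        except ValueError:
            raise ParseError(f"{path}: unknown sex code {sex_code!r}") from None
        refs.append(
            LMSReference(
                trait=str(trait),
                sex=sex,
                age_grid=grp["age_y"].to_numpy(),
                L=grp["L"].to_numpy(),
                M=grp["M"].to_numpy(),
                S=grp["S"].to_numpy(),
                fit_meta={"source": str(path)},
            )
        )
    return refs
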