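"""Bivariate statistics on the RXc plane.

A population's (R/H, Xc/H) vectors form an elliptical cloud. Two ellipse
families are used: the *confidence* ellipse, a region for the group MEAN
vector, and the *tolerance* ellipse, a region expected to contain a stated
fraction of INDIVIDUAL vectors. Both share the sample covariance
eigen-structure and differ only in scale; exact small-sample F-based
scalings are used by default, with the large-sample chi-square variant
behind a flag for cross-checking against other BIVA software.

Group mean vectors are compared with the two-sample Hotelling T^2 test
(pooled covariance), the bivariate generalisation of the t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import chi2, f as f_dist

from .errors import ConfigurationError, DegenerateGeometryError, DomainError

__all__ = [
    "EllipseSpec",
    "HotellingResult",
    "confidence_ellipse",
    "tolerance_ellipse",
    "hotelling_two_sample",
    "ellipse_polygon",
    "ellipse_contains",
    "rxc_plot",
]

_P = 2  # bivariate throughout


@dataclass(frozen=True)
class EllipseSpec:
    """Centre, semi-axes, orientation and coverage level of an ellipse.

    ``orientation`` is the angle of the semi-major axis from the positive
    x-axis, reported in [0, 180) degrees; the circular case reports 0.
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float  # degrees in [0, 180)
    level: float
    kind: str  # "confidence" | "tolerance"
    n: int

    @property
    def area(self) -> float:
        return math.pi * self.semi_major * self.semi_minor


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    mean_difference: tuple[float, float]


def _eigen_sorted(cov: np.ndarray):
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def _sample_stats(points) -> tuple[np.ndarray, np.ndarray, int]:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != _P:
        raise DomainError("expected an (n, 2) array of bivariate points")
    n = pts.shape[0]
    if n < 4:
        raise DomainError("need at least 4 points")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.det(cov) <= 0 or not np.all(np.isfinite(cov)):
        raise DegenerateGeometryError("singular sample covariance")
    return mean, cov, n


def _orientation_deg(evals, evecs) -> float:
    if np.isclose(evals[0], evals[1]):
        return 0.0
    vx, vy = evecs[:, 0]
    ang = math.degrees(math.atan2(vy, vx)) % 180.0
    return ang


def _build_ellipse(points, level, kind, chi2_scaling) -> EllipseSpec:
    if not (0.0 < level < 1.0):
        raise DomainError("level must be in (0, 1)")
    mean, cov, n = _sample_stats(points)
    evals, evecs = _eigen_sorted(cov)
    if chi2_scaling:
        q = chi2.ppf(level, _P)
        scale = q / n if kind == "confidence" else q
    else:
        q = f_dist.ppf(level, _P, n - _P)
        if kind == "confidence":
            scale = _P * (n - 1) / (n * (n - _P)) * q
        else:
            scale = _P * (n * n - 1) / (n * (n - _P)) * q
    semi = np.sqrt(evals * scale)
    return EllipseSpec(
        center=(float(mean[0]), float(mean[1])),
        semi_major=float(semi[0]),
        semi_minor=float(semi[1]),
        orientation=_orientation_deg(evals, evecs),
        level=float(level),
        kind=kind,
        n=n,
    )


def confidence_ellipse(points, level: float = 0.95, chi2_scaling: bool = False) -> EllipseSpec:
    """Ellipse for the group MEAN vector at the given coverage level."""
    return _build_ellipse(points, level, "confidence", chi2_scaling)


def tolerance_ellipse(points, level: float = 0.95, chi2_scaling: bool = False) -> EllipseSpec:
    """Ellipse expected to contain ``level`` of INDIVIDUAL vectors."""
    return _build_ellipse(points, level, "tolerance", chi2_scaling)


def ellipse_polygon(spec: EllipseSpec, num: int = 361) -> np.ndarray:
    """(num, 2) polygon tracing the ellipse, for plotting and containment."""
    theta = np.linspace(0.0, 2.0 * math.pi, num)
    ang = math.radians(spec.orientation)
    rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
    xy = np.column_stack([spec.semi_major * np.cos(theta), spec.semi_minor * np.sin(theta)])
    return xy @ rot.T + np.asarray(spec.center)


def ellipse_contains(spec: EllipseSpec, points) -> np.ndarray:
    """Boolean mask of points inside (or on) the ellipse."""
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(spec.center)
    ang = math.radians(spec.orientation)
    rot = np.array([[math.cos(ang), math.sin(ang)], [-math.sin(ang), math.cos(ang)]])
    local = pts @ rot.T
    return (local[:, 0] / spec.semi_major) ** 2 + (local[:, 1] / spec.semi_minor) ** 2 <= 1.0 + 1e-12


def hotelling_two_sample(group_a, group_b) -> HotellingResult:
    """Two-sample Hotelling T^2 with pooled covariance (p = 2).

    T^2 = (n1 n2 / (n1 + n2)) d' S_pooled^{-1} d, with d the mean
    difference; the F transform is ((n1+n2-p-1) / (p (n1+n2-2))) T^2 on
    (p, n1+n2-p-1) degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for g in (a, b):
        if g.ndim != 2 or g.shape[1] != _P:
            raise DomainError("expected (n, 2) arrays")
        if g.shape[0] < 3:
            raise DomainError("each group needs at least 3 points")
    n1, n2 = a.shape[0], b.shape[0]
    d = a.mean(axis=0) - b.mean(axis=0)
    s_pooled = ((n1 - 1) * np.cov(a, rowvar=False, ddof=1) + (n2 - 1) * np.cov(b, rowvar=False, ddof=1)) / (
        n1 + n2 - 2
    )
    det = np.linalg.det(s_pooled)
    if not np.isfinite(det) or det <= 0:
        raise DegenerateGeometryError("singular pooled covariance")
    t2 = float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(s_pooled, d))
    df2 = n1 + n2 - _P - 1
    f_stat = (df2 / (_P * (n1 + n2 - 2))) * t2
    p_value = float(f_dist.sf(f_stat, _P, df2))
    return HotellingResult(
        t2=t2,
        f_stat=float(f_stat),
        df=(_P, df2),
        p_value=p_value,
        mean_difference=(float(d[0]), float(d[1])),
    )


def rxc_plot(
    groups: Mapping[str, np.ndarray],
    ellipses: Optional[Mapping[str, Sequence[EllipseSpec] | EllipseSpec]] = None,
    axes_mode: str = "sds",
    path=None,
    title: Optional[str] = None,
):
    """Plot group mean vectors and their ellipses on the RXc plane.

    ``axes_mode`` is ``"raw"`` (ohm/m axes) or ``"sds"``; all groups must
    share it — the two scales cannot be mixed on one plot. Returns the
    matplotlib figure; writes it to ``path`` when given. Deterministic for
    identical inputs.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if axes_mode not in ("raw", "sds"):
        raise ConfigurationError(f"unknown axes_mode {axes_mode!r}")
    if not groups:
        raise ConfigurationError("no groups to plot")

    fig, ax = plt.subplots(figsize=(6, 6))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, (label, pts) in enumerate(groups.items()):
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ConfigurationError(f"group {label!r}: expected (n, 2) points")
        color = colors[i % len(colors)]
        mean = pts.mean(axis=0)
        ax.plot(*mean, marker="o", color=color, label=label)
        specs = (ellipses or {}).get(label, [])
        if isinstance(specs, EllipseSpec):
            specs = [specs]
        for spec in specs:
            poly = ellipse_polygon(spec)
            ax.plot(poly[:, 0], poly[:, 1], color=color, lw=1.2)
    if axes_mode == "raw":
        ax.set_xlabel("R/H (Ω/m)")
        ax.set_ylabel("Xc/H (Ω/m)")
    else:
        ax.set_xlabel("R/H (SDS)")
        ax.set_ylabel("Xc/H (SDS)")
    ax.legend(loc="best", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150, metadata={"Software": None})
    return fig
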