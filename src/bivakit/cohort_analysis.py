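"""Cohort-level statistics on SDS data.

Operates on a tidy table of per-subject standard deviation scores for the
seven traits (phase angle, R/H, Xc/H, BMI, fat-free mass, fat mass, FFM
hydration): category construction on an SDS column, whole-cohort and
subgroup Pearson correlation matrices, multiple regression on SDS columns,
pairwise group contrasts with Bonferroni correction, and the dummy-plus-
interaction regression testing whether the Xc/H-on-R/H slope differs
between groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import CollinearityError, DomainError

__all__ = [
    "SDS_COLUMNS",
    "CategoryScheme",
    "FFM_SDS_SCHEME",
    "HFFM_SDS_SCHEME",
    "TermEstimate",
    "RegressionResult",
    "categorize",
    "correlation_matrix",
    "standardized_regression",
    "group_contrasts",
    "slope_heterogeneity",
]

#: Canonical SDS column order (matches the trait correlation matrix order).
SDS_COLUMNS = ["pa_sds", "rh_sds", "xch_sds", "bmi_sds", "ffm_sds", "fm_sds", "hffm_sds"]


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered interval partition of an SDS column.

    ``boundary_rule`` is ``"right_closed"`` ((a, b] intervals, the default)
    or ``"left_closed"`` ([a, b)); outermost intervals are open-ended, so
    every value receives exactly one label.
    """

    variable: str
    cut_points: tuple[float, ...]
    labels: tuple[str, ...]
    boundary_rule: str = "right_closed"

    def __post_init__(self):
        if list(self.cut_points) != sorted(set(self.cut_points)):
            raise DomainError("cut points must be strictly increasing")
        if len(self.labels) != len(self.cut_points) + 1:
            raise DomainError("need exactly one more label than cut points")
        if self.boundary_rule not in ("right_closed", "left_closed"):
            raise DomainError(f"unknown boundary rule {self.boundary_rule!r}")


#: Five fat-free-mass SDS bands: < -1, -1..0, 0..0.75, 0.75..1.5, > 1.5.
FFM_SDS_SCHEME = CategoryScheme(
    variable="ffm_sds",
    cut_points=(-1.0, 0.0, 0.75, 1.50),
    labels=("FFM1", "FFM2", "FFM3", "FFM4", "FFM5"),
)

#: Five FFM-hydration SDS bands: < -1, -1..-0.5, -0.5..0, 0..1, > 1.
HFFM_SDS_SCHEME = CategoryScheme(
    variable="hffm_sds",
    cut_points=(-1.0, -0.5, 0.0, 1.0),
    labels=("H1", "H2", "H3", "H4", "H5"),
)


def categorize(table: pd.DataFrame, scheme: CategoryScheme) -> tuple[pd.Series, pd.Series]:
    """Assign every row exactly one group label; returns (labels, counts).

    Counts include empty groups and always sum to the number of rows.
    """
    if scheme.variable not in table.columns:
        raise DomainError(f"column {scheme.variable!r} not in table")
    values = table[scheme.variable]
    if values.isna().any():
        raise DomainError(f"column {scheme.variable!r} has missing values")
    bins = [-np.inf, *scheme.cut_points, np.inf]
    labels = pd.cut(
        values,
        bins=bins,
        labels=list(scheme.labels),
        right=(scheme.boundary_rule == "right_closed"),
    )
    labels = labels.astype(pd.CategoricalDtype(list(scheme.labels), ordered=True))
    counts = labels.value_counts(sort=False)
    return labels, counts


def correlation_matrix(
    table: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    subgroup: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise Pearson correlations with two-sided p-values.

    ``subgroup`` is an optional boolean row mask (e.g. a narrow age band).
    Returns (r matrix, p matrix, flagged columns); zero-variance columns
    are flagged and their entries left undefined (NaN) rather than silent.
    """
    cols = list(columns) if columns is not None else [c for c in SDS_COLUMNS if c in table.columns]
    data = table.loc[subgroup, cols] if subgroup is not None else table[cols]
    data = data.dropna()
    if len(data) < 3:
        raise DomainError("need at least 3 complete rows")
    flagged = [c for c in cols if np.isclose(data[c].std(ddof=1), 0.0)]
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for ca, cb in itertools.combinations(cols, 2):
        if ca in flagged or cb in flagged:
            r.loc[ca, cb] = r.loc[cb, ca] = np.nan
            p.loc[ca, cb] = p.loc[cb, ca] = np.nan
            continue
        res = stats.pearsonr(data[ca], data[cb])
        r.loc[ca, cb] = r.loc[cb, ca] = res.statistic
        p.loc[ca, cb] = p.loc[cb, ca] = res.pvalue
    for c in flagged:
        r.loc[c, c] = np.nan
    return r, p, flagged


@dataclass(frozen=True)
class TermEstimate:
    name: str
    coefficient: float
    standard_error: float
    p_value: float


@dataclass
class RegressionResult:
    outcome: str
    terms: list[TermEstimate]
    r2: float
    n: int
    model: object = field(default=None, repr=False)

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _ols(y: np.ndarray, X: pd.DataFrame, outcome: str) -> RegressionResult:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # Name columns whose removal restores full rank.
        offenders = [
            c
            for c in X.columns
            if c != "const"
            and np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank
        ]
        raise CollinearityError(offenders or list(X.columns))
    fit = sm.OLS(y, X).fit()
    terms = [
        TermEstimate(name, float(fit.params[name]), float(fit.bse[name]), float(fit.pvalues[name]))
        for name in X.columns
    ]
    return RegressionResult(outcome=outcome, terms=terms, r2=float(fit.rsquared), n=int(fit.nobs), model=fit)


def standardized_regression(
    table: pd.DataFrame, outcome: str, predictors: Sequence[str]
) -> RegressionResult:
    """OLS of one SDS column on others, coefficients on the SDS scale.

    SDS columns are already standardised by construction, so no
    re-scaling is applied; the intercept is reported as ``const``.
    """
    cols = [outcome, *predictors]
    data = table[cols].dropna()
    if len(data) <= len(predictors) + 1:
        raise DomainError("too few complete rows for the requested model")
    X = sm.add_constant(data[list(predictors)])
    return _ols(data[outcome].to_numpy(), X, outcome)


def group_contrasts(
    table: pd.DataFrame,
    outcome: str,
    groups: pd.Series,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise group mean contrasts with Bonferroni-adjusted p-values.

    Pooled-variance t tests by default (the classic ANOVA follow-up);
    ``equal_var=False`` switches to Welch. Adjusted p = min(1, p * n_pairs).
    Singleton groups yield an undefined (NaN) p-value and a flag, never a
    silent drop.
    """
    groups = groups.loc[table.index]
    levels = [g for g in groups.cat.categories] if hasattr(groups, "cat") else sorted(groups.unique())
    present = [g for g in levels if (groups == g).sum() > 0]
    if len(present) < 2:
        raise DomainError("need at least two non-empty groups")
    pairs = list(itertools.combinations(present, 2))
    rows = []
    for ga, gb in pairs:
        a = table.loc[groups == ga, outcome].dropna().to_numpy()
        b = table.loc[groups == gb, outcome].dropna().to_numpy()
        diff = float(a.mean() - b.mean()) if len(a) and len(b) else np.nan
        if len(a) < 2 or len(b) < 2:
            rows.append((ga, gb, len(a), len(b), diff, np.nan, np.nan, False, "singleton group"))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        p_adj = min(1.0, float(p) * len(pairs))
        rows.append((ga, gb, len(a), len(b), diff, float(p), p_adj, p_adj < alpha, ""))
    return pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "n_a", "n_b", "mean_diff", "p_raw", "p_bonferroni", "significant", "flag"],
    )


def slope_heterogeneity(
    table: pd.DataFrame,
    y: str,
    x: str,
    groups: pd.Series,
    reference: Optional[str] = None,
    min_group_size: int = 3,
) -> RegressionResult:
    """Test whether the y-on-x slope differs between groups.

    Fits y ~ x + group dummies + x:group interactions with the reference
    group (largest by default) absorbed into the baseline. Groups smaller
    than ``min_group_size`` are excluded from dummy/interaction coding and
    noted on the result via the ``excluded_groups`` attribute.
    """
    groups = groups.loc[table.index].astype(str)
    counts = groups.value_counts()
    usable = [g for g in counts.index if counts[g] >= min_group_size]
    excluded = [g for g in counts.index if counts[g] < min_group_size]
    if len(usable) < 2:
        raise DomainError("need at least two groups of usable size")
    ref = reference if reference is not None else counts[usable].idxmax()
    if ref not in usable:
        raise DomainError(f"reference group {ref!r} too small or absent")
    mask = groups.isin(usable)
    data = table.loc[mask, [y, x]].dropna()
    g = groups.loc[data.index]

    X = pd.DataFrame({"const": 1.0, x: data[x]}, index=data.index)
    for level in sorted(set(usable) - {ref}):
        dummy = (g == level).astype(float)
        X[f"group[{level}]"] = dummy
        X[f"{x}:group[{level}]"] = dummy * data[x]
    result = _ols(data[y].to_numpy(), X, y)
    result.excluded_groups = excluded
    result.reference_group = ref
    return result
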