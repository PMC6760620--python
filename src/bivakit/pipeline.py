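"""End-to-end orchestration: cohort CSV in, SDS analyses and charts out.

Stages: read -> QC -> vectors -> 4C composition -> LMS references (fitted
from the cohort, or ingested from a reference CSV) -> SDS -> categories ->
correlations / regressions / contrasts / slope heterogeneity -> ellipses
and centile charts. A machine-readable run report (JSON) records stage
counts, settings and every artifact path; rerunning with identical inputs
reproduces identical numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .biva_core import QCThresholds, compute_vector, qc_filter
from .body_composition import FourComponentCoefficients, FULLER_4C, compose_table
from .cohort_analysis import (
    FFM_SDS_SCHEME,
    HFFM_SDS_SCHEME,
    categorize,
    correlation_matrix,
    group_contrasts,
    slope_heterogeneity,
    standardized_regression,
)
from .cohort_io import CohortTable, Sex, read_cohort
from .errors import BivakitError, PipelineError
from .lms_reference import (
    LMSReference,
    centile_table,
    fit_references,
    read_reference,
    to_sds,
    write_reference,
)
from .vector_geometry import confidence_ellipse, rxc_plot

__all__ = ["run_pipeline", "sds_table", "build_trait_frame"]

#: Traits standardised to SDS, mapped to their column in the trait frame.
TRAIT_COLUMNS = {
    "pa": "pa",
    "rh": "rh",
    "xch": "xch",
    "bmi": "bmi",
    "ffm": "ffm_kg",
    "fm": "fm_kg",
    "hffm": "h_ffm",
}


def build_trait_frame(table: CohortTable, coefficients: FourComponentCoefficients = FULLER_4C) -> pd.DataFrame:
    """Per-subject raw trait values (vector components + composition)."""
    return compose_table(table, coefficients=coefficients, include_vectors=True)


def sds_table(
    frame: pd.DataFrame,
    references: Mapping[tuple[str, Sex], LMSReference],
) -> pd.DataFrame:
    """Convert raw trait columns to SDS under per-sex references."""
    out = frame[["subject_id", "sex", "age_y"]].copy()
    for trait, col in TRAIT_COLUMNS.items():
        if col not in frame.columns:
            continue
        z = np.full(len(frame), np.nan)
        for sex in (Sex.MALE, Sex.FEMALE):
            mask = (frame["sex"] == sex.value).to_numpy() & frame[col].notna().to_numpy()
            if not mask.any():
                continue
            ref = references[(trait, sex)]
            z[mask] = to_sds(frame.loc[mask, col].to_numpy(), frame.loc[mask, "age_y"].to_numpy(), ref)
        out[f"{trait}_sds"] = z
    return out


def _qc_thresholds(config: Mapping) -> QCThresholds:
    qc = config.get("qc", {})
    return QCThresholds(
        pa_max=qc.get("pa_max", 8.0),
        pa_dup_max=qc.get("pa_dup_max", 0.5),
        rh_dup_max=qc.get("rh_dup_max", 6.0),
        xch_dup_max=qc.get("xch_dup_max", 6.0),
    )


def _coefficients(config: Mapping) -> FourComponentCoefficients:
    fc = config.get("four_component", {}).get("coefficients")
    if not fc:
        return FULLER_4C
    return FourComponentCoefficients(**fc)


def run_pipeline(
    cohort: CohortTable | str | Path,
    config: Optional[Mapping] = None,
    out_dir: str | Path = "results",
    make_plots: bool = True,
) -> dict:
    """Run the full analysis; returns the run report (also written as JSON).

    ``cohort`` is a CSV path or an in-memory :class:`CohortTable`;
    ``config`` mirrors the module configurations under the keys ``qc``,
    ``four_component``, ``lms`` and ``analysis``.
    """
    config = dict(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "settings": json.loads(json.dumps(config, default=str)),
        "counts": {},
        "outputs": {},
        "warnings": [],
    }

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except BivakitError as exc:
                _write_report(report, out)
                raise PipelineError(name, str(exc), report) from exc

        return wrap

    # --- read -------------------------------------------------------------
    if isinstance(cohort, (str, Path)):
        table = stage("read")(read_cohort, cohort, config.get("schema"))
    else:
        table = cohort
    report["counts"]["read"] = len(table) + len(table.provenance.rejects)
    report["counts"]["parsed"] = len(table)
    report["counts"]["parse_rejected"] = len(table.provenance.rejects)

    # --- QC ---------------------------------------------------------------
    partition = stage("qc")(qc_filter, table, _qc_thresholds(config))
    report["counts"]["qc_kept"] = len(partition.kept)
    report["counts"]["qc_excluded"] = len(partition.excluded)
    report["counts"]["qc_excluded_by_reason"] = partition.reasons_count()
    qc_path = out / "qc_exclusions.csv"
    pd.DataFrame(
        [(rec.subject_id, "; ".join(reasons)) for rec, reasons in partition.excluded],
        columns=["subject_id", "reasons"],
    ).to_csv(qc_path, index=False)
    report["outputs"]["qc_exclusions"] = str(qc_path)
    if len(partition.kept) == 0:
        _write_report(report, out)
        raise PipelineError("sds", "no records survived QC; nothing to standardise", report)

    # --- vectors + composition -------------------------------------------
    coeffs = _coefficients(config)
    frame = stage("composition")(build_trait_frame, partition.kept, coeffs)
    comp_path = out / "composition.csv"
    frame.to_csv(comp_path, index=False, float_format="%.8g")
    report["outputs"]["composition"] = str(comp_path)

    # --- LMS references ---------------------------------------------------
    lms_cfg = config.get("lms", {})
    traits = [t for t, col in TRAIT_COLUMNS.items() if col in frame.columns and frame[col].notna().any()]
    if lms_cfg.get("mode", "fit") == "reference":
        refs_list = stage("lms")(read_reference, lms_cfg["reference_path"])
        references = {(r.trait, r.sex): r for r in refs_list}
    else:
        fit_kwargs = {}
        if "min_n" in lms_cfg:
            fit_kwargs["min_n"] = lms_cfg["min_n"]
        if "edf_range" in lms_cfg:
            fit_kwargs["edf_range"] = lms_cfg["edf_range"]
        named = frame.rename(columns={v: k for k, v in TRAIT_COLUMNS.items() if v in frame.columns})
        references = stage("lms")(fit_references, named, traits, **fit_kwargs)
        ref_path = out / "lms_reference.csv"
        write_reference(list(references.values()), ref_path)
        report["outputs"]["lms_reference"] = str(ref_path)
    report["lms_fit"] = {
        f"{trait}/{sex.value}": {
            k: ref.fit_meta.get(k) for k in ("n", "deviance", "edf", "sample_z_mean", "sample_z_sd")
        }
        for (trait, sex), ref in references.items()
    }

    # --- SDS --------------------------------------------------------------
    sds = stage("sds")(sds_table, frame, references)
    sds_path = out / "sds.csv"
    sds.to_csv(sds_path, index=False, float_format="%.8g")
    report["outputs"]["sds"] = str(sds_path)
    report["counts"]["sds_rows"] = len(sds)

    # --- categories -------------------------------------------------------
    analysis_cfg = config.get("analysis", {})
    have_composition = {"ffm_sds", "hffm_sds"}.issubset(sds.columns) and sds["ffm_sds"].notna().all()
    groupings = {}
    if have_composition:
        for name, scheme in (("ffm", FFM_SDS_SCHEME), ("hffm", HFFM_SDS_SCHEME)):
            labels, counts = stage("categories")(categorize, sds, scheme)
            groupings[name] = labels
            report["counts"][f"{name}_groups"] = {str(k): int(v) for k, v in counts.items()}

    # --- correlations -----------------------------------------------------
    sds_cols = [c for c in sds.columns if c.endswith("_sds") and sds[c].notna().any()]
    r, p, flagged = stage("correlations")(correlation_matrix, sds, sds_cols)
    r_path, p_path = out / "correlations.csv", out / "correlation_pvalues.csv"
    r.to_csv(r_path, float_format="%.4f")
    p.to_csv(p_path, float_format="%.3g")
    report["outputs"]["correlations"] = str(r_path)
    report["outputs"]["correlation_pvalues"] = str(p_path)
    if flagged:
        report["warnings"].append(f"zero-variance SDS columns: {flagged}")

    # --- regressions, contrasts, slope heterogeneity ----------------------
    if have_composition:
        reg_specs = analysis_cfg.get(
            "regressions",
            [
                {"outcome": "ffm_sds", "predictors": ["rh_sds", "xch_sds", "pa_sds"]},
                {"outcome": "hffm_sds", "predictors": ["rh_sds", "xch_sds", "pa_sds"]},
                {"outcome": "rh_sds", "predictors": ["ffm_sds", "fm_sds", "hffm_sds"]},
                {"outcome": "xch_sds", "predictors": ["ffm_sds", "fm_sds", "hffm_sds"]},
                {"outcome": "pa_sds", "predictors": ["ffm_sds", "fm_sds", "hffm_sds"]},
            ],
        )
        reg_rows = []
        for spec in reg_specs:
            res = stage("regressions")(standardized_regression, sds, spec["outcome"], spec["predictors"])
            for term in res.terms:
                reg_rows.append(
                    (res.outcome, term.name, term.coefficient, term.standard_error, term.p_value, res.r2, res.n)
                )
        reg_path = out / "regressions.csv"
        pd.DataFrame(
            reg_rows, columns=["outcome", "term", "coefficient", "se", "p_value", "r2", "n"]
        ).to_csv(reg_path, index=False, float_format="%.6g")
        report["outputs"]["regressions"] = str(reg_path)

        contrast_frames = []
        for gname, labels in groupings.items():
            for outcome in ("pa_sds", "rh_sds", "xch_sds"):
                c = stage("contrasts")(group_contrasts, sds, outcome, labels)
                c.insert(0, "grouping", gname)
                c.insert(1, "outcome", outcome)
                contrast_frames.append(c)
        contrasts_path = out / "contrasts.csv"
        pd.concat(contrast_frames, ignore_index=True).to_csv(contrasts_path, index=False, float_format="%.6g")
        report["outputs"]["contrasts"] = str(contrasts_path)

        het_rows = []
        for gname, labels in groupings.items():
            res = stage("slope_heterogeneity")(slope_heterogeneity, sds, "xch_sds", "rh_sds", labels)
            for term in res.terms:
                het_rows.append((gname, term.name, term.coefficient, term.standard_error, term.p_value, res.r2))
        het_path = out / "slope_heterogeneity.csv"
        pd.DataFrame(
            het_rows, columns=["grouping", "term", "coefficient", "se", "p_value", "r2"]
        ).to_csv(het_path, index=False, float_format="%.6g")
        report["outputs"]["slope_heterogeneity"] = str(het_path)

        # --- ellipses -----------------------------------------------------
        level = analysis_cfg.get("ellipse_level", 0.95)
        ellipse_rows = []
        for gname, labels in groupings.items():
            specs = {}
            pts_by_group = {}
            for g in labels.cat.categories:
                pts = sds.loc[(labels == g).to_numpy(), ["rh_sds", "xch_sds"]].dropna().to_numpy()
                if len(pts) >= 4:
                    spec = stage("ellipses")(confidence_ellipse, pts, level)
                    specs[str(g)] = spec
                    pts_by_group[str(g)] = pts
                    ellipse_rows.append(
                        (gname, str(g), spec.center[0], spec.center[1], spec.semi_major,
                         spec.semi_minor, spec.orientation, spec.level, spec.n)
                    )
            if make_plots and pts_by_group:
                fig = rxc_plot(pts_by_group, specs, axes_mode="sds", path=out / f"ellipses_{gname}.png")
                import matplotlib.pyplot as plt

                plt.close(fig)
                report["outputs"][f"ellipse_plot_{gname}"] = str(out / f"ellipses_{gname}.png")
        ell_path = out / "ellipses.csv"
        pd.DataFrame(
            ellipse_rows,
            columns=["grouping", "group", "center_rh", "center_xch", "semi_major", "semi_minor",
                     "orientation_deg", "level", "n"],
        ).to_csv(ell_path, index=False, float_format="%.6g")
        report["outputs"]["ellipses"] = str(ell_path)

    # --- centile charts ---------------------------------------------------
    charts_dir = out / "centiles"
    charts_dir.mkdir(exist_ok=True)
    for (trait, sex), ref in references.items():
        tbl = centile_table(ref)
        tbl_path = charts_dir / f"{trait}_{sex.value}.csv"
        tbl.to_csv(tbl_path, index=False, float_format="%.6g")
    report["outputs"]["centile_tables"] = str(charts_dir)
    if make_plots:
        _centile_charts(references, charts_dir)
        report["outputs"]["centile_charts"] = str(charts_dir)

    _write_report(report, out)
    report["outputs"]["run_report"] = str(out / "run_report.json")
    return report


def _centile_charts(references, charts_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    traits = sorted({t for t, _ in references})
    for trait in traits:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, sex in zip(axes, (Sex.MALE, Sex.FEMALE)):
            ref = references.get((trait, sex))
            if ref is None:
                continue
            tbl = centile_table(ref)
            for col in tbl.columns[1:]:
                ax.plot(tbl["age_y"], tbl[col], lw=1, label=col)
            ax.set_title(f"{trait} — {sex.value}")
            ax.set_xlabel("age (y)")
        axes[0].set_ylabel(trait)
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(charts_dir / f"{trait}_centiles.png", dpi=120)
        plt.close(fig)


def _write_report(report: dict, out: Path) -> None:
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
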