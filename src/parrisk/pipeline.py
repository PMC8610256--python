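"""End-to-end orchestration: extract -> score -> stratify -> validate -> report.

All result tables are assembled in memory first and written together at the
end, so a failing stage leaves no partial output directory.  Stage-by-stage
record counts are logged (reconstructing the inclusion/exclusion cascade)
and recorded in the run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import ehr_features as ehr
from . import risk_strata as strata
from . import validation_stats as vstats
from .score_model import (
    ORIGINAL_THRESHOLDS,
    RiskThresholds,
    ScoreDefinition,
    assign_risk_group,
    bundled_score_definition,
    compute_raw_score,
)

__all__ = ["run_pipeline", "characteristics_table", "RunManifest", "PipelineResult"]

log = logging.getLogger("parrisk")

_OUTPUT_FILES = (
    "performance.csv", "calibration.csv", "strata.csv", "classification.csv",
    "observed_predicted.csv", "sensitivity.csv", "manifest.json",
)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    input_dir: str
    output_dir: str
    score_definition: str
    thresholds: dict[str, list[int]]
    seed: int | None
    software_version: str
    counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class PipelineResult:
    output_dir: Path
    tables: dict[str, pd.DataFrame]
    manifest: RunManifest


def _pct(x: float) -> float:
    return round(100.0 * x, 1)


def characteristics_table(
    predictors: pd.DataFrame,
    admissions: list[ehr.PatientAdmission],
    y: np.ndarray,
) -> pd.DataFrame:
    """Cohort summary: n and percentage per predictor and descriptive row."""
    n = len(predictors)
    if n == 0:
        raise ValueError("empty cohort: nothing to summarise")
    ages = np.array([a.age for a in admissions])
    sexes = np.array([a.sex for a in admissions])
    rows = [
        ("total_patients", n, None),
        ("par_cases", int(np.sum(y)), _pct(np.mean(y))),
        ("age_65_75", int(np.sum(ages <= 75)), _pct(np.mean(ages <= 75))),
        ("age_76_plus", int(np.sum(ages > 75)), _pct(np.mean(ages > 75))),
        ("male_sex", int(np.sum(sexes == "M")), _pct(np.mean(sexes == "M"))),
    ]
    for name in ehr.PREDICTOR_NAMES:
        col = predictors[name].to_numpy()
        rows.append((name, int(col.sum()), _pct(col.mean())))
    for name in ("potassium_missing",):
        col = predictors[name].to_numpy()
        rows.append((name, int(col.sum()), _pct(col.mean())))
    return pd.DataFrame(rows, columns=["characteristic", "n", "percent"])


def _scores_and_groups(
    predictors: pd.DataFrame,
    definition: ScoreDefinition,
    thresholds: RiskThresholds,
) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array(
        [
            compute_raw_score(dict(row), definition)
            for _, row in predictors[list(ehr.PREDICTOR_NAMES)].iterrows()
        ]
    )
    groups = np.array([assign_risk_group(int(s), thresholds) for s in scores])
    return scores, groups


def _threshold_report(
    label: str,
    thresholds: RiskThresholds,
    scores: np.ndarray,
    y: np.ndarray,
    fit: vstats.LogisticFit,
) -> tuple[list[dict], list[dict], list[dict]]:
    groups = np.array([assign_risk_group(int(s), thresholds) for s in scores])
    table = strata.build_strata_table(groups, y)
    try:
        ors = strata.group_odds_ratios(table)
    except ValueError as exc:
        log.warning("%s thresholds: %s; using continuity correction", label, exc)
        ors = strata.group_odds_ratios(table, continuity_correction=True)
    strata_rows = []
    for g in ("low", "medium", "high"):
        n_par, n_non = table.counts[g]
        if g == "low":
            or_, lo, hi = 1.0, np.nan, np.nan
        else:
            or_, lo, hi = ors[f"{g}_vs_low"]
        strata_rows.append(
            {
                "threshold_set": label, "group": g,
                "cut_low": thresholds.cut_low, "cut_high": thresholds.cut_high,
                "n_par": n_par, "n_nonpar": n_non,
                "odds_ratio": round(or_, 2),
                "ci_low": round(lo, 2) if np.isfinite(lo) else "",
                "ci_high": round(hi, 2) if np.isfinite(hi) else "",
            }
        )
    class_rows = []
    for g in ("medium", "high"):
        try:
            m = strata.pairwise_classification_metrics(table, g)
            row = {k: _pct(m[k]) for k in ("sensitivity", "specificity",
                                           "ppv", "npv")}
        except ValueError as exc:
            log.warning("%s thresholds, %s vs low: %s", label, g, exc)
            row = {k: "" for k in ("sensitivity", "specificity", "ppv", "npv")}
        class_rows.append(
            {"threshold_set": label, "comparison": f"{g}_vs_low", **row}
        )
    ovp = strata.observed_vs_predicted(table, groups, scores, fit=fit)
    ovp_rows = [
        {
            "threshold_set": label, "group": r.group, "n": r.n,
            "observed_pct": _pct(r.observed), "predicted_pct": _pct(r.predicted),
        }
        for r in ovp.itertuples(index=False)
    ]
    return strata_rows, class_rows, ovp_rows


def run_pipeline(
    input_dir: str | Path,
    output_dir: str | Path,
    *,
    score_definition: ScoreDefinition | None = None,
    score_definition_path: str | None = None,
    comorbidity_map: ehr.ComorbidityMap | None = None,
    thresholds: str = "both",            # original | adapted | both
    sensitivity: bool = True,
    seed: int | None = None,
) -> PipelineResult:
    """Run every stage on the CSV tables in ``input_dir``.

    The outcome label is read from ``outcomes.csv`` (columns ``patient_id``
    and ``par``): readmission adjudication itself is an upstream input, not
    part of the pipeline.  Writes the report tables and a manifest to
    ``output_dir`` only if every stage succeeds.
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    if thresholds not in ("original", "adapted", "both"):
        raise ValueError(f"unknown thresholds mode {thresholds!r}")
    definition = score_definition or bundled_score_definition()
    cmap = comorbidity_map or ehr.bundled_comorbidity_map()

    counts: dict[str, int] = {}
    admissions = ehr.load_cohort(input_dir)
    counts["loaded"] = len(admissions)
    log.info("loaded %d admissions", len(admissions))

    included = ehr.apply_inclusion(admissions)
    counts["after_inclusion"] = len(included)
    log.info("inclusion (age >= 65, stay >= 48 h): %d -> %d",
             len(admissions), len(included))

    retained, tally = ehr.apply_exclusion(included)
    for reason, k in tally.items():
        counts[f"excluded_{reason}"] = k
        log.info("excluded %-19s %d", reason, k)
    counts["final_cohort"] = len(retained)
    log.info("final cohort: %d", len(retained))

    outcome_df = pd.read_csv(input_dir / "outcomes.csv").set_index("patient_id")
    dispensing_missing = [
        a for a in included
        if a.disposition not in ("death", "transfer")
        and a.residency == "Swiss" and not a.dispensing_available
    ]

    predictors = ehr.extract_predictor_table(retained, cmap)
    y = outcome_df.loc[predictors.index, "par"].to_numpy()
    counts["par_cases"] = int(y.sum())

    scores, _ = _scores_and_groups(predictors, definition, ORIGINAL_THRESHOLDS)
    fit = vstats.fit_logistic(scores[:, None], y)
    c, c_lo, c_hi = vstats.c_statistic(scores, y)
    brier = vstats.brier_score(fit.fitted, y)
    gof_t, gof_z, gof_p = vstats.gof_unweighted_ss(fit)
    performance = pd.DataFrame(
        [
            {"statistic": "c_statistic", "estimate": round(c, 4),
             "ci_low": round(c_lo, 4), "ci_high": round(c_hi, 4)},
            {"statistic": "brier_score", "estimate": round(brier, 4),
             "ci_low": "", "ci_high": ""},
            {"statistic": "gof_T", "estimate": round(gof_t, 4),
             "ci_low": "", "ci_high": ""},
            {"statistic": "gof_z", "estimate": round(gof_z, 4),
             "ci_low": "", "ci_high": ""},
            {"statistic": "gof_p", "estimate": round(gof_p, 6),
             "ci_low": "", "ci_high": ""},
        ]
    )
    calibration = vstats.calibration_table(fit, scores, y)
    calibration["observed"] = calibration["observed"].round(6)
    calibration["predicted"] = calibration["predicted"].round(6)

    threshold_sets: dict[str, RiskThresholds] = {}
    if thresholds in ("original", "both"):
        threshold_sets["original"] = ORIGINAL_THRESHOLDS
    if thresholds in ("adapted", "both"):
        threshold_sets["adapted"] = strata.tertile_thresholds(scores)
        log.info("tertile-adapted thresholds: <%d / %d-%d / >%d",
                 threshold_sets["adapted"].cut_low,
                 threshold_sets["adapted"].cut_low,
                 threshold_sets["adapted"].cut_high,
                 threshold_sets["adapted"].cut_high)

    strata_rows: list[dict] = []
    class_rows: list[dict] = []
    ovp_rows: list[dict] = []
    for label, thr in threshold_sets.items():
        s_rows, c_rows, o_rows = _threshold_report(label, thr, scores, y, fit)
        strata_rows += s_rows
        class_rows += c_rows
        ovp_rows += o_rows

    sens_rows: list[dict] = []
    if sensitivity:
        variants = ehr.sensitivity_variants(predictors, dispensing_missing, cmap)
        for name, vdf in variants.items():
            v_scores, _ = _scores_and_groups(vdf, definition, ORIGINAL_THRESHOLDS)
            v_y = outcome_df.loc[vdf.index, "par"].to_numpy()
            vc, vlo, vhi = vstats.c_statistic(v_scores, v_y)
            sens_rows.append(
                {"variant": name, "n": len(vdf),
                 "c_statistic": round(vc, 4),
                 "ci_low": round(vlo, 4), "ci_high": round(vhi, 4)}
            )
            log.info("sensitivity %-18s n=%d C=%.3f", name, len(vdf), vc)

    characteristics = characteristics_table(predictors, retained, y)

    manifest = RunManifest(
        input_dir=str(input_dir),
        output_dir=str(output_dir),
        score_definition=score_definition_path or definition.label,
        thresholds={
            k: [v.cut_low, v.cut_high] for k, v in threshold_sets.items()
        },
        seed=seed,
        software_version=_pkg_version("parrisk"),
        counts=counts,
    )

    tables = {
        "performance": performance,
        "calibration": calibration,
        "strata": pd.DataFrame(strata_rows),
        "classification": pd.DataFrame(class_rows),
        "observed_predicted": pd.DataFrame(ovp_rows),
        "sensitivity": pd.DataFrame(
            sens_rows, columns=["variant", "n", "c_statistic", "ci_low", "ci_high"]
        ),
        "characteristics": characteristics,
    }

    # every stage succeeded: write everything
    output_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(output_dir / f"{name}.csv", index=False)
    manifest.write(output_dir / "manifest.json")
    return PipelineResult(output_dir=output_dir, tables=tables, manifest=manifest)
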