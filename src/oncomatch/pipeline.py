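"""End-to-end study orchestration: read/generate -> aggregate -> score ->
dichotomize -> outcome analysis, with a machine-readable output bundle."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .matching import compute_matching, write_matching_scores
from .outcomes import (
    cox_model,
    cr_durations,
    kaplan_meier,
    logrank_test,
    response_rates,
    survival_frame,
    write_cox_table,
    write_km_curves,
)
from .records import (
    PatientRecord,
    aggregate_treatments,
    best_response,
    inclusion_filter,
    read_cohort,
)
from .simulate import SyntheticCohortConfig, generate_cohort
from .stratify import dichotomize, write_groups

__all__ = ["AnalysisConfig", "StageError", "run_study", "make_baseline_table"]

log = logging.getLogger("oncomatch")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Inputs and decision flags for one full study run.

    Exactly one of ``cohort_dir`` (CSV inputs) or ``simulation`` must be
    supplied.
    """

    output_dir: str | Path = "results"
    cohort_dir: Optional[str | Path] = None
    simulation: Optional[SyntheticCohortConfig] = None
    dichotomization_method: str = "median"
    fixed_threshold: float = 50.0
    score_variant: str = "modified"  # "modified" | "standard"
    post_report_only: bool = True
    include_unscored: bool = True
    min_administrations: int = 3
    cr_relapse_categories: tuple[str, ...] = ("PD",)
    seed: int = 0

    def validate(self) -> None:
        if (self.cohort_dir is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of cohort_dir or simulation must be supplied")
        if self.score_variant not in ("modified", "standard"):
            raise ValueError(f"unknown score variant {self.score_variant!r}")


def _load_patients(config: AnalysisConfig) -> list[PatientRecord]:
    if config.cohort_dir is not None:
        d = Path(config.cohort_dir)
        return read_cohort(d / "reports.csv", d / "administrations.csv",
                           d / "responses.csv", d / "patients.csv")
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    patients, _ = generate_cohort(sim)
    return patients


def run_study(config: AnalysisConfig) -> dict:
    """Run the full analysis and write the output bundle.

    Writes matching_scores.csv, groups.csv, km_curves.csv, cox_table.csv,
    summary.json and run_log.json under ``config.output_dir`` and returns
    the summary dict.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        patients = _load_patients(config)
    except Exception as err:
        raise StageError("load", str(err)) from err
    log.info("loaded %d patients", len(patients))

    included, exclusions = inclusion_filter(
        patients, min_administrations=config.min_administrations)
    log.info("inclusion filter: %d kept, %d excluded",
             len(included), len(exclusions))

    results = {}
    try:
        for p in included:
            courses = aggregate_treatments(
                p.administrations, p.report.delivery_date,
                post_report_only=config.post_report_only)
            results[p.patient_id] = compute_matching(
                courses, p.report, include_unscored=config.include_unscored)
    except Exception as err:
        raise StageError("matching", str(err)) from err
    write_matching_scores(
        [results[p.patient_id] for p in included],
        outdir / "matching_scores.csv")

    attr = f"{config.score_variant}_score"
    scored, scores = [], {}
    for p in included:
        value = getattr(results[p.patient_id], attr)
        if value is None:
            exclusions.append(
                (p.patient_id, f"undefined {config.score_variant} score"))
        else:
            scored.append(p)
            scores[p.patient_id] = value

    try:
        outcome_data = {p.patient_id: (float(p.survival_days), bool(p.event))
                        for p in scored}
        ga = dichotomize(scores, method=config.dichotomization_method,
                         fixed_threshold=config.fixed_threshold,
                         outcome_data=outcome_data)
    except Exception as err:
        raise StageError("dichotomize", str(err)) from err
    write_groups(ga, scores, outdir / "groups.csv")

    try:
        curves = {}
        for label in ("low", "high"):
            ids = ga.group_ids(label)
            durs = [outcome_data[i][0] for i in ids]
            evts = [outcome_data[i][1] for i in ids]
            curves[label] = kaplan_meier(durs, evts)
        lr_stat, lr_p = logrank_test(
            [outcome_data[i][0] for i in ga.group_ids("low")],
            [outcome_data[i][1] for i in ga.group_ids("low")],
            [outcome_data[i][0] for i in ga.group_ids("high")],
            [outcome_data[i][1] for i in ga.group_ids("high")],
        )
        cr_curves = cr_durations(
            scored, ga.assignment,
            relapse_categories=config.cr_relapse_categories)
        responses = response_rates(
            ga.assignment,
            {p.patient_id: best_response(p) for p in scored})
        df = survival_frame(scored, ga.assignment)
        covariates = ["grade", "substage", "stage", "matching_group"]
        uni = cox_model(df, covariates, mode="univariate")
        multi = cox_model(df, covariates, mode="multivariate")
    except StageError:
        raise
    except Exception as err:
        raise StageError("outcomes", str(err)) from err

    write_km_curves({**{f"survival_{k}": v for k, v in curves.items()},
                     **{f"cr_duration_{k}": v for k, v in cr_curves.items()}},
                    outdir / "km_curves.csv")
    write_cox_table([*uni, multi], outdir / "cox_table.csv")

    group_hr = next(e for e in multi.effects if e.name == "matching_group")
    summary = {
        "n_input": len(patients),
        "n_included": len(scored),
        "n_excluded": len(exclusions),
        "score_variant": config.score_variant,
        "dichotomization": {
            "method": ga.method,
            "threshold": round(ga.threshold, 6),
            "n_low": ga.n_low,
            "n_high": ga.n_high,
        },
        "median_survival_days": {
            label: curves[label].median for label in ("low", "high")},
        "logrank": {"statistic": round(lr_stat, 6), "p": round(lr_p, 6)},
        "response": {
            "groups": responses.groups,
            "crr_fisher_p": responses.crr_fisher_p,
            "orr_fisher_p": responses.orr_fisher_p,
        },
        "median_cr_duration_days": {
            label: curve.median for label, curve in sorted(cr_curves.items())},
        "cox_multivariate_matching_group": {
            "hr": round(group_hr.hr, 6),
            "ci": [round(group_hr.ci_low, 6), round(group_hr.ci_high, 6)],
            "p": round(group_hr.p, 8),
            "concordance": round(multi.concordance, 6),
        },
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")

    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "flags": {
            "dichotomization_method": config.dichotomization_method,
            "fixed_threshold": config.fixed_threshold,
            "score_variant": config.score_variant,
            "post_report_only": config.post_report_only,
            "include_unscored": config.include_unscored,
            "min_administrations": config.min_administrations,
            "cr_relapse_categories": list(config.cr_relapse_categories),
        },
        "exclusions": [{"patient_id": pid, "reason": reason}
                       for pid, reason in exclusions],
    }
    (outdir / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return summary


def make_baseline_table(patients: Sequence[PatientRecord],
                        assignment: Mapping[str, str] | None = None,
                        ) -> pd.DataFrame:
    """Grouped baseline characteristics (counts for categoricals, median
    [IQR] for stage); missing covariates are counted, never dropped."""
    if not patients:
        raise ValueError("empty cohort")
    if assignment is None:
        assignment = {p.patient_id: "all" for p in patients}
    frames = {}
    for label in sorted(set(assignment.values())):
        group = [p for p in patients if assignment.get(p.patient_id) == label]
        stages = pd.Series([p.stage for p in group], dtype=float)
        col = {
            "n": len(group),
            "grade: high": sum(p.grade == "high" for p in group),
            "grade: low": sum(p.grade == "low" for p in group),
            "substage: a": sum(p.substage == "a" for p in group),
            "substage: b": sum(p.substage == "b" for p in group),
            "stage: median": float(stages.median()),
            "stage: IQR": float(stages.quantile(0.75) - stages.quantile(0.25)),
            "missing": int(stages.isna().sum()),
        }
        frames[label] = col
    return pd.DataFrame(frames)
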