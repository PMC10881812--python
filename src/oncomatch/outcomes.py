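"""Survival and response statistics for the dichotomized cohort.

Kaplan-Meier estimation and logrank testing are delegated to lifelines,
Fisher's exact test to scipy, and the two-sample Z-test and
Benjamini-Hochberg adjustment to statsmodels; this module owns the
cohort-specific derivations (CR-duration endpoints, response-rate
tables, per-drug prediction-frequency comparisons) and the tabular
output schemas.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .records import PatientRecord, best_response

__all__ = [
    "SurvivalCurve",
    "CovariateEffect",
    "CoxResult",
    "ResponseSummary",
    "kaplan_meier",
    "logrank_test",
    "response_rates",
    "cr_durations",
    "prediction_frequency_comparison",
    "cox_model",
    "historical_survival_after_relapse",
    "survival_frame",
    "write_km_curves",
    "write_cox_table",
]


@dataclass
class SurvivalCurve:
    """A product-limit survival estimate on its distinct observed times."""

    event_times: np.ndarray  # ascending days
    survival_prob: np.ndarray  # nonincreasing, in [0, 1]
    at_risk: np.ndarray  # nonincreasing integers
    median: Optional[float]  # smallest t with S(t) <= 0.5, None if never
    n: int = 0
    n_events: int = 0


@dataclass
class CovariateEffect:
    name: str
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    ph_pass: Optional[bool] = None  # proportional-hazards check at alpha=.05


@dataclass
class CoxResult:
    mode: str  # "univariate" | "multivariate"
    effects: list[CovariateEffect]
    concordance: float
    n: int
    n_events: int
    n_dropped_missing: int = 0


@dataclass
class ResponseSummary:
    """Per-group response counts/rates with Fisher p-values for CRR/ORR."""

    groups: dict[str, dict] = field(default_factory=dict)
    crr_fisher_p: Optional[float] = None
    orr_fisher_p: Optional[float] = None


def kaplan_meier(durations: Sequence[float],
                 events: Sequence[bool]) -> SurvivalCurve:
    """Product-limit estimate; censored subjects shrink risk sets only."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValueError("kaplan_meier requires at least one subject")
    if durations.size != events.size:
        raise ValueError("durations and events must have equal length")
    if np.any(durations < 0):
        raise ValueError("durations must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    # drop the t=0 anchor row unless subjects actually start there
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=int)
    keep = (times > 0) | (table["observed"].to_numpy() > 0) \
        | (table["censored"].to_numpy() > 0)
    median = kmf.median_survival_time_
    return SurvivalCurve(
        event_times=times[keep],
        survival_prob=surv[keep],
        at_risk=at_risk[keep],
        median=None if np.isinf(median) else float(median),
        n=int(durations.size),
        n_events=int(events.sum()),
    )


def logrank_test(
    durations_a: Sequence[float], events_a: Sequence[bool],
    durations_b: Sequence[float], events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group logrank chi-square (1 df) and its p-value."""
    if len(durations_a) == 0 or len(durations_b) == 0:
        raise ValueError("logrank_test requires two nonempty groups")
    res = _ll_logrank(durations_a, durations_b,
                      event_observed_A=np.asarray(events_a, dtype=int),
                      event_observed_B=np.asarray(events_b, dtype=int))
    return float(res.test_statistic), float(res.p_value)


def response_rates(
    groups: Mapping[str, str],
    best_responses: Mapping[str, Optional[str]],
) -> ResponseSummary:
    """Per-group CRR/ORR with Fisher's exact tests across two groups.

    Patients with no post-report assessment stay in the denominator as
    non-responders.  Fisher p-values are computed only when exactly two
    groups are present (responder vs not, by group, two-sided).
    """
    labels = sorted(set(groups.values()))
    summary = ResponseSummary()
    for label in labels:
        ids = [pid for pid, g in groups.items() if g == label]
        if not ids:
            raise ValueError(f"group {label!r} is empty")
        cats = [best_responses.get(pid) for pid in ids]
        n = len(ids)
        counts = {c: sum(1 for x in cats if x == c)
                  for c in ("CR", "PR", "SD", "PD")}
        n_none = sum(1 for x in cats if x is None)
        summary.groups[label] = {
            "n": n,
            "n_CR": counts["CR"], "n_PR": counts["PR"],
            "n_SD": counts["SD"], "n_PD": counts["PD"],
            "n_no_assessment": n_none,
            "CRR": 100.0 * counts["CR"] / n,
            "ORR": 100.0 * (counts["CR"] + counts["PR"]) / n,
        }
    if len(labels) == 2:
        a, b = labels
        ga, gb = summary.groups[a], summary.groups[b]
        for key, attr in (("n_CR", "crr_fisher_p"), (None, "orr_fisher_p")):
            if key == "n_CR":
                ra, rb = ga["n_CR"], gb["n_CR"]
            else:
                ra, rb = ga["n_CR"] + ga["n_PR"], gb["n_CR"] + gb["n_PR"]
            table = [[ra, ga["n"] - ra], [rb, gb["n"] - rb]]
            setattr(summary, attr,
                    float(stats.fisher_exact(table, alternative="two-sided")[1]))
    return summary


def cr_durations(
    patients: Sequence[PatientRecord],
    groups: Mapping[str, str],
    relapse_categories: tuple[str, ...] = ("PD",),
) -> dict[str, SurvivalCurve]:
    """Per-group KM of CR duration for patients whose best response is CR.

    Duration runs from the first post-report CR to the first later
    assessment in ``relapse_categories`` (event) or to last follow-up /
    death (censored).  Groups without CR patients are omitted with a
    warning.
    """
    per_group: dict[str, tuple[list[float], list[bool]]] = {}
    for p in patients:
        if p.patient_id not in groups or best_response(p) != "CR":
            continue
        post = p.post_report_responses()
        cr_date = next(r.date for r in post if r.category == "CR")
        relapse = next((r for r in post
                        if r.date > cr_date
                        and r.category in relapse_categories), None)
        if relapse is not None:
            duration, event = (relapse.date - cr_date).days, True
        else:
            duration, event = (p.end_date - cr_date).days, False
        bucket = per_group.setdefault(groups[p.patient_id], ([], []))
        bucket[0].append(float(duration))
        bucket[1].append(event)
    curves: dict[str, SurvivalCurve] = {}
    for label in sorted(set(groups.values())):
        if label not in per_group:
            warnings.warn(f"no CR patients in group {label!r}; curve omitted",
                          stacklevel=2)
            continue
        durs, evts = per_group[label]
        curves[label] = kaplan_meier(durs, evts)
    return curves


def prediction_frequency_comparison(
    reports: Mapping[str, Mapping[str, float]],
    groups: Mapping[str, str],
    drug_panel: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-drug positive-prediction frequencies by group, Z-test + BH.

    Frequency is the fraction of a group's patients whose report scores
    the drug strictly above ``threshold``.  A pooled two-sample Z-test
    per drug, Benjamini-Hochberg adjusted across the panel.  Drugs in no
    report are dropped with a warning.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("prediction_frequency_comparison needs two groups")
    if set(labels) == {"low", "high"}:
        lo, hi = "low", "high"
    else:
        lo, hi = labels
    seen = set()
    for scores in reports.values():
        seen.update(scores)
    panel = list(drug_panel) if drug_panel is not None else sorted(seen)
    missing = [d for d in panel if d not in seen]
    for d in missing:
        warnings.warn(f"drug {d!r} appears in no report; excluded",
                      stacklevel=2)
    panel = [d for d in panel if d in seen]

    ids_lo = [pid for pid, g in groups.items() if g == lo]
    ids_hi = [pid for pid, g in groups.items() if g == hi]
    rows = []
    for drug in panel:
        x_lo = sum(1 for pid in ids_lo
                   if reports[pid].get(drug, 0.0) > threshold)
        x_hi = sum(1 for pid in ids_hi
                   if reports[pid].get(drug, 0.0) > threshold)
        n_lo, n_hi = len(ids_lo), len(ids_hi)
        if (x_lo + x_hi == 0) or (x_lo + x_hi == n_lo + n_hi):
            z, p = 0.0, 1.0  # pooled proportion degenerate; no difference
        else:
            z, p = proportions_ztest([x_hi, x_lo], [n_hi, n_lo])
        rows.append({"drug": drug,
                     "freq_low": x_lo / n_lo, "freq_high": x_hi / n_hi,
                     "z": float(z), "p": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p"].to_numpy(),
                                         method="fdr_bh")[1]
    else:
        df["p_adjusted"] = []
    return df


def cox_model(
    data: pd.DataFrame,
    covariates: Sequence[str],
    mode: str = "multivariate",
    duration_col: str = "duration",
    event_col: str = "event",
    ph_alpha: float = 0.05,
) -> CoxResult | list[CoxResult]:
    """Cox PH fit(s) with Breslow ties, no penalization, Wald intervals.

    ``multivariate`` returns one model over all covariates;
    ``univariate`` returns one single-covariate model per covariate.
    Rows with missing values are dropped (count recorded).  Each
    covariate gets a proportional-hazards check (scaled Schoenfeld
    residuals vs. rank-transformed time) reported as pass/fail at
    ``ph_alpha``.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "univariate":
        return [cox_model(data, [c], mode="multivariate",
                          duration_col=duration_col, event_col=event_col,
                          ph_alpha=ph_alpha)
                for c in covariates]

    cols = [duration_col, event_col, *covariates]
    df = data[cols].copy()
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if df.empty:
        raise ValueError("no complete-case rows to fit")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(
                f"covariate {c!r} is constant; cannot estimate its effect")

    cph = CoxPHFitter(baseline_estimation_method="breslow", penalizer=0.0)
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise ConvergenceError(
            f"Cox fit failed to converge for covariates {list(covariates)}; "
            "check for separation or rescale (a penalizer flag would be "
            f"needed for separated data): {err}") from err

    try:
        ph = proportional_hazard_test(cph, df, time_transform="rank")
        ph_p = ph.summary["p"]
        if isinstance(ph_p.index, pd.MultiIndex):
            ph_p = ph_p.droplevel(-1)
        ph_pass = {c: bool(ph_p.loc[c] > ph_alpha) for c in covariates}
    except Exception:  # PH test can fail on tiny degenerate fits
        ph_pass = {c: None for c in covariates}

    ci = cph.confidence_intervals_
    effects = []
    for c in covariates:
        effects.append(CovariateEffect(
            name=c,
            coef=float(cph.params_[c]),
            hr=float(np.exp(cph.params_[c])),
            ci_low=float(np.exp(ci.loc[c].iloc[0])),
            ci_high=float(np.exp(ci.loc[c].iloc[1])),
            p=float(cph.summary.loc[c, "p"]),
            ph_pass=ph_pass[c],
        ))
    mode_label = "univariate" if len(covariates) == 1 else "multivariate"
    return CoxResult(
        mode=mode_label,
        effects=effects,
        concordance=float(cph.concordance_index_),
        n=len(df),
        n_events=int(df[event_col].sum()),
        n_dropped_missing=n_dropped,
    )


def historical_survival_after_relapse(median_os: float,
                                      median_time_to_relapse: float) -> float:
    """Median survival after relapse = median OS minus median time to relapse."""
    if median_os <= 0 or median_time_to_relapse <= 0:
        raise ValueError("both medians must be positive")
    diff = median_os - median_time_to_relapse
    if diff <= 0:
        raise ValueError(
            "median overall survival must exceed median time to relapse")
    return float(diff)


# ---------------------------------------------------------------------------
# Helpers and writers
# ---------------------------------------------------------------------------

def survival_frame(patients: Sequence[PatientRecord],
                   assignment: Mapping[str, str] | None = None,
                   grade_coding: Mapping[str, int] = {"low": 0, "high": 1},
                   substage_coding: Mapping[str, int] = {"a": 0, "b": 1},
                   ) -> pd.DataFrame:
    """Cox-ready frame: duration, event and numerically coded covariates."""
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "duration": float(p.survival_days),
            "event": int(p.event),
            "grade": grade_coding[p.grade],
            "stage": int(p.stage),
            "substage": substage_coding[p.substage],
        }
        if assignment is not None:
            if p.patient_id not in assignment:
                continue
            row["matching_group"] = int(assignment[p.patient_id] == "high")
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def write_km_curves(curves: Mapping[str, SurvivalCurve],
                    path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["group", "time", "survival", "at_risk", "median"])
        for label in sorted(curves):
            c = curves[label]
            med = "" if c.median is None else f"{c.median:.6f}"
            for t, s, r in zip(c.event_times, c.survival_prob, c.at_risk):
                w.writerow([label, f"{t:.6f}", f"{s:.6f}", int(r), med])
    return path


def write_cox_table(results: Sequence[CoxResult], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["covariate", "mode", "coef", "HR", "CI_low", "CI_high",
                    "p", "concordance", "ph_pass"])
        for res in results:
            for eff in res.effects:
                w.writerow([
                    eff.name, res.mode, f"{eff.coef:.6f}", f"{eff.hr:.6f}",
                    f"{eff.ci_low:.6f}", f"{eff.ci_high:.6f}",
                    f"{eff.p:.6g}", f"{res.concordance:.6f}",
                    "" if eff.ph_pass is None else int(eff.ph_pass),
                ])
    return path
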