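"""Cohort dichotomization into low/high matching groups.

Three threshold methods: the sample median (primary; no investigator
degrees of freedom), a fixed cutoff (default 50%), and an
outcome-optimized scan over all candidate thresholds that maximizes the
between-group logrank statistic.  The optimized method reports both the
raw logrank p and a Bonferroni correction over the number of thresholds
scanned, since scanning is a multiple-testing exercise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "DegenerateStratificationError",
    "GroupAssignment",
    "dichotomize",
    "stratification_sensitivity",
    "write_groups",
]

#: outcome_data values are (duration_days, event_observed) pairs
SurvivalData = Mapping[str, tuple[float, bool]]


class DegenerateStratificationError(ValueError):
    """All scores identical (or too few distinct values to scan)."""


@dataclass
class GroupAssignment:
    """Result of one dichotomization: threshold and per-patient group."""

    method: str  # "median" | "fixed" | "optimized"
    threshold: float
    assignment: dict[str, str]  # patient_id -> "low" | "high"
    n_low: int = 0
    n_high: int = 0
    # optimized-method extras
    logrank_p: Optional[float] = None
    logrank_p_adjusted: Optional[float] = None
    n_thresholds_scanned: Optional[int] = None
    notes: list[str] = field(default_factory=list)

    def group_ids(self, group: str) -> list[str]:
        return sorted(p for p, g in self.assignment.items() if g == group)


def _counts(assignment: dict[str, str]) -> tuple[int, int]:
    n_low = sum(1 for g in assignment.values() if g == "low")
    return n_low, len(assignment) - n_low


def _fast_logrank_stat(durations: np.ndarray, events: np.ndarray,
                       in_high: np.ndarray) -> float:
    """Two-group logrank chi-square; same statistic as lifelines.

    Used inside the optimized-threshold scan where calling the full
    library per candidate would dominate runtime.
    """
    order = np.argsort(durations, kind="stable")
    t = durations[order]
    e = events[order].astype(float)
    g = in_high[order].astype(float)
    uniq, idx = np.unique(t, return_index=True)
    # deaths per time, per group
    d_total = np.add.reduceat(e, idx)
    d_high = np.add.reduceat(e * g, idx)
    # at risk just before each time
    n_total = len(t) - idx
    n_high_cum = np.concatenate(([0.0], np.cumsum(g)))
    n_high = g.sum() - n_high_cum[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d_total * n_high / n_total
        var = np.where(
            n_total > 1,
            d_total * (n_total - d_total) * n_high * (n_total - n_high)
            / (n_total ** 2 * (n_total - 1.0)),
            0.0)
    observed_minus_expected = (d_high - expected).sum()
    v = var.sum()
    if v <= 0:
        return 0.0
    return float(observed_minus_expected ** 2 / v)


def _logrank_stat(assignment: Mapping[str, str],
                  outcome_data: SurvivalData) -> tuple[float, float]:
    low = [pid for pid, g in assignment.items() if g == "low"]
    high = [pid for pid, g in assignment.items() if g == "high"]
    res = _ll_logrank(
        [outcome_data[p][0] for p in low],
        [outcome_data[p][0] for p in high],
        event_observed_A=[outcome_data[p][1] for p in low],
        event_observed_B=[outcome_data[p][1] for p in high],
    )
    return float(res.test_statistic), float(res.p_value)


def dichotomize(
    scores: Mapping[str, float],
    method: str = "median",
    fixed_threshold: float = 50.0,
    outcome_data: SurvivalData | None = None,
    min_group_frac: float = 0.1,
) -> GroupAssignment:
    """Split patients into low/high groups by matching score.

    ``median``: threshold is the sample median; scores strictly above go
    high, strictly below go low, and patients exactly at the median are
    allocated in ascending patient-id order to the currently smaller
    group (high first on ties) so group sizes are as equal as possible.

    ``fixed``: score >= ``fixed_threshold`` goes high.

    ``optimized``: every distinct score is tried as a ``>=`` threshold,
    keeping only splits that leave at least ``min_group_frac`` of the
    cohort in each group (extreme splits make the logrank chi-square
    approximation wildly anticonservative); the threshold maximizing the
    logrank statistic wins, ties broken toward the more balanced split,
    then the lower threshold.  Requires ``outcome_data``.  The reported
    ``logrank_p_adjusted`` is Bonferroni over the scanned thresholds.
    """
    if not scores:
        raise ValueError("no scores to dichotomize")
    if any(v is None or not np.isfinite(v) for v in scores.values()):
        raise ValueError("all scores must be defined and finite")

    values = np.asarray(list(scores.values()), dtype=float)

    if method == "median":
        if np.unique(values).size == 1:
            raise DegenerateStratificationError(
                "all matching scores identical; median split impossible")
        threshold = float(np.median(values))
        assignment: dict[str, str] = {}
        ties: list[str] = []
        for pid, s in scores.items():
            if s > threshold:
                assignment[pid] = "high"
            elif s < threshold:
                assignment[pid] = "low"
            else:
                ties.append(pid)
        for pid in sorted(ties):
            n_low, n_high = _counts(assignment)
            assignment[pid] = "high" if n_high <= n_low else "low"
        n_low, n_high = _counts(assignment)
        if n_low == 0 or n_high == 0:
            raise DegenerateStratificationError(
                "median split produced an empty group")
        return GroupAssignment(method="median", threshold=threshold,
                               assignment=assignment,
                               n_low=n_low, n_high=n_high)

    if method == "fixed":
        assignment = {pid: ("high" if s >= fixed_threshold else "low")
                      for pid, s in scores.items()}
        n_low, n_high = _counts(assignment)
        return GroupAssignment(method="fixed", threshold=float(fixed_threshold),
                               assignment=assignment,
                               n_low=n_low, n_high=n_high)

    if method == "optimized":
        if outcome_data is None:
            raise ValueError("optimized method requires outcome_data")
        missing = set(scores) - set(outcome_data)
        if missing:
            raise ValueError(
                f"outcome_data missing for patients {sorted(missing)[:5]}")
        candidates = sorted(set(float(v) for v in values))
        if len(candidates) < 2:
            raise DegenerateStratificationError(
                "fewer than 2 distinct scores; nothing to scan")
        pids = sorted(scores)
        svec = np.array([scores[p] for p in pids], dtype=float)
        durs = np.array([outcome_data[p][0] for p in pids], dtype=float)
        evts = np.array([outcome_data[p][1] for p in pids], dtype=bool)
        n = len(pids)
        min_group = max(1, int(np.ceil(min_group_frac * n)))
        best = None
        n_scanned = 0
        for t in candidates[1:]:  # threshold at min would put everyone high
            in_high = svec >= t
            n_high = int(in_high.sum())
            n_low = n - n_high
            if n_low < min_group or n_high < min_group:
                continue
            n_scanned += 1
            stat = _fast_logrank_stat(durs, evts, in_high)
            key = (stat, -abs(n_high - n_low), -t)
            if best is None or key > best[0]:
                best = (key, t, in_high, n_low, n_high, stat)
        if best is None:
            raise DegenerateStratificationError(
                "no threshold yields two acceptably sized groups")
        _, t, in_high, n_low, n_high, stat = best
        assignment = {pid: ("high" if h else "low")
                      for pid, h in zip(pids, in_high)}
        p = float(chi2.sf(stat, 1))
        return GroupAssignment(
            method="optimized", threshold=t, assignment=assignment,
            n_low=n_low, n_high=n_high,
            logrank_p=p,
            logrank_p_adjusted=min(1.0, p * n_scanned),
            n_thresholds_scanned=n_scanned,
        )

    raise ValueError(f"unknown dichotomization method {method!r}")


def stratification_sensitivity(
    scores: Mapping[str, float],
    outcome_data: SurvivalData,
    methods: Sequence[str] = ("median", "fixed", "optimized"),
    fixed_threshold: float = 50.0,
) -> pd.DataFrame:
    """One row per method: threshold, group sizes, Cox HR and logrank p.

    Degenerate stratifications do not abort the table; the failing row
    carries the error message in its ``error`` column and NaN stats.
    """
    rows = []
    for method in methods:
        row: dict = {"method": method, "threshold": np.nan,
                     "n_low": np.nan, "n_high": np.nan, "hr": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan,
                     "logrank_p": np.nan, "error": ""}
        try:
            ga = dichotomize(scores, method=method,
                             fixed_threshold=fixed_threshold,
                             outcome_data=outcome_data)
            row.update(threshold=ga.threshold, n_low=ga.n_low,
                       n_high=ga.n_high)
            _, p = _logrank_stat(ga.assignment, outcome_data)
            row["logrank_p"] = p
            df = pd.DataFrame({
                "duration": [outcome_data[pid][0] for pid in ga.assignment],
                "event": [int(outcome_data[pid][1]) for pid in ga.assignment],
                "group": [int(ga.assignment[pid] == "high")
                          for pid in ga.assignment],
            })
            cph = CoxPHFitter(baseline_estimation_method="breslow",
                              penalizer=0.0)
            cph.fit(df, duration_col="duration", event_col="event")
            row["hr"] = float(np.exp(cph.params_["group"]))
            ci = cph.confidence_intervals_
            row["ci_low"] = float(np.exp(ci.iloc[0, 0]))
            row["ci_high"] = float(np.exp(ci.iloc[0, 1]))
        except (ValueError, ConvergenceError) as err:
            row["error"] = f"{type(err).__name__}: {err}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_groups(ga: GroupAssignment, scores: Mapping[str, float],
                 path: str | Path) -> Path:
    """Write groups.csv: patient_id, matching_score, group, method, threshold."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "matching_score", "group", "method",
                    "threshold"])
        for pid in sorted(ga.assignment):
            w.writerow([pid, f"{scores[pid]:.6f}", ga.assignment[pid],
                        ga.method, f"{ga.threshold:.6f}"])
    return path
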