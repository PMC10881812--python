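"""Matching scores: the course-denominated (modified) score and the
literature-standard actionable-set score, plus the shuffled-recommendation
null used as a survivorship-bias diagnostic.

The modified score counts treatment courses: the percentage of all
administered courses whose drug scored strictly above the match threshold
in the prediction report.  The standard score counts distinct drugs:
administered drugs in the actionable set divided by the size of the
actionable set.  The standard score rewards receiving many different
drugs, so it inflates for long-lived patients; the modified score does
not, because every course enters its denominator.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .records import PatientRecord, PredictionReport, TreatmentCourse

__all__ = [
    "MATCH_THRESHOLD",
    "MatchingResult",
    "modified_matching_score",
    "standard_matching_score",
    "compute_matching",
    "shuffle_predictions",
    "write_matching_scores",
]

#: a drug "matches" when its prediction score is strictly above this value
MATCH_THRESHOLD = 0.5


@dataclass
class MatchingResult:
    """Matched/total counts and both score variants for one patient.

    Scores are percentages in [0, 100]; ``None`` marks an undefined score
    (no courses for the modified variant, empty actionable set for the
    standard variant) and flags the patient for downstream exclusion.
    """

    patient_id: str
    n_courses: int = 0
    n_matched_courses: int = 0
    modified_score: Optional[float] = None
    n_recommended_drugs: int = 0
    n_matched_drugs: int = 0
    standard_score: Optional[float] = None
    n_unscored_courses: int = 0


def modified_matching_score(
    courses: Sequence[TreatmentCourse],
    report: PredictionReport,
    include_unscored: bool = True,
    threshold: float = MATCH_THRESHOLD,
) -> MatchingResult:
    """Percentage of administered courses whose drug scored > ``threshold``.

    Every course counts in the denominator, including courses of drugs
    absent from the report (which can never match); those are tallied in
    ``n_unscored_courses``.  Set ``include_unscored=False`` to drop them
    from the denominator (sensitivity analysis only).
    """
    pid = report.patient_id
    scored = [c for c in courses if c.drug in report.scores]
    unscored = len(courses) - len(scored)
    denominator = courses if include_unscored else scored
    matched = sum(1 for c in scored if report.scores[c.drug] > threshold)
    result = MatchingResult(
        patient_id=pid,
        n_courses=len(denominator),
        n_matched_courses=matched,
        n_unscored_courses=unscored,
    )
    if result.n_courses > 0:
        result.modified_score = 100.0 * matched / result.n_courses
    return result


def standard_matching_score(
    courses: Sequence[TreatmentCourse],
    report: PredictionReport,
    threshold: float = MATCH_THRESHOLD,
) -> MatchingResult:
    """Distinct administered drugs in the actionable set over its size.

    The actionable set is the distinct report drugs scoring strictly
    above ``threshold``; the score is undefined when that set is empty.
    """
    actionable = report.recommended_drugs(threshold)
    administered = {c.drug for c in courses}
    matched = len(administered & actionable)
    result = MatchingResult(
        patient_id=report.patient_id,
        n_recommended_drugs=len(actionable),
        n_matched_drugs=matched,
    )
    if actionable:
        result.standard_score = 100.0 * matched / len(actionable)
    return result


def compute_matching(
    courses: Sequence[TreatmentCourse],
    report: PredictionReport,
    include_unscored: bool = True,
    threshold: float = MATCH_THRESHOLD,
) -> MatchingResult:
    """Both score variants for one patient in a single result."""
    mod = modified_matching_score(courses, report, include_unscored, threshold)
    std = standard_matching_score(courses, report, threshold)
    mod.n_recommended_drugs = std.n_recommended_drugs
    mod.n_matched_drugs = std.n_matched_drugs
    mod.standard_score = std.standard_score
    return mod


def shuffle_predictions(
    cohort: Sequence[PatientRecord],
    seed: int,
    mode: str = "across_patients",
) -> list[PatientRecord]:
    """Return a deep copy of the cohort with permuted prediction scores.

    ``across_patients`` applies one uniform random permutation of whole
    score mappings between patients (delivery dates stay with their
    patients, so post-report filtering is unchanged).  ``within_patient``
    permutes each patient's scores across that patient's report drugs.
    Deterministic given ``seed``.
    """
    if not cohort:
        raise ValueError("shuffle_predictions requires a nonempty cohort")
    if mode not in ("across_patients", "within_patient"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    rng = np.random.default_rng(seed)
    shuffled = copy.deepcopy(list(cohort))
    if mode == "across_patients":
        perm = rng.permutation(len(shuffled))
        score_maps = [dict(p.report.scores) for p in shuffled]
        for patient, j in zip(shuffled, perm):
            patient.report = PredictionReport(
                patient_id=patient.patient_id,
                delivery_date=patient.report.delivery_date,
                scores=score_maps[j],
            )
    else:
        for patient in shuffled:
            drugs = sorted(patient.report.scores)
            values = [patient.report.scores[d] for d in drugs]
            perm = rng.permutation(len(drugs))
            patient.report = PredictionReport(
                patient_id=patient.patient_id,
                delivery_date=patient.report.delivery_date,
                scores={d: values[j] for d, j in zip(drugs, perm)},
            )
    return shuffled


def write_matching_scores(results: Sequence[MatchingResult],
                          path: str | Path) -> Path:
    """Write matching_scores.csv (one row per patient)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "n_courses", "n_matched_courses",
                    "modified_score", "n_recommended_drugs",
                    "n_matched_drugs", "standard_score",
                    "n_unscored_courses"])
        for r in results:
            w.writerow([
                r.patient_id, r.n_courses, r.n_matched_courses,
                "" if r.modified_score is None else f"{r.modified_score:.6f}",
                r.n_recommended_drugs, r.n_matched_drugs,
                "" if r.standard_score is None else f"{r.standard_score:.6f}",
                r.n_unscored_courses,
            ])
    return path
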