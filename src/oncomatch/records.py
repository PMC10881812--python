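"""Cohort domain model and CSV I/O.

Patients, prediction reports, drug administrations and tumor-response
assessments are represented as frozen dataclasses.  Raw administration
events are aggregated into *treatment courses*, the unit in which
matching scores are counted: a drug given more than once in any 7-day
span contributes one course per (nonempty) 7-day window anchored at its
first retained administration; a drug given weekly or less often
contributes one course per administration.
"""

from __future__ import annotations

import csv
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "CohortValidationError",
    "PredictionReport",
    "AdministrationEvent",
    "TreatmentCourse",
    "ResponseAssessment",
    "PatientRecord",
    "RESPONSE_CATEGORIES",
    "RESPONSE_ORDER",
    "aggregate_treatments",
    "derive_response_labels",
    "best_response",
    "inclusion_filter",
    "read_cohort",
    "write_cohort_csvs",
]

RESPONSE_CATEGORIES = ("PD", "SD", "PR", "CR")
#: ordering used for best-response derivation (higher is better)
RESPONSE_ORDER = {"PD": 0, "SD": 1, "PR": 2, "CR": 3}

WEEK = datetime.timedelta(days=7)


class CohortValidationError(ValueError):
    """Raised when an input file or record violates a domain invariant."""

    def __init__(self, message: str, *, file: str | None = None,
                 row: int | None = None, fld: str | None = None) -> None:
        ctx = []
        if file is not None:
            ctx.append(f"file={file}")
        if row is not None:
            ctx.append(f"row={row}")
        if fld is not None:
            ctx.append(f"field={fld}")
        suffix = f" [{', '.join(ctx)}]" if ctx else ""
        super().__init__(message + suffix)
        self.file = file
        self.row = row
        self.field = fld


@dataclass(frozen=True)
class PredictionReport:
    """Per-patient drug response predictions, each score in [0, 1]."""

    patient_id: str
    delivery_date: datetime.date
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        for drug, score in self.scores.items():
            if not (0.0 <= score <= 1.0):
                raise CohortValidationError(
                    f"score {score!r} for drug {drug!r} outside [0, 1]",
                    fld="score",
                )

    def recommended_drugs(self, threshold: float = 0.5) -> frozenset[str]:
        """Drugs with score strictly above ``threshold`` (the actionable set)."""
        return frozenset(d for d, s in self.scores.items() if s > threshold)


@dataclass(frozen=True)
class AdministrationEvent:
    """A single dated administration of one drug."""

    patient_id: str
    drug: str
    date: datetime.date


@dataclass(frozen=True)
class TreatmentCourse:
    """One countable treatment: a weekly course or a single administration."""

    patient_id: str
    drug: str
    start_date: datetime.date
    n_administrations: int
    counting_mode: str  # "weekly_window" | "per_administration"

    def __post_init__(self) -> None:
        if self.n_administrations < 1:
            raise CohortValidationError("n_administrations must be >= 1")
        if self.counting_mode not in ("weekly_window", "per_administration"):
            raise CohortValidationError(
                f"unknown counting_mode {self.counting_mode!r}")


@dataclass(frozen=True)
class ResponseAssessment:
    """A dated tumor response assessment in {PD, SD, PR, CR}."""

    patient_id: str
    date: datetime.date
    category: str

    def __post_init__(self) -> None:
        if self.category not in RESPONSE_CATEGORIES:
            raise CohortValidationError(
                f"unknown response category {self.category!r}", fld="category")


@dataclass
class PatientRecord:
    """One patient: covariates, report, raw events and survival endpoint."""

    patient_id: str
    grade: str  # "low" | "high"
    stage: int  # 1..5
    substage: str  # "a" | "b"
    report: PredictionReport
    administrations: list[AdministrationEvent] = field(default_factory=list)
    responses: list[ResponseAssessment] = field(default_factory=list)
    last_followup_date: datetime.date | None = None
    death_date: datetime.date | None = None
    event: bool = False

    def __post_init__(self) -> None:
        if self.grade not in ("low", "high"):
            raise CohortValidationError(
                f"grade must be low/high, got {self.grade!r}", fld="grade")
        if not 1 <= int(self.stage) <= 5:
            raise CohortValidationError(
                f"stage must be 1..5, got {self.stage!r}", fld="stage")
        if self.substage not in ("a", "b"):
            raise CohortValidationError(
                f"substage must be a/b, got {self.substage!r}", fld="substage")
        if self.event != (self.death_date is not None):
            raise CohortValidationError(
                f"patient {self.patient_id}: event flag must agree with "
                "presence of death_date")
        if (self.death_date is not None
                and self.death_date < self.report.delivery_date):
            raise CohortValidationError(
                f"patient {self.patient_id}: death_date precedes report "
                "delivery")

    @property
    def end_date(self) -> datetime.date:
        """Death date if observed, else last follow-up."""
        if self.death_date is not None:
            return self.death_date
        if self.last_followup_date is None:
            raise CohortValidationError(
                f"patient {self.patient_id}: no death or follow-up date")
        return self.last_followup_date

    @property
    def survival_days(self) -> int:
        """Days from report delivery to death or last follow-up."""
        days = (self.end_date - self.report.delivery_date).days
        if days < 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: negative survival time")
        return days

    def post_report_administrations(self) -> list[AdministrationEvent]:
        d = self.report.delivery_date
        return [e for e in self.administrations if e.date > d]

    def post_report_responses(self) -> list[ResponseAssessment]:
        d = self.report.delivery_date
        return sorted((r for r in self.responses if r.date > d),
                      key=lambda r: r.date)


# ---------------------------------------------------------------------------
# Treatment-course aggregation
# ---------------------------------------------------------------------------

def aggregate_treatments(
    events: Sequence[AdministrationEvent],
    report_delivery_date: datetime.date | None = None,
    post_report_only: bool = True,
) -> list[TreatmentCourse]:
    """Aggregate one patient's administrations into treatment courses.

    Per drug: if any two administrations fall within a 7-day span (i.e.
    the drug was given more than once per week anywhere in its history),
    all of its administrations are binned into consecutive half-open
    7-day windows ``[anchor + 7k, anchor + 7(k+1))`` anchored at the
    first retained administration, one course per nonempty window.
    Otherwise each administration is its own course.

    When ``post_report_only`` is set, events dated on or before
    ``report_delivery_date`` are dropped first.
    """
    if post_report_only:
        if report_delivery_date is None:
            raise ValueError(
                "report_delivery_date required when post_report_only is set")
        events = [e for e in events if e.date > report_delivery_date]
    if not events:
        return []
    pids = {e.patient_id for e in events}
    if len(pids) > 1:
        raise ValueError(
            f"aggregate_treatments expects a single patient, got {sorted(pids)}")

    by_drug: dict[str, list[datetime.date]] = {}
    for e in events:
        by_drug.setdefault(e.drug, []).append(e.date)

    courses: list[TreatmentCourse] = []
    pid = next(iter(pids))
    for drug in sorted(by_drug):
        dates = sorted(by_drug[drug])
        # >1 administration within any 7-day window <=> some consecutive
        # pair of sorted dates is < 7 days apart
        more_than_weekly = any(
            (b - a) < WEEK for a, b in zip(dates, dates[1:]))
        if more_than_weekly:
            anchor = dates[0]
            windows: dict[int, int] = {}
            for d in dates:
                windows[(d - anchor).days // 7] = windows.get(
                    (d - anchor).days // 7, 0) + 1
            for k in sorted(windows):
                courses.append(TreatmentCourse(
                    patient_id=pid,
                    drug=drug,
                    start_date=anchor + k * WEEK,
                    n_administrations=windows[k],
                    counting_mode="weekly_window",
                ))
        else:
            for d in dates:
                courses.append(TreatmentCourse(
                    patient_id=pid, drug=drug, start_date=d,
                    n_administrations=1,
                    counting_mode="per_administration",
                ))
    courses.sort(key=lambda c: (c.start_date, c.drug))
    return courses


def derive_response_labels(
    responses: Sequence[ResponseAssessment],
    courses: Sequence[TreatmentCourse],
) -> list[tuple[TreatmentCourse, int]]:
    """Pair each course with the binary label of its next assessment.

    The first assessment dated on/after the course start supplies the
    label: CR/PR -> 1, SD/PD -> 0.  Courses with no subsequent
    assessment are omitted.
    """
    ordered = sorted(responses, key=lambda r: r.date)
    out: list[tuple[TreatmentCourse, int]] = []
    for course in courses:
        nxt = next((r for r in ordered if r.date >= course.start_date), None)
        if nxt is None:
            continue
        out.append((course, 1 if nxt.category in ("CR", "PR") else 0))
    return out


def best_response(patient: PatientRecord) -> Optional[str]:
    """Best post-report response category (CR > PR > SD > PD), or None."""
    post = patient.post_report_responses()
    if not post:
        return None
    return max(post, key=lambda r: RESPONSE_ORDER[r.category]).category


def inclusion_filter(
    patients: Sequence[PatientRecord],
    min_administrations: int = 3,
) -> tuple[list[PatientRecord], list[tuple[str, str]]]:
    """Keep patients with >= ``min_administrations`` post-report events.

    Returns ``(included, exclusion_log)`` where the log holds
    ``(patient_id, reason)`` pairs.
    """
    included: list[PatientRecord] = []
    log: list[tuple[str, str]] = []
    for p in patients:
        n = len(p.post_report_administrations())
        if n >= min_administrations:
            included.append(p)
        else:
            log.append((
                p.patient_id,
                f"only {n} post-report administrations "
                f"(minimum {min_administrations})",
            ))
    return included, log


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_date(raw: str, *, file: str, row: int, fld: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(raw.strip())
    except ValueError:
        raise CohortValidationError(
            f"malformed date {raw!r}", file=file, row=row, fld=fld) from None


def _read_rows(path: str | Path, required: Sequence[str]) -> Iterable[tuple[int, dict]]:
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise CohortValidationError(
                f"missing required columns {missing}", file=path.name)
        for i, rec in enumerate(reader, start=2):  # 1-based incl. header
            yield i, rec


def read_cohort(
    reports_path: str | Path,
    administrations_path: str | Path,
    responses_path: str | Path,
    patients_path: str | Path,
) -> list[PatientRecord]:
    """Load a cohort from the four CSV tables, one PatientRecord per id.

    ``patients.csv`` is the roster; rows elsewhere referring to unknown
    patient ids raise a validation error, as do malformed dates, scores
    outside [0, 1] and duplicate (patient, drug) report rows.
    """
    rep_name = Path(reports_path).name
    adm_name = Path(administrations_path).name
    res_name = Path(responses_path).name
    pat_name = Path(patients_path).name

    roster: dict[str, dict] = {}
    for i, rec in _read_rows(patients_path, (
            "patient_id", "grade", "stage", "substage",
            "last_followup_date", "death_date", "event")):
        pid = rec["patient_id"].strip()
        if pid in roster:
            raise CohortValidationError(
                f"duplicate patient id {pid!r}", file=pat_name, row=i,
                fld="patient_id")
        try:
            stage = int(rec["stage"])
        except ValueError:
            raise CohortValidationError(
                f"malformed stage {rec['stage']!r}", file=pat_name, row=i,
                fld="stage") from None
        death_raw = (rec["death_date"] or "").strip()
        roster[pid] = {
            "grade": rec["grade"].strip().lower(),
            "stage": stage,
            "substage": rec["substage"].strip().lower(),
            "last_followup_date": _parse_date(
                rec["last_followup_date"], file=pat_name, row=i,
                fld="last_followup_date"),
            "death_date": (_parse_date(death_raw, file=pat_name, row=i,
                                       fld="death_date")
                           if death_raw else None),
            "event": rec["event"].strip() in ("1", "true", "True"),
        }

    reports: dict[str, dict] = {}
    for i, rec in _read_rows(reports_path, (
            "patient_id", "drug", "score", "delivery_date")):
        pid = rec["patient_id"].strip()
        if pid not in roster:
            raise CohortValidationError(
                f"unknown patient id {pid!r}", file=rep_name, row=i,
                fld="patient_id")
        try:
            score = float(rec["score"])
        except ValueError:
            raise CohortValidationError(
                f"malformed score {rec['score']!r}", file=rep_name, row=i,
                fld="score") from None
        if not (0.0 <= score <= 1.0):
            raise CohortValidationError(
                f"score {score} outside [0, 1]", file=rep_name, row=i,
                fld="score")
        delivery = _parse_date(rec["delivery_date"], file=rep_name, row=i,
                               fld="delivery_date")
        entry = reports.setdefault(pid, {"delivery": delivery, "scores": {}})
        if entry["delivery"] != delivery:
            raise CohortValidationError(
                f"inconsistent delivery_date for patient {pid!r}",
                file=rep_name, row=i, fld="delivery_date")
        drug = rec["drug"].strip()
        if drug in entry["scores"]:
            raise CohortValidationError(
                f"duplicate drug {drug!r} in report for patient {pid!r}",
                file=rep_name, row=i, fld="drug")
        entry["scores"][drug] = score

    admins: dict[str, list[AdministrationEvent]] = {p: [] for p in roster}
    for i, rec in _read_rows(administrations_path, (
            "patient_id", "drug", "date")):
        pid = rec["patient_id"].strip()
        if pid not in roster:
            raise CohortValidationError(
                f"unknown patient id {pid!r}", file=adm_name, row=i,
                fld="patient_id")
        admins[pid].append(AdministrationEvent(
            patient_id=pid, drug=rec["drug"].strip(),
            date=_parse_date(rec["date"], file=adm_name, row=i, fld="date")))

    resps: dict[str, list[ResponseAssessment]] = {p: [] for p in roster}
    for i, rec in _read_rows(responses_path, (
            "patient_id", "date", "category")):
        pid = rec["patient_id"].strip()
        if pid not in roster:
            raise CohortValidationError(
                f"unknown patient id {pid!r}", file=res_name, row=i,
                fld="patient_id")
        cat = rec["category"].strip().upper()
        if cat not in RESPONSE_CATEGORIES:
            raise CohortValidationError(
                f"unknown response category {rec['category']!r}",
                file=res_name, row=i, fld="category")
        resps[pid].append(ResponseAssessment(
            patient_id=pid, category=cat,
            date=_parse_date(rec["date"], file=res_name, row=i, fld="date")))

    patients: list[PatientRecord] = []
    for pid in sorted(roster):
        if pid not in reports:
            raise CohortValidationError(
                f"patient {pid!r} has no prediction report", file=rep_name)
        meta = roster[pid]
        report = PredictionReport(
            patient_id=pid,
            delivery_date=reports[pid]["delivery"],
            scores=dict(sorted(reports[pid]["scores"].items())),
        )
        patients.append(PatientRecord(
            patient_id=pid,
            grade=meta["grade"],
            stage=meta["stage"],
            substage=meta["substage"],
            report=report,
            administrations=sorted(admins[pid],
                                   key=lambda e: (e.date, e.drug)),
            responses=sorted(resps[pid], key=lambda r: r.date),
            last_followup_date=meta["last_followup_date"],
            death_date=meta["death_date"],
            event=meta["event"],
        ))
    return patients


def write_cohort_csvs(patients: Sequence[PatientRecord],
                      directory: str | Path) -> dict[str, Path]:
    """Write the four cohort CSVs; inverse of :func:`read_cohort`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / f"{name}.csv"
             for name in ("reports", "administrations", "responses",
                          "patients")}

    with open(paths["reports"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "drug", "score", "delivery_date"])
        for p in patients:
            for drug, score in sorted(p.report.scores.items()):
                w.writerow([p.patient_id, drug, repr(score),
                            p.report.delivery_date.isoformat()])

    with open(paths["administrations"], "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "drug", "date"])
        for p in patients:
            for e in sorted(p.administrations, key=lambda e: (e.date, e.drug)):
                w.writerow([p.patient_id, e.drug, e.date.isoformat()])

    with open(paths["responses"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "date", "category"])
        for p in patients:
            for r in sorted(p.responses, key=lambda r: r.date):
                w.writerow([p.patient_id, r.date.isoformat(), r.category])

    with open(paths["patients"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "grade", "stage", "substage",
                    "last_followup_date", "death_date", "event"])
        for p in patients:
            w.writerow([
                p.patient_id, p.grade, p.stage, p.substage,
                p.last_followup_date.isoformat()
                if p.last_followup_date else "",
                p.death_date.isoformat() if p.death_date else "",
                int(p.event),
            ])
    return paths
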