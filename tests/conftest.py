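import datetime as dt

import pytest

from oncomatch.records import (
    AdministrationEvent,
    PredictionReport,
    ResponseAssessment,
)

DELIVERY = dt.date(2021, 1, 1)


def day(n: int) -> dt.date:
    """Calendar date n days after report delivery."""
    return DELIVERY + dt.timedelta(days=n)


def worked_example_events(pid: str = "dog1") -> list[AdministrationEvent]:
    """Six weeks of twice-weekly prednisone plus two rabacfosadine
    infusions three weeks apart, all strictly post-report."""
    events = []
    for week in range(6):
        events.append(AdministrationEvent(pid, "prednisone", day(7 * week + 1)))
        events.append(AdministrationEvent(pid, "prednisone", day(7 * week + 4)))
    events.append(AdministrationEvent(pid, "rabacfosadine", day(1)))
    events.append(AdministrationEvent(pid, "rabacfosadine", day(22)))
    return events


def worked_example_report(pid: str = "dog1") -> PredictionReport:
    return PredictionReport(
        patient_id=pid, delivery_date=DELIVERY,
        scores={"prednisone": 0.3, "rabacfosadine": 0.7})


@pytest.fixture
def worked_example():
    return worked_example_events(), worked_example_report()


@pytest.fixture
def cohort_csv_dir(tmp_path):
    """Minimal two-patient cohort on disk in the four-file dialect."""
    (tmp_path / "reports.csv").write_text(
        "patient_id,drug,score,delivery_date\n"
        "dog1,prednisone,0.3,2021-01-01\n"
        "dog1,rabacfosadine,0.7,2021-01-01\n"
        "dog2,prednisone,0.6,2021-01-01\n"
        "dog2,rabacfosadine,0.2,2021-01-01\n")
    (tmp_path / "administrations.csv").write_text(
        "patient_id,drug,date\n"
        "dog1,prednisone,2021-01-05\n"
        "dog1,rabacfosadine,2021-01-12\n"
        "dog2,prednisone,2021-01-06\n")
    (tmp_path / "responses.csv").write_text(
        "patient_id,date,category\n"
        "dog1,2021-02-01,PR\n"
        "dog2,2021-02-01,sd\n")
    (tmp_path / "patients.csv").write_text(
        "patient_id,grade,stage,substage,last_followup_date,death_date,event\n"
        "dog1,high,4,b,2021-06-01,2021-06-01,1\n"
        "dog2,low,3,a,2021-12-01,,0\n")
    return tmp_path


def make_response(pid, d, cat):
    return ResponseAssessment(patient_id=pid, date=d, category=cat)
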