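"""Synthetic cohort generator.

Emulates the statistical structure the matching-score analysis assumes:

* per-drug true response probabilities ``p_d ~ Beta(2, 2)`` with noisy
  prediction scores ``s_d = clip(p_d + N(0, sd), 0, 1)``, so a score of
  0.5 corresponds to roughly a 50% response probability;
* oncologist drug choice as a mixture of picking the top-scoring
  available drug (with probability ``adherence``) and picking uniformly;
* switch-on-progression dynamics — a PD assessment retires the current
  drug — so longer-lived patients accumulate more distinct drugs, the
  mechanism that inflates drug-count-rewarding matching scores;
* survival from a piecewise-constant hazard
  ``baseline_hazard * exp(beta_match * f)`` where ``f`` is the running
  fraction of received courses whose drug has ``p_d > 0.5``; with
  ``beta_match = log(0.3)`` a fully matched patient has hazard ratio 0.3
  relative to a fully unmatched one;
* administrative censoring at the study horizon.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import matching, stratify
from .outcomes import cox_model
from .records import (
    AdministrationEvent,
    PatientRecord,
    PredictionReport,
    ResponseAssessment,
    aggregate_treatments,
    inclusion_filter,
    write_cohort_csvs,
)

__all__ = [
    "DEFAULT_DRUG_PANEL",
    "SyntheticCohortConfig",
    "generate_cohort",
    "bias_experiment",
    "write_cohort",
]

#: drugs commonly used for canine lymphoma rescue therapy
DEFAULT_DRUG_PANEL = (
    "prednisone", "rabacfosadine", "doxorubicin", "lomustine",
    "vincristine", "cyclophosphamide", "mitoxantrone", "chlorambucil",
    "vinblastine", "dacarbazine",
)

_ORIGIN = datetime.date(2021, 1, 1)


@dataclass
class SyntheticCohortConfig:
    n_patients: int = 60
    drug_panel: tuple[str, ...] = DEFAULT_DRUG_PANEL
    score_noise_sd: float = 0.1
    adherence: float = 0.85
    #: Beta concentration of the per-patient adherence propensity around
    #: ``adherence``; small values give persistent between-patient
    #: differences in how recommendations are followed
    adherence_concentration: float = 1.0
    baseline_hazard: float = 0.008  # per-day hazard for a fully unmatched patient
    beta_match: float = float(np.log(0.3))  # log-HR of full matching
    switch_on_progression: bool = True
    #: background drug co-administered twice weekly for the whole course
    #: of treatment (None disables); kept out of the primary-choice set so
    #: per-patient score mixtures spread over (0, 100) as real
    #: combination-therapy histories do
    background_drug: str | None = "prednisone"
    background_prob: float = 0.5
    assessment_interval_days: int = 21
    study_horizon_days: int = 365
    success_cr_fraction: float = 0.5  # CR:PR split among positive responses
    failure_pd_fraction: float = 0.5  # PD:SD split among negative responses
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not self.drug_panel:
            raise ValueError("drug_panel must be nonempty")
        if self.score_noise_sd <= 0:
            raise ValueError("score_noise_sd must be positive")
        if not 0.0 <= self.adherence <= 1.0:
            raise ValueError("adherence must be in [0, 1]")
        if self.adherence_concentration <= 0:
            raise ValueError("adherence_concentration must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.assessment_interval_days < 7:
            raise ValueError("assessment_interval_days must be >= 7")
        if self.background_drug is not None:
            if self.background_drug not in self.drug_panel:
                raise ValueError("background_drug must be in drug_panel")
            if len(self.drug_panel) < 2:
                raise ValueError(
                    "drug_panel needs a non-background drug to choose from")
        if not 0.0 <= self.background_prob <= 1.0:
            raise ValueError("background_prob must be in [0, 1]")
        if self.study_horizon_days <= 0:
            raise ValueError("study_horizon_days must be positive")
        for frac in (self.success_cr_fraction, self.failure_pd_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("category split fractions must be in [0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticCohortConfig":
        cfg = cls(**{k: (tuple(v) if k == "drug_panel" else v)
                     for k, v in data.items()})
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticCohortConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drug_panel"] = list(self.drug_panel)
        return d


def _choose_drug(rng: np.random.Generator, scores: dict[str, float],
                 available: list[str], adherence: float) -> str:
    """Top-scoring available drug w.p. ``adherence``, else uniform."""
    if rng.random() < adherence:
        return max(available, key=lambda d: (scores[d], d))
    return available[rng.integers(len(available))]


def _simulate_patient(pid: str, cfg: SyntheticCohortConfig,
                      rng: np.random.Generator) -> PatientRecord:
    panel = list(cfg.drug_panel)
    p_true = {d: rng.beta(2.0, 2.0) for d in panel}
    scores = {
        d: float(np.clip(p_true[d] + rng.normal(0.0, cfg.score_noise_sd),
                         0.0, 1.0))
        for d in panel
    }
    report = PredictionReport(patient_id=pid, delivery_date=_ORIGIN,
                              scores=scores)

    grade = "high" if rng.random() < 0.8 else "low"
    stage = int(rng.choice([3, 4, 5], p=[0.3, 0.4, 0.3]))
    substage = "a" if rng.random() < 0.5 else "b"

    # persistent per-patient tendency to follow the report; drug choices
    # recur only on progression, so between-patient heterogeneity here is
    # what makes matching scores informative about the received hazard
    if cfg.adherence in (0.0, 1.0):
        propensity = cfg.adherence
    else:
        c = cfg.adherence_concentration
        propensity = float(rng.beta(cfg.adherence * c,
                                    (1.0 - cfg.adherence) * c))

    background = cfg.background_drug
    on_background = (background is not None
                     and rng.random() < cfg.background_prob)

    administrations: list[AdministrationEvent] = []
    responses: list[ResponseAssessment] = []
    choosable = sorted(d for d in panel if d != background)
    available = list(choosable)
    current = _choose_drug(rng, scores, available, propensity)
    n_courses = 0
    n_matched = 0
    death_day: float | None = None

    t = 0
    horizon = cfg.study_horizon_days
    interval = cfg.assessment_interval_days
    while t < horizon:
        epoch_end = min(t + interval, horizon)
        # primary drug once per week of the epoch, offset one day past
        # the epoch start so the first dose is strictly post-report;
        # weekly spacing means one course per administration
        admin_days = list(range(t + 1, epoch_end + 1, 7))
        for day in admin_days:
            administrations.append(AdministrationEvent(
                patient_id=pid, drug=current,
                date=_ORIGIN + datetime.timedelta(days=day)))
            n_courses += 1
            if p_true[current] > 0.5:
                n_matched += 1
        if on_background:
            # twice-weekly background drug aggregates to one weekly
            # course, so it adds one course (not two) per week
            for day in admin_days:
                for offset in (0, 3):
                    if day + offset <= epoch_end:
                        administrations.append(AdministrationEvent(
                            patient_id=pid, drug=background,
                            date=_ORIGIN + datetime.timedelta(
                                days=day + offset)))
                n_courses += 1
                if p_true[background] > 0.5:
                    n_matched += 1
        f = n_matched / n_courses if n_courses else 0.0
        hazard = cfg.baseline_hazard * float(np.exp(cfg.beta_match * f))
        wait = rng.exponential(1.0 / hazard)
        if t + wait < epoch_end:
            death_day = t + wait
            break
        # assessment at epoch end while alive
        success = rng.random() < p_true[current]
        if success:
            cat = "CR" if rng.random() < cfg.success_cr_fraction else "PR"
        else:
            cat = "PD" if rng.random() < cfg.failure_pd_fraction else "SD"
        responses.append(ResponseAssessment(
            patient_id=pid, category=cat,
            date=_ORIGIN + datetime.timedelta(days=epoch_end)))
        if cat == "PD" and cfg.switch_on_progression:
            # switch away from the progressing drug; retired drugs stay
            # eligible later (memoryless choice), which keeps the
            # empirical-therapy drift toward effective drugs from
            # ratcheting survivors' scores upward under a null effect
            alternatives = [d for d in choosable if d != current]
            current = _choose_drug(rng, scores, alternatives, propensity)
        t = epoch_end

    administrations.sort(key=lambda e: (e.date, e.drug))
    if death_day is not None:
        death_date = _ORIGIN + datetime.timedelta(days=int(np.ceil(death_day)))
        death_date = max(death_date, _ORIGIN + datetime.timedelta(days=1))
        administrations = [a for a in administrations if a.date <= death_date]
        responses = [r for r in responses if r.date <= death_date]
        record = PatientRecord(
            patient_id=pid, grade=grade, stage=stage, substage=substage,
            report=report, administrations=administrations,
            responses=responses, last_followup_date=death_date,
            death_date=death_date, event=True)
    else:
        followup = _ORIGIN + datetime.timedelta(days=horizon)
        record = PatientRecord(
            patient_id=pid, grade=grade, stage=stage, substage=substage,
            report=report, administrations=administrations,
            responses=responses, last_followup_date=followup,
            death_date=None, event=False)
    # simulation-only diagnostics (not part of the CSV schema): the true
    # per-drug response probabilities, the final matched-course fraction
    # driving the hazard, and the latent adherence propensity
    record.sim_truth = {
        "p_true": dict(p_true),
        "matched_fraction": n_matched / n_courses if n_courses else 0.0,
        "propensity": propensity,
    }
    return record


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[PatientRecord], list[PredictionReport]]:
    """Simulate a cohort; deterministic given ``config.seed``.

    Patient ids (``P0000``, ``P0001``, ...) and the drug panel depend
    only on the config shape, and each patient consumes an independent
    child RNG stream, so changing a behavioral knob such as
    ``adherence`` leaves ids and panel unchanged.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    patients = [
        _simulate_patient(f"P{i:04d}", config, np.random.default_rng(s))
        for i, s in enumerate(streams)
    ]
    return patients, [p.report for p in patients]


def write_cohort(patients: Sequence[PatientRecord],
                 reports: Sequence[PredictionReport] | None,
                 directory: str | Path) -> dict[str, Path]:
    """Write the cohort as the four CSVs read back by ``read_cohort``."""
    if reports is not None:
        by_id = {r.patient_id: r for r in reports}
        for p in patients:
            if p.report is not by_id.get(p.patient_id, p.report):
                raise ValueError(
                    f"report list disagrees with patient {p.patient_id}")
    return write_cohort_csvs(patients, directory)


def _dichotomized_hr(patients: list[PatientRecord],
                     scores: dict[str, float]) -> tuple[float, float, float]:
    """Median-split Cox HR (and CI) of the high-vs-low group indicator."""
    ga = stratify.dichotomize(scores, method="median")
    df = pd.DataFrame({
        "duration": [float(p.survival_days) for p in patients],
        "event": [int(p.event) for p in patients],
        "group": [int(ga.assignment[p.patient_id] == "high")
                  for p in patients],
    })
    res = cox_model(df, ["group"], mode="multivariate")
    eff = res.effects[0]
    return eff.hr, eff.ci_low, eff.ci_high


def bias_experiment(config: SyntheticCohortConfig, n_reps: int,
                    shuffle: bool = True) -> pd.DataFrame:
    """Replicate the shuffled-recommendation diagnostic.

    Per replicate: generate a cohort, optionally shuffle reports across
    patients, compute both matching-score variants, median-dichotomize
    each, and fit a univariate Cox model on the group indicator.
    Returns one row per (replicate, score_variant) with HR and 95% CI.
    A drug-count-rewarding score shows HR < 1 even under the shuffle;
    an unbiased one does not.
    """
    config.validate()
    rows = []
    rep_seeds = np.random.SeedSequence(config.seed).spawn(n_reps)
    for rep, seq in enumerate(rep_seeds):
        child = seq.generate_state(2)
        rep_cfg = SyntheticCohortConfig(**{
            **config.to_dict(), "seed": int(child[0]),
            "drug_panel": config.drug_panel})
        patients, _ = generate_cohort(rep_cfg)
        patients, _ = inclusion_filter(patients)
        if shuffle:
            patients = matching.shuffle_predictions(
                patients, seed=int(child[1]), mode="across_patients")
        results = {}
        for p in patients:
            courses = aggregate_treatments(
                p.administrations, p.report.delivery_date)
            results[p.patient_id] = matching.compute_matching(
                courses, p.report)
        for variant in ("modified", "standard"):
            attr = f"{variant}_score"
            scored = [p for p in patients
                      if getattr(results[p.patient_id], attr) is not None]
            scores = {p.patient_id: getattr(results[p.patient_id], attr)
                      for p in scored}
            try:
                hr, lo, hi = _dichotomized_hr(scored, scores)
            except (ValueError, stratify.DegenerateStratificationError):
                hr = lo = hi = float("nan")
            rows.append({"replicate": rep, "score_variant": variant,
                         "hr": hr, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
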