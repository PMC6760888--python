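"""Synthetic claims generator with a known true adherence threshold.

Emulates a new-user lipid-lowering-drug cohort at desk scale: each patient
carries a latent adherence propensity p_i drawn from a right-skewed
two-component Beta mixture (defaults give median ~0.8 and a wide
interquartile range); refills of a fixed days-supply follow the index fill
with random extra gaps whose mean, supply·(1−p_i)/p_i, makes the expected
long-run coverage fraction equal p_i. Event hazards are exponential and jump
by a factor HR* when p_i falls below the true threshold tau*; hazards depend
on the latent propensity, not on realized PDC, so ground truth is
well-defined and realized PDC is exactly the noisy proxy the threshold
estimators face. Hospitalizations are a Poisson process with log-normal stay
lengths, loss to follow-up is exponential, and administrative censoring
applies at 1825 days. Configurable fractions of deliberately ineligible
patients (prior event, short follow-up, non-new user, unobservable clean
period) exercise the cohort filters.

All randomness flows from a single seed; per-patient substreams are spawned
deterministically from the patient index, so output CSVs are byte-identical
across runs for a fixed configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pdcthresh.claims_io import (
    COMORBIDITIES,
    DispensationRecord,
    EventType,
    HospitalStay,
    OutcomeEvent,
    PatientBaseline,
    Sex,
    write_table,
)

DAYS_PER_YEAR = 365.25


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Rates are per 1000 person-years for events and per year for
    hospitalization/loss processes; day parameters are integer days.
    """

    n_patients: int = 10_000
    seed: int = 0
    # adherence propensity: two-component Beta mixture (good / poor adherers)
    mixture_weights: tuple[float, float] = (0.62, 0.38)
    mixture_shapes: tuple[tuple[float, float], tuple[float, float]] = (
        (4.0, 0.55),
        (0.8, 1.5),
    )
    days_supply: int = 30
    gap_shape: float = 4.0  # gamma shape of the extra inter-fill gap
    discontinuation_hazard: float = 0.0  # per-refill probability of stopping
    # ground truth
    tau_star: float = 0.50
    hr_star: float = 2.0
    # baseline (good-adherer) event rates, per 1000 person-years
    acs_rate_per_1000py: float = 8.0
    death_rate_per_1000py: float = 7.0
    cv_death_fraction: float = 0.37
    # nuisance processes
    hospitalization_rate_per_year: float = 0.10
    stay_meanlog: float = 2.08  # median stay ~8 days
    stay_sdlog: float = 1.57  # IQR ~3-25 days
    loss_rate_per_year: float = 0.02
    max_followup_days: int = 1825
    lookback_days: int = 365
    # deliberately ineligible fractions
    frac_prior_event: float = 0.03
    frac_short_followup: float = 0.03
    frac_non_new_user: float = 0.03
    frac_insufficient_history: float = 0.01
    # baseline covariate prevalences (independent of adherence and hazard)
    age_mean: float = 61.0
    age_sd: float = 12.5
    male_fraction: float = 0.541
    comorbidity_prevalence: dict = field(
        default_factory=lambda: {
            "diabetes": 0.425,
            "copd": 0.093,
            "asthma": 0.128,
            "heart_failure": 0.073,
            "ihd_history": 0.229,
            "mental_health": 0.498,
            "ckd": 0.036,
        }
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.tau_star < 1.0):
            raise ValueError("tau_star must lie in (0, 1)")
        if self.hr_star <= 0:
            raise ValueError("hr_star must be > 0")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        for name in (
            "acs_rate_per_1000py",
            "death_rate_per_1000py",
            "hospitalization_rate_per_year",
            "loss_rate_per_year",
            "discontinuation_hazard",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the data; never consumed by the pipeline."""

    tau_star: float
    hr_star: float
    per_patient: pd.DataFrame  # patient_id, propensity, poor_adherer, role


@dataclass
class StudyTables:
    dispensations: list[DispensationRecord]
    hospital_stays: list[HospitalStay]
    outcomes: list[OutcomeEvent]
    patients: list[PatientBaseline]
    truth: SimTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(self.dispensations, out / "dispensations.csv", "dispensations")
        write_table(self.hospital_stays, out / "hospital_stays.csv", "hospital_stays")
        write_table(self.outcomes, out / "outcomes.csv", "outcomes")
        write_table(self.patients, out / "patients.csv", "patients")
        truth = self.truth.per_patient.copy()
        truth["tau_star"] = self.truth.tau_star
        truth["hr_star"] = self.truth.hr_star
        truth.to_csv(out / "truth.csv", index=False, encoding="utf-8")


def sample_propensities(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one adherence propensity per patient from the Beta mixture."""
    n = config.n_patients
    (a1, b1), (a2, b2) = config.mixture_shapes
    comp = rng.random(n) >= config.mixture_weights[0]
    p = np.where(comp, rng.beta(a2, b2, n), rng.beta(a1, b1, n))
    return np.clip(p, 1e-6, 1.0 - 1e-6)


def generate_dispensations(
    p_i: float,
    index_day: int,
    stop_day: int,
    config: SimConfig,
    rng: np.random.Generator,
    patient_id: str,
) -> list[DispensationRecord]:
    """Refill sequence for one patient from the index fill until ``stop_day``.

    The extra gap after each supply runs out is gamma-distributed with mean
    supply·(1−p)/p (shape ``gap_shape``), so long-run expected coverage is p.
    An optional per-refill discontinuation hazard stops refills permanently.
    """
    supply = config.days_supply
    mean_gap = supply * (1.0 - p_i) / p_i
    records = [DispensationRecord(patient_id, index_day, supply)]
    day = index_day
    horizon = stop_day
    while True:
        if config.discontinuation_hazard > 0 and rng.random() < config.discontinuation_hazard:
            break
        if mean_gap > 0:
            gap = int(round(rng.gamma(config.gap_shape, mean_gap / config.gap_shape)))
        else:
            gap = 0
        day = day + supply + gap
        if day >= horizon:
            break
        records.append(DispensationRecord(patient_id, day, supply))
    return records


def _event_time(rate_per_1000py: float, mult: float, rng: np.random.Generator) -> float:
    """Exponential waiting time in days (inf when the rate is zero)."""
    lam = rate_per_1000py / 1000.0 / DAYS_PER_YEAR * mult
    if lam <= 0:
        return math.inf
    return rng.exponential(1.0 / lam)


def generate_study(config: SimConfig) -> StudyTables:
    """Generate the four claims tables plus ground truth for one cohort."""
    n = config.n_patients
    root = np.random.SeedSequence(config.seed)
    global_rng = np.random.default_rng(root.spawn(1)[0])
    patient_seeds = root.spawn(n + 1)[1:]

    propensities = sample_propensities(config, global_rng)
    poor = propensities < config.tau_star

    # assign ineligibility roles from the global stream
    roles = np.full(n, "eligible", dtype=object)
    u = global_rng.random(n)
    edges = np.cumsum(
        [
            config.frac_prior_event,
            config.frac_short_followup,
            config.frac_non_new_user,
            config.frac_insufficient_history,
        ]
    )
    roles[u < edges[0]] = "prior_event"
    roles[(u >= edges[0]) & (u < edges[1])] = "short_followup"
    roles[(u >= edges[1]) & (u < edges[2])] = "non_new_user"
    roles[(u >= edges[2]) & (u < edges[3])] = "insufficient_history"

    ages = np.clip(global_rng.normal(config.age_mean, config.age_sd, n), 30.0, 95.0)
    male = global_rng.random(n) < config.male_fraction
    comorb = {
        c: global_rng.random(n) < config.comorbidity_prevalence[c]
        for c in COMORBIDITIES
    }

    dispensations: list[DispensationRecord] = []
    stays: list[HospitalStay] = []
    outcomes: list[OutcomeEvent] = []
    patients: list[PatientBaseline] = []

    cap = config.max_followup_days
    for i in range(n):
        pid = f"P{i:06d}"
        rng = np.random.default_rng(patient_seeds[i])
        p = float(propensities[i])
        role = roles[i]
        hr_mult = config.hr_star if poor[i] else 1.0

        if role == "insufficient_history":
            # single fill before a full clean period is observable
            day = int(rng.integers(0, config.lookback_days // 2))
            dispensations.append(DispensationRecord(pid, day, config.days_supply))
            patients.append(
                PatientBaseline(
                    pid, float(ages[i]), Sex.M if male[i] else Sex.F,
                    **{c: bool(comorb[c][i]) for c in COMORBIDITIES},
                    enrol_start_day=0, enrol_end_day=day + cap,
                )
            )
            continue
        if role == "non_new_user":
            # steady refill chain starting inside the clean period: every
            # fill with observable history has a prior fill within lookback
            day = int(rng.integers(0, config.lookback_days // 2))
            end = day + cap
            dispensations.extend(
                generate_dispensations(max(p, 0.5), day, end, config, rng, pid)
            )
            patients.append(
                PatientBaseline(
                    pid, float(ages[i]), Sex.M if male[i] else Sex.F,
                    **{c: bool(comorb[c][i]) for c in COMORBIDITIES},
                    enrol_start_day=0, enrol_end_day=end,
                )
            )
            continue

        index_day = config.lookback_days + int(rng.integers(0, 366))

        # latent event/censoring times, in days after index
        t_acs = _event_time(config.acs_rate_per_1000py, hr_mult, rng)
        t_death = _event_time(config.death_rate_per_1000py, hr_mult, rng)
        t_loss = _event_time(config.loss_rate_per_year * 1000.0, 1.0, rng)
        if role == "short_followup":
            t_loss = float(rng.integers(14, 180 - config.days_supply))
        loss_day = (
            index_day + max(1, int(math.ceil(t_loss)))
            if t_loss < cap
            else index_day + cap + 365
        )
        death_day = (
            index_day + max(1, int(math.ceil(t_death))) if t_death <= cap else None
        )
        observation_end = min(loss_day, death_day or loss_day, index_day + cap)

        if death_day is not None and death_day <= min(loss_day, index_day + cap):
            outcomes.append(
                OutcomeEvent(
                    pid, EventType.DEATH, death_day,
                    cv_cause=bool(rng.random() < config.cv_death_fraction),
                    icd_code=None,
                )
            )
        acs_day = (
            index_day + max(1, int(math.ceil(t_acs))) if t_acs <= cap else None
        )
        if acs_day is not None and acs_day <= observation_end:
            outcomes.append(OutcomeEvent(pid, EventType.ACS_STROKE, acs_day))
        if role == "prior_event":
            prior_day = index_day - int(rng.integers(30, 300))
            outcomes.append(OutcomeEvent(pid, EventType.ACS_STROKE, max(0, prior_day)))

        dispensations.extend(
            generate_dispensations(p, index_day, observation_end, config, rng, pid)
        )

        # hospitalizations: Poisson over the observation period
        obs_years = (observation_end - index_day) / DAYS_PER_YEAR
        n_stays = rng.poisson(config.hospitalization_rate_per_year * max(obs_years, 0))
        for _ in range(n_stays):
            admit = int(rng.integers(index_day, observation_end))
            length = max(1, int(round(rng.lognormal(config.stay_meanlog, config.stay_sdlog))))
            stays.append(HospitalStay(pid, admit, admit + length))

        patients.append(
            PatientBaseline(
                pid, float(ages[i]), Sex.M if male[i] else Sex.F,
                **{c: bool(comorb[c][i]) for c in COMORBIDITIES},
                enrol_start_day=0, enrol_end_day=loss_day,
            )
        )

    truth = SimTruth(
        tau_star=config.tau_star,
        hr_star=config.hr_star,
        per_patient=pd.DataFrame(
            {
                "patient_id": [f"P{i:06d}" for i in range(n)],
                "propensity": propensities,
                "poor_adherer": poor.astype(int),
                "role": roles,
            }
        ),
    )
    return StudyTables(dispensations, stays, outcomes, patients, truth)
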