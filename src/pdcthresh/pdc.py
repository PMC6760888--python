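"""Proportion-of-days-covered (PDC) from dispensation claims.

A patient's PDC over an observation window is the fraction of window days on
which dispensed supply of any drug in the class covers the day. Two overlap
rules are provided:

``union``
    a day is covered if at least one fill's supply interval
    ``[dispense_day, dispense_day + days_supply)`` spans it (the
    conventional PDC definition);
``carryover``
    early-refill surplus is stockpiled — each fill starts dispensing when
    the previous supply runs out, shifting overlap forward in time.

Hospital days are removed from both numerator and denominator: drug use in
hospital is not observable in pharmacy claims, so those days can neither
count as covered nor as observation time.

Windows are outcome-specific: for patients with the event the window (and
the survival time) ends at the event day; for patients lost to follow-up it
ends at their specific end date; completers get a fixed window capped at the
administrative maximum (1825 days).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

from pdcthresh.claims_io import (
    COMORBIDITIES,
    DispensationRecord,
    EventType,
    HospitalStay,
    OutcomeEvent,
    PatientBaseline,
    RunConfig,
    Sex,
)
from pdcthresh.cohort import CohortEntry, ConsistencyError

logger = logging.getLogger(__name__)

Interval = tuple[int, int]  # half-open [start, end)

OUTCOME_KINDS = ("ACS_STROKE", "ALL_CAUSE_DEATH", "CV_DEATH")


class WindowAnchor(str, enum.Enum):
    EVENT_ANCHORED = "EVENT_ANCHORED"
    FIXED_1825 = "FIXED_1825"
    CENSOR_ANCHORED = "CENSOR_ANCHORED"


@dataclass(frozen=True)
class ObservationWindow:
    start_day: int
    end_day: int
    outcome_anchor: WindowAnchor = WindowAnchor.FIXED_1825

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise ValueError("end_day must be > start_day")

    @property
    def length(self) -> int:
        return self.end_day - self.start_day


class ZeroDenominatorError(ValueError):
    """The entire observation window is in hospital: PDC is undefined."""


@dataclass(frozen=True)
class AnalysisRow:
    """One patient's (PDC, time, event, covariates) for one outcome."""

    patient_id: str
    pdc: float
    time_days: int
    event: bool
    age_years: float
    sex_male: bool
    diabetes: bool
    copd: bool
    asthma: bool
    heart_failure: bool
    ihd_history: bool
    mental_health: bool
    ckd: bool
    hospitalized: bool


# ---------------------------------------------------------------------------
# interval arithmetic


def _merge(intervals: list[Interval]) -> list[Interval]:
    """Union of half-open intervals as a sorted disjoint list."""
    out: list[Interval] = []
    for s, e in sorted(i for i in intervals if i[1] > i[0]):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _clip(intervals: list[Interval], window: ObservationWindow) -> list[Interval]:
    lo, hi = window.start_day, window.end_day
    return [(max(s, lo), min(e, hi)) for s, e in intervals if min(e, hi) > max(s, lo)]


def _total(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def _subtract(base: list[Interval], minus: list[Interval]) -> list[Interval]:
    """Set difference of disjoint sorted interval lists."""
    out: list[Interval] = []
    for s, e in base:
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _supply_intervals(
    dispensations: list[DispensationRecord], mode: str
) -> list[Interval]:
    fills = sorted(
        (d.dispense_day, d.days_supply) for d in dispensations
    )
    if mode == "union":
        return _merge([(day, day + supply) for day, supply in fills])
    if mode == "carryover":
        # each fill starts dispensing when the previous supply runs out
        intervals: list[Interval] = []
        supply_end = None
        for day, supply in fills:
            start = day if supply_end is None else max(day, supply_end)
            supply_end = start + supply
            intervals.append((start, supply_end))
        return _merge(intervals)
    raise ValueError(f"unknown PDC mode: {mode!r}")


# ---------------------------------------------------------------------------
# public operations


def coverage_days(
    dispensations: list[DispensationRecord],
    window: ObservationWindow,
    mode: str = "union",
) -> int:
    """Days of the window covered by dispensed supply under ``mode``.

    Fills outside the window contribute their in-window overlap, including
    the in-window remainder of a pre-window fill (carry-in) — this matters
    for event-anchored sub-windows, since the window otherwise starts at the
    first fill by construction.
    """
    return _total(_clip(_supply_intervals(dispensations, mode), window))


def compute_pdc(
    dispensations: list[DispensationRecord],
    window: ObservationWindow,
    hospital_stays: list[HospitalStay] = (),
    mode: str = "union",
) -> float:
    """PDC = covered days outside hospital / (window days − hospital days)."""
    hosp = _clip(_merge([(h.admit_day, h.discharge_day) for h in hospital_stays]), window)
    denominator = window.length - _total(hosp)
    if denominator <= 0:
        raise ZeroDenominatorError(
            f"window [{window.start_day}, {window.end_day}) entirely in hospital"
        )
    covered = _clip(_supply_intervals(dispensations, mode), window)
    numerator = _total(_subtract(covered, hosp))
    return numerator / denominator


def build_analysis_table(
    cohort: list[CohortEntry],
    dispensations: list[DispensationRecord],
    stays: list[HospitalStay],
    outcomes: list[OutcomeEvent],
    patients: list[PatientBaseline],
    outcome_kind: str,
    config: RunConfig | None = None,
) -> list[AnalysisRow]:
    """Assemble one analysis row per included patient for one outcome.

    The observation window and the survival time share the anchor: event
    cases end at the event day, lost/censored patients at their specific end
    date, completers at the fixed administrative cap. In the CV-mortality
    analysis a non-cardiovascular death censors at the death day.
    """
    if outcome_kind not in OUTCOME_KINDS:
        raise ValueError(f"unknown outcome kind: {outcome_kind!r}")
    config = config or RunConfig()
    cap = config.max_followup_days

    disp_by_pid: dict[str, list[DispensationRecord]] = {}
    for d in dispensations:
        disp_by_pid.setdefault(d.patient_id, []).append(d)
    stays_by_pid: dict[str, list[HospitalStay]] = {}
    for h in stays:
        stays_by_pid.setdefault(h.patient_id, []).append(h)
    events_by_pid: dict[str, list[OutcomeEvent]] = {}
    for ev in outcomes:
        events_by_pid.setdefault(ev.patient_id, []).append(ev)
    baseline = {p.patient_id: p for p in patients}

    rows: list[AnalysisRow] = []
    for entry in cohort:
        if not entry.included:
            continue
        idx = entry.index_day
        p = baseline[entry.patient_id]
        evs = events_by_pid.get(entry.patient_id, [])
        acs = [e.event_day for e in evs if e.event_type is EventType.ACS_STROKE and e.event_day >= idx]
        deaths = [e for e in evs if e.event_type is EventType.DEATH]
        death_day = min((e.event_day for e in deaths), default=None)
        cv_death = any(e.cv_cause for e in deaths)
        for ev in evs:
            if ev.event_day > p.enrol_end_day:
                raise ConsistencyError(
                    f"patient {entry.patient_id!r}: outcome at day {ev.event_day} "
                    f"after enrolment end {p.enrol_end_day}"
                )

        admin_end = idx + cap
        censor_end = min(p.enrol_end_day, admin_end)
        if outcome_kind == "ACS_STROKE":
            event_day = min(acs, default=None)
        else:
            event_day = death_day
        if event_day is not None and event_day <= censor_end:
            end_day = event_day
            observed = True
        else:
            # death censors the ACS/stroke analysis at the death day
            if outcome_kind == "ACS_STROKE" and death_day is not None:
                end_day = min(death_day, censor_end)
            else:
                end_day = censor_end
            observed = False
        if outcome_kind == "CV_DEATH" and observed and not cv_death:
            observed = False  # non-CV death: censoring, not an event

        if observed:
            anchor = WindowAnchor.EVENT_ANCHORED
        elif end_day == admin_end:
            anchor = WindowAnchor.FIXED_1825
        else:
            anchor = WindowAnchor.CENSOR_ANCHORED
        window = ObservationWindow(idx, end_day, anchor)

        patient_stays = stays_by_pid.get(entry.patient_id, [])
        try:
            pdc = compute_pdc(
                disp_by_pid.get(entry.patient_id, []),
                window,
                patient_stays,
                mode=config.pdc_mode,
            )
        except ZeroDenominatorError:
            logger.warning(
                "patient %s: window [%d, %d) entirely in hospital; "
                "excluded from %s analysis",
                entry.patient_id, idx, end_day, outcome_kind,
            )
            continue

        hospitalized = any(
            h.discharge_day > idx and h.admit_day < end_day for h in patient_stays
        )
        rows.append(
            AnalysisRow(
                patient_id=entry.patient_id,
                pdc=pdc,
                time_days=window.length,
                event=observed,
                age_years=p.age_years,
                sex_male=p.sex is Sex.M,
                **{c: getattr(p, c) for c in COMORBIDITIES},
                hospitalized=hospitalized,
            )
        )
    return rows


def rows_to_frame(rows: list[AnalysisRow]):
    """Analysis rows as a DataFrame (numeric covariates, ready for Cox fits)."""
    import pandas as pd

    df = pd.DataFrame([r.__dict__ for r in rows])
    for col in ("event", "sex_male", "hospitalized", *COMORBIDITIES):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return df
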