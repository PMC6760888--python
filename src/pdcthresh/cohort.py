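"""New-user cohort construction: index dates, exclusions, follow-up windows.

The design is a classic new-user cohort: a patient enters at the first
dispensation that is preceded by a fully observable clean period (no
dispensation of the drug class during the lookback, default 365 days, and
database enrolment covering all of it). Patients with the outcome before
initiation or with under ``min_followup_days`` of observable follow-up are
excluded. Follow-up is capped at ``max_followup_days`` (default 1825).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from pdcthresh.claims_io import (
    DispensationRecord,
    EventType,
    OutcomeEvent,
    PatientBaseline,
)


class EndReason(str, enum.Enum):
    EVENT = "EVENT"
    DEATH = "DEATH"
    LOST = "LOST"
    ADMIN_1825 = "ADMIN_1825"


class ExclusionFlag(str, enum.Enum):
    INSUFFICIENT_HISTORY = "INSUFFICIENT_HISTORY"
    NOT_NEW_USER = "NOT_NEW_USER"
    PRIOR_EVENT = "PRIOR_EVENT"
    SHORT_FOLLOWUP = "SHORT_FOLLOWUP"


#: fixed precedence used only for funnel counting: a patient with several
#: flags is counted once, under the first applicable flag in this order.
EXCLUSION_PRECEDENCE = (
    ExclusionFlag.INSUFFICIENT_HISTORY,
    ExclusionFlag.NOT_NEW_USER,
    ExclusionFlag.PRIOR_EVENT,
    ExclusionFlag.SHORT_FOLLOWUP,
)


class ReferentialError(ValueError):
    """A claims row refers to a patient absent from the baseline table."""


class ConsistencyError(ValueError):
    """Cross-table contradiction (e.g. outcome before enrolment start)."""


@dataclass
class CohortEntry:
    """One candidate patient with index date, follow-up window and audit trail.

    ``exclusion_flags`` is empty exactly for included patients. For entries
    without a qualifying index date, ``index_day`` is None and the follow-up
    fields are unset (None).
    """

    patient_id: str
    index_day: int | None
    followup_end_day: int | None = None
    end_reason: EndReason | None = None
    exclusion_flags: set[ExclusionFlag] = field(default_factory=set)

    @property
    def included(self) -> bool:
        return not self.exclusion_flags

    @property
    def followup_days(self) -> int | None:
        if self.index_day is None or self.followup_end_day is None:
            return None
        return self.followup_end_day - self.index_day


def identify_new_users(
    dispensations: list[DispensationRecord],
    patients: list[PatientBaseline],
    lookback_days: int = 365,
) -> dict[str, int | ExclusionFlag]:
    """Find each patient's index day, or the reason none exists.

    The index day is the earliest dispensation preceded by at least
    ``lookback_days`` of enrolment with no dispensation of the class in
    ``[index - lookback_days, index)``. A candidate fill whose clean period
    is not fully observable cannot establish new use and yields
    INSUFFICIENT_HISTORY; one with a prior fill inside the lookback yields
    NOT_NEW_USER. Only the first qualifying index is taken.
    """
    if lookback_days < 1:
        raise ValueError("lookback_days must be >= 1")
    baseline = {p.patient_id: p for p in patients}
    by_patient: dict[str, list[int]] = {}
    for d in dispensations:
        if d.patient_id not in baseline:
            raise ReferentialError(
                f"dispensation for unknown patient {d.patient_id!r}"
            )
        by_patient.setdefault(d.patient_id, []).append(d.dispense_day)

    result: dict[str, int | ExclusionFlag] = {}
    for pid, days in by_patient.items():
        days = sorted(days)
        p = baseline[pid]
        saw_clean_violation = False
        for i, day in enumerate(days):
            if day - lookback_days < p.enrol_start_day:
                continue  # clean period not observable for this fill
            prior_in_window = any(
                day - lookback_days <= d < day for d in days[:i]
            )
            if prior_in_window:
                saw_clean_violation = True
                continue
            result[pid] = day
            break
        else:
            result[pid] = (
                ExclusionFlag.NOT_NEW_USER
                if saw_clean_violation
                else ExclusionFlag.INSUFFICIENT_HISTORY
            )
    return result


def apply_exclusions(
    candidates: dict[str, int | ExclusionFlag],
    outcomes: list[OutcomeEvent],
    patients: list[PatientBaseline],
    min_followup_days: int = 180,
    max_followup_days: int = 1825,
) -> list[CohortEntry]:
    """Assign follow-up windows and exclusion flags to index candidates.

    Follow-up ends at the earliest of: first post-index ACS/stroke event,
    death, enrolment end (loss to follow-up), and the administrative cap
    ``index + max_followup_days``; ties are resolved EVENT > DEATH >
    ADMIN_1825 > LOST so an event on the censoring day still counts.
    SHORT_FOLLOWUP is strict: exactly ``min_followup_days`` of follow-up is
    included. Output is sorted by patient_id, so it does not depend on input
    row order.
    """
    baseline = {p.patient_id: p for p in patients}
    events_by_patient: dict[str, list[OutcomeEvent]] = {}
    for ev in outcomes:
        if ev.patient_id in baseline:
            if ev.event_day < baseline[ev.patient_id].enrol_start_day:
                raise ConsistencyError(
                    f"patient {ev.patient_id!r}: outcome at day {ev.event_day} "
                    f"precedes enrolment start"
                )
        events_by_patient.setdefault(ev.patient_id, []).append(ev)

    entries: list[CohortEntry] = []
    for pid in sorted(candidates):
        idx = candidates[pid]
        if isinstance(idx, ExclusionFlag):
            entries.append(
                CohortEntry(patient_id=pid, index_day=None, exclusion_flags={idx})
            )
            continue
        p = baseline[pid]
        evs = events_by_patient.get(pid, [])
        flags: set[ExclusionFlag] = set()

        acs_days = [e.event_day for e in evs if e.event_type is EventType.ACS_STROKE]
        death_days = [e.event_day for e in evs if e.event_type is EventType.DEATH]
        if any(d < idx for d in acs_days):
            flags.add(ExclusionFlag.PRIOR_EVENT)

        # candidate ends, in tie-breaking precedence order
        ends: list[tuple[int, EndReason]] = []
        post_acs = [d for d in acs_days if d >= idx]
        if post_acs:
            ends.append((min(post_acs), EndReason.EVENT))
        if death_days:
            ends.append((min(death_days), EndReason.DEATH))
        ends.append((idx + max_followup_days, EndReason.ADMIN_1825))
        ends.append((p.enrol_end_day, EndReason.LOST))
        end_day, reason = min(ends, key=lambda t: t[0])  # stable: earlier wins ties

        if end_day - idx < min_followup_days:
            flags.add(ExclusionFlag.SHORT_FOLLOWUP)
        entries.append(
            CohortEntry(
                patient_id=pid,
                index_day=idx,
                followup_end_day=end_day,
                end_reason=reason,
                exclusion_flags=flags,
            )
        )
    return entries


def build_cohort(
    dispensations: list[DispensationRecord],
    patients: list[PatientBaseline],
    outcomes: list[OutcomeEvent],
    lookback_days: int = 365,
    min_followup_days: int = 180,
    max_followup_days: int = 1825,
) -> list[CohortEntry]:
    """Convenience chain: identify_new_users then apply_exclusions."""
    candidates = identify_new_users(dispensations, patients, lookback_days)
    return apply_exclusions(
        candidates, outcomes, patients, min_followup_days, max_followup_days
    )


def cohort_summary(entries: list[CohortEntry]) -> dict[str, int]:
    """Funnel counts: total, included, and exclusions by first applicable flag."""
    counts = {"total": len(entries), "included": 0}
    for flag in EXCLUSION_PRECEDENCE:
        counts[f"excluded_{flag.value}"] = 0
    for e in entries:
        if e.included:
            counts["included"] += 1
            continue
        for flag in EXCLUSION_PRECEDENCE:
            if flag in e.exclusion_flags:
                counts[f"excluded_{flag.value}"] += 1
                break
    return counts
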