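"""End-to-end orchestration: cohort → PDC → cutpoints → Cox comparison.

One report section per outcome (hospitalization for ACS/stroke, all-cause
mortality, cardiovascular mortality), each with an overall block and, when
enabled, age-stratified blocks (<65 / >=65 at index) in which the whole
chain — including cutpoint estimation — is rerun within the stratum. The
report is a pure function of (input tables, config): plain nested dicts,
serializable by :func:`pdcthresh.claims_io.write_report`.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from pdcthresh.claims_io import (
    DispensationRecord,
    HospitalStay,
    OutcomeEvent,
    PatientBaseline,
    RunConfig,
    read_table,
)
from pdcthresh.cohort import build_cohort, cohort_summary
from pdcthresh.cutpoints import (
    contal_oquigley_scan,
    make_candidate_grid,
    min_distance_threshold,
    roc_points,
    youden_threshold,
)
from pdcthresh.model_comparison import compare_thresholds, retain_threshold_range
from pdcthresh.pdc import OUTCOME_KINDS, build_analysis_table

logger = logging.getLogger(__name__)


@dataclass
class InputTables:
    dispensations: list[DispensationRecord]
    hospital_stays: list[HospitalStay]
    outcomes: list[OutcomeEvent]
    patients: list[PatientBaseline]

    @classmethod
    def from_dir(cls, path: str | Path) -> "InputTables":
        path = Path(path)
        return cls(
            dispensations=read_table(path / "dispensations.csv", "dispensations")
            .raise_on_rejects()
            .records,
            hospital_stays=read_table(path / "hospital_stays.csv", "hospital_stays")
            .raise_on_rejects()
            .records,
            outcomes=read_table(path / "outcomes.csv", "outcomes")
            .raise_on_rejects()
            .records,
            patients=read_table(path / "patients.csv", "patients")
            .raise_on_rejects()
            .records,
        )


class StageError(RuntimeError):
    """Failure wrapped with the pipeline stage and outcome/stratum labels."""


def _covariates_for(config: RunConfig, outcome_kind: str) -> tuple[str, ...]:
    covs = config.covariates.get(outcome_kind, ())
    if not config.include_hospitalized_covariate:
        covs = tuple(c for c in covs if c != "hospitalized")
    return covs


def _alternate_thresholds(
    method_thresholds: dict[str, float], config: RunConfig, admissible: set[float]
) -> dict[float, str]:
    """Comparison-table threshold set with provenance labels.

    Each method threshold is bracketed by the configured symmetric offsets;
    the conventional 0.80 is always proposed. Only thresholds admissible on
    the candidate grid are kept.
    """
    chosen: dict[float, str] = {}
    for method, t in method_thresholds.items():
        if t in admissible:
            chosen.setdefault(t, method)
    for t in method_thresholds.values():
        for off in config.alternate_offsets:
            alt = round(t + off, 10)
            if alt in admissible:
                chosen.setdefault(alt, "alternate")
    conv = round(config.conventional_threshold, 10)
    if conv in admissible:
        chosen.setdefault(conv, "conventional")
    return chosen


def _analysis_block(tables: InputTables, outcome_kind: str, config: RunConfig) -> dict:
    """Full chain for one outcome on one (sub)population."""
    cohort = build_cohort(
        tables.dispensations,
        tables.patients,
        tables.outcomes,
        lookback_days=config.lookback_days,
        min_followup_days=config.min_followup_days,
        max_followup_days=config.max_followup_days,
    )
    funnel = cohort_summary(cohort)
    rows = build_analysis_table(
        cohort,
        tables.dispensations,
        tables.hospital_stays,
        tables.outcomes,
        tables.patients,
        outcome_kind,
        config,
    )
    n_events = sum(r.event for r in rows)
    base = {
        "outcome": outcome_kind,
        "funnel": funnel,
        "n_rows": len(rows),
        "n_events": n_events,
    }
    try:
        grid = make_candidate_grid(
            [r.pdc for r in rows],
            mode=config.grid_mode,
            resolution=config.grid_resolution,
            trim_fraction=config.trim_fraction,
        )
        co_result, scan = contal_oquigley_scan(rows, grid)
        roc = roc_points(rows, grid)
        yj = youden_threshold(roc)
        md = min_distance_threshold(roc)
    except ValueError as exc:
        logger.warning("%s: %s", outcome_kind, exc)
        return {**base, "insufficient_events": str(exc)}

    z_at = dict(zip(scan.candidates, scan.z))
    cutpoints = {
        "contal_oquigley": {
            "threshold": co_result.threshold,
            "statistic": co_result.statistic,
            "z_at_threshold": z_at.get(co_result.threshold),
            "p_approx": scan.p_approx,
            "n_event_times": scan.n_event_times,
        },
        "youden": {"threshold": yj.threshold, "statistic": yj.statistic},
        "min_distance": {"threshold": md.threshold, "statistic": md.statistic},
    }
    method_thresholds = {
        "contal_oquigley": co_result.threshold,
        "youden": yj.threshold,
        "min_distance": md.threshold,
    }
    provenance = _alternate_thresholds(
        method_thresholds, config, set(grid.candidates)
    )
    covariates = _covariates_for(config, outcome_kind)
    try:
        table = compare_thresholds(
            rows, list(provenance), covariates, provenance=provenance
        )
    except (RuntimeError, ValueError) as exc:
        raise StageError(
            f"survival_model_comparison failed for {outcome_kind}: {exc}"
        ) from exc
    retained, rng = retain_threshold_range(table, cut=config.delta_aic_cut)
    return {
        **base,
        "cutpoints": cutpoints,
        "comparison_table": table.to_records(),
        "reference_threshold": table.reference_threshold,
        "retained": {"thresholds": retained, "range": list(rng)},
    }


def _subset_by_age(tables: InputTables, lo: float, hi: float) -> InputTables:
    keep = {p.patient_id for p in tables.patients if lo <= p.age_years < hi}
    return InputTables(
        dispensations=[d for d in tables.dispensations if d.patient_id in keep],
        hospital_stays=[h for h in tables.hospital_stays if h.patient_id in keep],
        outcomes=[o for o in tables.outcomes if o.patient_id in keep],
        patients=[p for p in tables.patients if p.patient_id in keep],
    )


def run_outcome_analysis(
    tables: InputTables, outcome_kind: str, config: RunConfig
) -> dict:
    """Overall block plus (optionally) age-stratified blocks for one outcome."""
    t0 = time.perf_counter()
    section = {"overall": _analysis_block(tables, outcome_kind, config)}
    if config.stratify_by_age:
        cut = config.age_cut
        for label, lo, hi in (
            (f"age_lt_{int(cut)}", float("-inf"), cut),
            (f"age_ge_{int(cut)}", cut, float("inf")),
        ):
            sub = _subset_by_age(tables, lo, hi)
            try:
                section[label] = _analysis_block(sub, outcome_kind, config)
            except StageError as exc:
                raise StageError(f"[{label}] {exc}") from exc
    logger.info(
        "outcome %s analysed in %.1fs", outcome_kind, time.perf_counter() - t0
    )
    return section


def run_full_study(tables: InputTables, config: RunConfig) -> dict:
    """All three outcomes, each with overall and age-stratified blocks."""
    cfg_yaml = yaml.safe_dump(
        {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.__dict__.items()
            if not isinstance(v, dict)
        },
        sort_keys=True,
    )
    report: dict = {
        "provenance": {
            "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "seed": config.seed,
            "n_dispensations": len(tables.dispensations),
            "n_hospital_stays": len(tables.hospital_stays),
            "n_outcome_events": len(tables.outcomes),
            "n_patients": len(tables.patients),
        },
        "outcomes": {},
    }
    for kind in OUTCOME_KINDS:
        try:
            report["outcomes"][kind] = run_outcome_analysis(tables, kind, config)
        except StageError as exc:
            raise StageError(f"[{kind}] {exc}") from exc
    return report
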