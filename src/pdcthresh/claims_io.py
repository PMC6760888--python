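"""Claims-style data model, strict CSV table I/O, run configuration, reports.

All dates are integer day offsets from a per-dataset epoch and all intervals
are half-open ``[start, end)``: day counting is plain subtraction and no
calendar logic exists anywhere in the package. CSV (comma-separated, header
required, UTF-8) is the only on-disk dialect.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterator

import pandas as pd
import yaml


class SchemaError(ValueError):
    """Header of an input table does not match the documented columns."""


class ReportError(ValueError):
    """A report is structurally unfit for serialization."""


class EventType(str, enum.Enum):
    ACS_STROKE = "ACS_STROKE"
    DEATH = "DEATH"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


@dataclass(frozen=True)
class DispensationRecord:
    """One pharmacy fill of any lipid-lowering drug.

    ``drug_class`` only confirms class membership — switches between drugs of
    the class are pooled, so coverage is computed over all records jointly.
    """

    patient_id: str
    dispense_day: int
    days_supply: int
    drug_class: str = "LLD"

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise ValueError("days_supply must be >= 1")


@dataclass(frozen=True)
class HospitalStay:
    """An inpatient episode, half-open [admit_day, discharge_day)."""

    patient_id: str
    admit_day: int
    discharge_day: int

    def __post_init__(self) -> None:
        if self.discharge_day < self.admit_day:
            raise ValueError("discharge_day must be >= admit_day")


@dataclass(frozen=True)
class OutcomeEvent:
    """A hospitalization for ACS/stroke or a death.

    ``cv_cause`` is meaningful only for deaths and marks a cardiovascular
    underlying cause; ``icd_code`` is carried as an opaque annotation.
    """

    patient_id: str
    event_type: EventType
    event_day: int
    cv_cause: bool = False
    icd_code: str | None = None

    def __post_init__(self) -> None:
        if self.cv_cause and self.event_type is not EventType.DEATH:
            raise ValueError("cv_cause is only meaningful for DEATH events")


@dataclass(frozen=True)
class PatientBaseline:
    patient_id: str
    age_years: float
    sex: Sex
    diabetes: bool = False
    copd: bool = False
    asthma: bool = False
    heart_failure: bool = False
    ihd_history: bool = False
    mental_health: bool = False
    ckd: bool = False
    enrol_start_day: int = 0
    enrol_end_day: int = 0

    def __post_init__(self) -> None:
        if self.enrol_end_day <= self.enrol_start_day:
            raise ValueError("enrol_end_day must be > enrol_start_day")


COMORBIDITIES = (
    "diabetes",
    "copd",
    "asthma",
    "heart_failure",
    "ihd_history",
    "mental_health",
    "ckd",
)

#: covariate sets used in the adjusted Cox models, per outcome. The
#: ACS/stroke analysis additionally adjusts for any hospitalization during
#: follow-up; the mortality analyses do not.
DEFAULT_COVARIATES = {
    "ACS_STROKE": ("age_years", "sex_male") + COMORBIDITIES + ("hospitalized",),
    "ALL_CAUSE_DEATH": ("age_years", "sex_male") + COMORBIDITIES,
    "CV_DEATH": ("age_years", "sex_male") + COMORBIDITIES,
}


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, with conventional defaults.

    Day parameters are integer days; ``delta_aic_cut`` is the strict
    retention bound on delta-AIC; ``age_cut`` splits the sensitivity strata.
    """

    outcome: str = "ACS_STROKE"
    grid_mode: str = "resolution"  # "resolution" | "observed"
    grid_resolution: float = 0.01
    trim_fraction: float = 0.05
    pdc_mode: str = "union"  # "union" | "carryover"
    max_followup_days: int = 1825
    min_followup_days: int = 180
    lookback_days: int = 365
    delta_aic_cut: float = 4.0
    age_cut: float = 65.0
    stratify_by_age: bool = True
    seed: int = 0
    covariates: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    #: extra thresholds always added to the comparison table
    alternate_offsets: tuple[float, ...] = (-0.10, -0.05, -0.01, 0.01, 0.05, 0.10)
    conventional_threshold: float = 0.80
    include_hospitalized_covariate: bool = True

    def __post_init__(self) -> None:
        for name in ("max_followup_days", "min_followup_days", "lookback_days"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not (0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must lie in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "covariates" in raw:
            raw["covariates"] = {k: tuple(v) for k, v in raw["covariates"].items()}
        if "alternate_offsets" in raw:
            raw["alternate_offsets"] = tuple(raw["alternate_offsets"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["covariates"] = {k: list(v) for k, v in raw["covariates"].items()}
        raw["alternate_offsets"] = list(raw["alternate_offsets"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# table reading


@dataclass(frozen=True)
class RowError:
    row_index: int  # 0-based data-row index (header excluded)
    message: str


@dataclass
class TableReadResult:
    """Validated records plus an audit trail of rejected rows.

    accepted + rejected always partitions the input rows; nothing is
    silently dropped.
    """

    records: list[Any]
    rejected: list[RowError]

    def __iter__(self) -> Iterator[Any]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def raise_on_rejects(self) -> "TableReadResult":
        if self.rejected:
            first = self.rejected[0]
            raise ValueError(
                f"{len(self.rejected)} rejected row(s); first: "
                f"row {first.row_index}: {first.message}"
            )
        return self


_SCHEMAS: dict[str, tuple[str, ...]] = {
    "dispensations": ("patient_id", "dispense_day", "days_supply", "drug_class"),
    "hospital_stays": ("patient_id", "admit_day", "discharge_day"),
    "outcomes": ("patient_id", "event_type", "event_day", "cv_cause", "icd_code"),
    "patients": (
        "patient_id",
        "age_years",
        "sex",
        *COMORBIDITIES,
        "enrol_start_day",
        "enrol_end_day",
    ),
}

_BOOL_TRUE = {"1", "true", "True", "TRUE"}
_BOOL_FALSE = {"0", "false", "False", "FALSE", ""}


def _parse_bool(text: str) -> bool:
    if text in _BOOL_TRUE:
        return True
    if text in _BOOL_FALSE:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _parse_int(text: str) -> int:
    return int(str(text).strip())


def _row_to_record(kind: str, row: dict[str, str]) -> Any:
    if kind == "dispensations":
        return DispensationRecord(
            patient_id=row["patient_id"],
            dispense_day=_parse_int(row["dispense_day"]),
            days_supply=_parse_int(row["days_supply"]),
            drug_class=row["drug_class"],
        )
    if kind == "hospital_stays":
        return HospitalStay(
            patient_id=row["patient_id"],
            admit_day=_parse_int(row["admit_day"]),
            discharge_day=_parse_int(row["discharge_day"]),
        )
    if kind == "outcomes":
        icd = row["icd_code"]
        return OutcomeEvent(
            patient_id=row["patient_id"],
            event_type=EventType(row["event_type"]),
            event_day=_parse_int(row["event_day"]),
            cv_cause=_parse_bool(row["cv_cause"]),
            icd_code=icd if icd != "" else None,
        )
    if kind == "patients":
        return PatientBaseline(
            patient_id=row["patient_id"],
            age_years=float(row["age_years"]),
            sex=Sex(row["sex"]),
            **{c: _parse_bool(row[c]) for c in COMORBIDITIES},
            enrol_start_day=_parse_int(row["enrol_start_day"]),
            enrol_end_day=_parse_int(row["enrol_end_day"]),
        )
    raise ValueError(f"unknown table kind: {kind!r}")


def read_table(path: str | Path, schema: str) -> TableReadResult:
    """Read one claims table, validating every row.

    Parameters
    ----------
    path
        CSV file with the exact documented header for ``schema``.
    schema
        One of ``dispensations``, ``hospital_stays``, ``outcomes``,
        ``patients``.

    Returns
    -------
    TableReadResult
        ``records`` holds validated typed rows; ``rejected`` holds
        ``(row_index, message)`` for rows violating a constraint. A header
        mismatch raises :class:`SchemaError` instead.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown table kind: {schema!r}")
    expected = _SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    got = tuple(df.columns)
    if got != expected:
        raise SchemaError(
            f"{schema} table at {path}: expected columns {expected}, got {got}"
        )
    records: list[Any] = []
    rejected: list[RowError] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            records.append(_row_to_record(schema, row))
        except (ValueError, KeyError) as exc:
            rejected.append(RowError(row_index=i, message=str(exc)))
    return TableReadResult(records=records, rejected=rejected)


def write_table(records: list[Any], path: str | Path, schema: str) -> None:
    """Write typed records back to the documented CSV shape (round-trips)."""
    cols = _SCHEMAS[schema]
    rows = []
    for r in records:
        d = asdict(r)
        for k, v in d.items():
            if isinstance(v, enum.Enum):
                d[k] = v.value
            elif isinstance(v, bool):
                d[k] = int(v)
            elif v is None:
                d[k] = ""
        rows.append(d)
    df = pd.DataFrame(rows, columns=list(cols))
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# report serialization

COMPARISON_COLUMNS = (
    "threshold",
    "hr",
    "ci_low",
    "ci_high",
    "aic",
    "delta_aic",
    "support",
)


def _comparison_tables(report: dict, prefix: str = "") -> Iterator[tuple[str, list[dict]]]:
    """Yield (name, rows) for every threshold-comparison table in a report."""
    for key, value in report.items():
        name = f"{prefix}{key}"
        if key == "comparison_table":
            yield prefix.rstrip("."), value
        elif isinstance(value, dict):
            yield from _comparison_tables(value, prefix=f"{name}.")


def write_report(report: dict, path: str | Path) -> None:
    """Serialize an analysis report to a directory.

    Writes ``report.json`` (the complete machine-readable report) plus one
    CSV per threshold-comparison table, mirroring the published table shape
    (threshold, hr, ci_low, ci_high, aic, delta_aic, support).
    """
    for name, rows in _comparison_tables(report):
        if not rows:
            raise ReportError(f"comparison table {name!r} is empty: nothing to report")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name, rows in _comparison_tables(report):
        df = pd.DataFrame(rows)
        keep = [c for c in COMPARISON_COLUMNS if c in df.columns]
        extra = [c for c in df.columns if c not in COMPARISON_COLUMNS]
        fname = (name.replace(".", "_") or "comparison") + ".csv"
        df[keep + extra].to_csv(out / fname, index=False, encoding="utf-8")


def read_report(path: str | Path) -> dict:
    """Read back a report written by :func:`write_report`."""
    with open(Path(path) / "report.json", "r", encoding="utf-8") as fh:
        return json.load(fh)
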