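"""Optimal-cutpoint estimation for a continuous covariate and a survival outcome.

Three estimators of the adherence threshold separating high- from low-risk
patients, all scanning a common candidate grid with the grouping rule
``poor adherence  <=>  PDC < c``:

* **maximally selected log-rank** (Contal–O'Quigley): at each candidate c the
  two-group log-rank numerator U(c) is computed over the ordered event
  times; the threshold maximizes |U(c)|, and the scan-level statistic
  q = max|U| / (s·sqrt(D−1)) carries a Brownian-bridge p-value
  approximation p ≈ 2·exp(−2q²), conventionally reported when q > 1;
* **Youden J**: maximizes Sn + Sp − 1 on the ROC of the classifier
  "PDC < c predicts event";
* **minimum distance**: minimizes the Euclidean distance from the ROC point
  to perfect classification (Sn, Sp) = (1, 1).

The ROC methods use the plain binary event indicator over each subject's
follow-up; censoring-time differences are ignored (time-dependent ROC is out
of scope).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


class Method(str, enum.Enum):
    CONTAL_OQUIGLEY = "CONTAL_OQUIGLEY"
    YOUDEN = "YOUDEN"
    MIN_DISTANCE = "MIN_DISTANCE"


@dataclass(frozen=True)
class CandidateGrid:
    """Ordered admissible thresholds; grouping rule is PDC < c."""

    candidates: tuple[float, ...]
    mode: str
    trim_fraction: float


@dataclass(frozen=True)
class RocPoint:
    c: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class CutpointResult:
    method: Method
    threshold: float
    statistic: float


@dataclass(frozen=True)
class CutpointScan:
    """Candidate-level trace of the maximally selected log-rank scan.

    ``u`` and ``v`` are the log-rank numerator and its hypergeometric
    variance per candidate; ``z = u/sqrt(v)`` is the ordinary two-group
    log-rank standardization, reported alongside the scan-level ``q``
    because published tables may print either scale.
    """

    candidates: tuple[float, ...]
    u: tuple[float, ...]
    v: tuple[float, ...]
    z: tuple[float, ...]
    n_event_times: int  # D: distinct event times
    s2: float  # scan variance constant
    q: float
    p_approx: float  # 2·exp(−2q²), capped at 1; approximation valid for q > 1
    threshold: float


def _extract(rows) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pdc, time, event) arrays from AnalysisRows or a DataFrame."""
    if hasattr(rows, "columns"):
        return (
            np.asarray(rows["pdc"], dtype=float),
            np.asarray(rows["time_days"], dtype=float),
            np.asarray(rows["event"], dtype=bool),
        )
    return (
        np.array([r.pdc for r in rows], dtype=float),
        np.array([r.time_days for r in rows], dtype=float),
        np.array([r.event for r in rows], dtype=bool),
    )


def make_candidate_grid(
    pdc_values: Sequence[float],
    mode: str = "resolution",
    resolution: float = 0.01,
    trim_fraction: float = 0.05,
) -> CandidateGrid:
    """Build the admissible candidate grid over observed PDC values.

    ``observed`` mode uses the distinct observed values; ``resolution`` mode
    uses multiples of ``resolution`` inside (0, 1) — the default 0.01 matches
    two-decimal reporting of thresholds. Candidates leaving fewer than
    ``trim_fraction`` of subjects on either side of the split are dropped.
    """
    x = np.asarray(pdc_values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct PDC values to form a candidate grid")
    if mode == "observed":
        cands = np.unique(x)
    elif mode == "resolution":
        k = int(math.ceil(1.0 / resolution)) - 1
        cands = np.round(np.arange(1, k + 1) * resolution, 10)
        cands = cands[(cands > 0.0) & (cands < 1.0)]
    else:
        raise ValueError(f"unknown grid mode: {mode!r}")
    n = x.size
    need = trim_fraction * n
    n_low = np.searchsorted(np.sort(x), cands, side="left")
    keep = (n_low >= need) & ((n - n_low) >= need)
    cands = cands[keep]
    if cands.size == 0:
        raise ValueError("no admissible cutpoints: every candidate trimmed")
    return CandidateGrid(tuple(float(c) for c in cands), mode, trim_fraction)


def contal_oquigley_scan(rows, grid: CandidateGrid) -> tuple[CutpointResult, CutpointScan]:
    """Maximally selected log-rank scan over the candidate grid.

    For each candidate c, U(c) sums over the ordered distinct event times
    the observed minus expected events in the low-adherence group
    (PDC < c), with expectation d_t·n_low(t)/n(t) under equal hazards. The
    threshold is argmax |U| (ties toward the smaller c). The scan-level
    variance constant is s² = (1/(D−1))·Σᵢ (1 − Σ_{j≤i} 1/(D−j+1))² over the
    D ordered distinct event times.
    """
    x, t, e = _extract(rows)
    if not e.any():
        raise ValueError("no events: cutpoint scan undefined")
    cands = np.asarray(grid.candidates, dtype=float)
    m = cands.size

    event_times = np.unique(t[e])
    big_d = event_times.size
    if big_d < 2:
        raise ValueError("single event time: variance constant undefined")

    # candidate-bin position of each subject: x_i < c_k  <=>  k >= pos_i
    pos = np.searchsorted(cands, x, side="right")

    u = np.zeros(m)
    v = np.zeros(m)
    # walk event times in decreasing order, growing the risk set
    order = np.argsort(-t, kind="stable")
    t_sorted = t[order]
    risk_bins = np.zeros(m + 1)
    ptr = 0
    n_at_risk = 0
    for ti in event_times[::-1]:
        while ptr < t_sorted.size and t_sorted[ptr] >= ti:
            risk_bins[pos[order[ptr]]] += 1
            n_at_risk += 1
            ptr += 1
        n_low = np.cumsum(risk_bins)[:m]  # at-risk subjects with x < c per candidate
        at_t = e & (t == ti)
        d_t = int(at_t.sum())
        d_low = np.cumsum(np.bincount(pos[at_t], minlength=m + 1))[:m]
        frac = n_low / n_at_risk
        u += d_low - d_t * frac
        if n_at_risk > 1:
            v += d_t * (n_at_risk - d_t) / (n_at_risk - 1) * frac * (1.0 - frac)

    # Contal–O'Quigley scan variance constant over D ordered event times
    inv = 1.0 / np.arange(big_d, 0, -1)  # 1/(D−j+1), j = 1..D
    a = 1.0 - np.cumsum(inv)
    s2 = float(np.sum(a * a) / (big_d - 1))

    best = int(np.argmax(np.abs(u)))  # first occurrence: ties toward smaller c
    q = float(abs(u[best]) / math.sqrt(s2 * (big_d - 1)))
    p_approx = min(1.0, 2.0 * math.exp(-2.0 * q * q))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(v > 0, u / np.sqrt(v), 0.0)
    scan = CutpointScan(
        candidates=tuple(cands),
        u=tuple(float(ui) for ui in u),
        v=tuple(float(vi) for vi in v),
        z=tuple(float(zi) for zi in z),
        n_event_times=big_d,
        s2=s2,
        q=q,
        p_approx=p_approx,
        threshold=float(cands[best]),
    )
    return CutpointResult(Method.CONTAL_OQUIGLEY, float(cands[best]), q), scan


def roc_points(rows, grid: CandidateGrid) -> list[RocPoint]:
    """ROC of "PDC < c predicts event" at every candidate threshold.

    Sn(c) is the fraction of event subjects with PDC < c; Sp(c) the
    fraction of non-event subjects with PDC >= c.
    """
    x, _, e = _extract(rows)
    if not e.any() or e.all():
        raise ValueError("ROC needs at least one event and one non-event subject")
    cands = np.asarray(grid.candidates, dtype=float)
    x_ev = np.sort(x[e])
    x_ne = np.sort(x[~e])
    sn = np.searchsorted(x_ev, cands, side="left") / x_ev.size
    sp = 1.0 - np.searchsorted(x_ne, cands, side="left") / x_ne.size
    return [
        RocPoint(float(c), float(s), float(p))
        for c, s, p in zip(cands, sn, sp)
    ]


def youden_threshold(roc: list[RocPoint]) -> CutpointResult:
    """Candidate maximizing J = Sn + Sp − 1 (ties toward the smaller c)."""
    if not roc:
        raise ValueError("empty ROC")
    j = np.array([p.sensitivity + p.specificity - 1.0 for p in roc])
    best = int(np.argmax(j))
    return CutpointResult(Method.YOUDEN, roc[best].c, float(j[best]))


def min_distance_threshold(roc: list[RocPoint]) -> CutpointResult:
    """Candidate minimizing d = sqrt((1−Sn)² + (1−Sp)²) (ties toward smaller c)."""
    if not roc:
        raise ValueError("empty ROC")
    d = np.array(
        [math.hypot(1.0 - p.sensitivity, 1.0 - p.specificity) for p in roc]
    )
    best = int(np.argmin(d))
    return CutpointResult(Method.MIN_DISTANCE, roc[best].c, float(d[best]))
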