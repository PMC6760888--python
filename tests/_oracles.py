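"""Independent brute-force oracles used by the test suite.

Each oracle deliberately materializes the naive definition (one boolean per
day, per-candidate risk-set enumeration, 1-D likelihood search) rather than
calling the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

from pdcthresh.claims_io import DispensationRecord, HospitalStay
from pdcthresh.pdc import ObservationWindow


def coverage_days_oracle(
    dispensations: list[DispensationRecord],
    window: ObservationWindow,
    mode: str,
) -> int:
    """Day-by-day boolean-array version of coverage counting."""
    if not dispensations:
        return 0
    fills = sorted((d.dispense_day, d.days_supply) for d in dispensations)
    lo = min(window.start_day, fills[0][0])
    hi = window.end_day
    total_supply = sum(s for _, s in fills)
    size = max(hi, fills[-1][0] + total_supply + 1) - lo
    covered = np.zeros(size, dtype=bool)
    if mode == "union":
        for day, supply in fills:
            covered[day - lo : day - lo + supply] = True
    elif mode == "carryover":
        supply_end = None
        for day, supply in fills:
            start = day if supply_end is None else max(day, supply_end)
            covered[start - lo : start - lo + supply] = True
            supply_end = start + supply
    else:
        raise ValueError(mode)
    w = covered[window.start_day - lo : window.end_day - lo]
    return int(w.sum())


def pdc_oracle(
    dispensations: list[DispensationRecord],
    window: ObservationWindow,
    stays: list[HospitalStay],
    mode: str,
) -> float:
    """Boolean-array PDC: covered-outside-hospital / (window − hospital days)."""
    if not dispensations:
        fills = []
        lo = window.start_day
    else:
        fills = sorted((d.dispense_day, d.days_supply) for d in dispensations)
        lo = min(window.start_day, fills[0][0])
    total_supply = sum(s for _, s in fills)
    size = max(window.end_day, (fills[-1][0] + total_supply + 1) if fills else 0) - lo
    covered = np.zeros(max(size, window.end_day - lo), dtype=bool)
    if mode == "union":
        for day, supply in fills:
            covered[day - lo : day - lo + supply] = True
    else:
        supply_end = None
        for day, supply in fills:
            start = day if supply_end is None else max(day, supply_end)
            covered[start - lo : start - lo + supply] = True
            supply_end = start + supply
    hosp = np.zeros_like(covered)
    for h in stays:
        a = max(h.admit_day, lo)
        b = min(h.discharge_day, lo + covered.size)
        if b > a:
            hosp[a - lo : b - lo] = True
    wsl = slice(window.start_day - lo, window.end_day - lo)
    num = int((covered[wsl] & ~hosp[wsl]).sum())
    den = (window.end_day - window.start_day) - int(hosp[wsl].sum())
    if den <= 0:
        raise ZeroDivisionError("window entirely in hospital")
    return num / den


def logrank_numerator_oracle(
    pdc: np.ndarray, time: np.ndarray, event: np.ndarray, c: float
) -> tuple[float, float]:
    """(U, V) for grouping PDC < c by direct risk-set enumeration."""
    u = 0.0
    v = 0.0
    for ti in np.unique(time[event]):
        at_risk = time >= ti
        n = int(at_risk.sum())
        n_low = int((at_risk & (pdc < c)).sum())
        dead = event & (time == ti)
        d = int(dead.sum())
        d_low = int((dead & (pdc < c)).sum())
        u += d_low - d * n_low / n
        if n > 1:
            frac = n_low / n
            v += d * (n - d) / (n - 1) * frac * (1 - frac)
    return u, v


def contal_threshold_oracle(
    pdc: np.ndarray, time: np.ndarray, event: np.ndarray, candidates
) -> float:
    """argmax_c |U(c)| by exhaustive enumeration (ties toward smaller c)."""
    best_c, best_u = None, -1.0
    for c in candidates:
        u, _ = logrank_numerator_oracle(pdc, time, event, c)
        if abs(u) > best_u + 1e-12:
            best_c, best_u = c, abs(u)
    return best_c


def roc_oracle(pdc: np.ndarray, event: np.ndarray, c: float) -> tuple[float, float]:
    """(Sn, Sp) for the classifier "PDC < c predicts event" by counting."""
    sn = float((pdc[event] < c).mean())
    sp = float((pdc[~event] >= c).mean())
    return sn, sp


def youden_oracle(pdc, event, candidates) -> float:
    best_c, best_j = None, -math.inf
    for c in candidates:
        sn, sp = roc_oracle(pdc, event, c)
        if sn + sp - 1 > best_j + 1e-12:
            best_c, best_j = c, sn + sp - 1
    return best_c


def min_distance_oracle(pdc, event, candidates) -> float:
    best_c, best_d = None, math.inf
    for c in candidates:
        sn, sp = roc_oracle(pdc, event, c)
        d = math.hypot(1 - sn, 1 - sp)
        if d < best_d - 1e-12:
            best_c, best_d = c, d
    return best_c


def efron_partial_loglik(
    beta: float, z: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Efron-corrected Cox partial log-likelihood for one covariate."""
    ll = 0.0
    exp_bz = np.exp(beta * z)
    for ti in np.unique(time[event]):
        dead = event & (time == ti)
        at_risk = time >= ti
        d = int(dead.sum())
        risk_sum = float(exp_bz[at_risk].sum())
        tied_sum = float(exp_bz[dead].sum())
        ll += beta * float(z[dead].sum())
        for l in range(d):
            ll -= math.log(risk_sum - (l / d) * tied_sum)
    return ll


def cox_beta_grid_oracle(
    z: np.ndarray, time: np.ndarray, event: np.ndarray,
    lo: float = -5.0, hi: float = 5.0,
) -> float:
    """1-D maximizer of the Efron partial likelihood: coarse grid + refinement."""
    grid = np.linspace(lo, hi, 2001)
    ll = np.array([efron_partial_loglik(b, z, time, event) for b in grid])
    b0 = grid[int(np.argmax(ll))]
    fine = np.linspace(b0 - 0.01, b0 + 0.01, 401)
    llf = np.array([efron_partial_loglik(b, z, time, event) for b in fine])
    return float(fine[int(np.argmax(llf))])
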