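"""Adjudication of candidate adherence thresholds with adjusted Cox models.

Each candidate threshold c defines a binary exposure 1(PDC < c). The same
adjusted proportional-hazards model is fitted at every candidate on the same
rows; models are compared by AIC = −2·logPL + 2k (partial likelihood, k
estimated coefficients) re-baselined against the best model, and the
threshold range is defined by the strict retention rule delta-AIC < 4, with
the Burnham–Anderson support categories attached to every row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from pdcthresh.pdc import rows_to_frame

logger = logging.getLogger(__name__)

#: Burnham–Anderson support categories on delta-AIC, plus the band (2, 4)
#: that the strict retention rule keeps without "substantial" support.
SUPPORT_LABELS = (
    "substantial",          # <= 2
    "retained-borderline",  # (2, 4)
    "considerably-less",    # [4, 7]
    "little",               # (7, 10]
    "none",                 # > 10
)


class DegenerateCovariateError(ValueError):
    """The threshold dichotomizer is constant across rows."""


@dataclass(frozen=True)
class CoxFit:
    threshold: float
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    covariate_coefs: dict[str, float]
    log_likelihood: float
    k: int
    aic: float


@dataclass(frozen=True)
class ComparisonRow:
    threshold: float
    hr: float
    ci_low: float
    ci_high: float
    aic: float
    delta_aic: float
    support: str
    provenance: str = ""  # e.g. "contal_oquigley", "youden", "alternate"


@dataclass
class ThresholdComparisonTable:
    rows: list[ComparisonRow]
    reference_threshold: float
    duplicate_reference: bool = False
    fits: list[CoxFit] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {
                "threshold": r.threshold,
                "hr": r.hr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "aic": r.aic,
                "delta_aic": r.delta_aic,
                "support": r.support,
                "provenance": r.provenance,
            }
            for r in self.rows
        ]


def _as_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows.copy()
    return rows_to_frame(rows)


def fit_cox_at_threshold(
    rows,
    c: float,
    covariates: tuple[str, ...] = (),
    ties_method: str = "efron",
) -> CoxFit:
    """Adjusted Cox model with PDC dichotomized at c (exposure 1(PDC < c)).

    Maximizes the Cox partial likelihood (Efron tie correction by default,
    Breslow as option), with Wald 95% CI on the log-hazard scale. Covariates
    that are constant in these rows are dropped with a warning rather than
    passed to a singular fit — this happens routinely in small strata.
    """
    df = _as_frame(rows)
    if not df["event"].astype(bool).any():
        raise ValueError("no events: Cox model undefined")
    df["poor_adherence"] = (df["pdc"] < c).astype(int)
    if df["poor_adherence"].nunique() < 2:
        raise DegenerateCovariateError(
            f"1(PDC < {c}) is constant across rows: threshold not estimable"
        )
    used = ["poor_adherence"]
    for cov in covariates:
        if df[cov].nunique() < 2:
            logger.warning("covariate %s constant in these rows; dropped", cov)
        else:
            used.append(cov)
    model_df = df[["time_days", "event", *used]]

    if ties_method == "efron":
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(model_df, duration_col="time_days", event_col="event")
        coefs = cph.params_
        ses = cph.standard_errors_
        log_pl = float(cph.log_likelihood_)
    elif ties_method == "breslow":
        import statsmodels.api as sm

        model = sm.PHReg(
            model_df["time_days"],
            model_df[used],
            status=model_df["event"],
            ties="breslow",
        )
        res = model.fit(disp=False)
        coefs = pd.Series(res.params, index=used)
        ses = pd.Series(res.bse, index=used)
        log_pl = float(res.llf)
    else:
        raise ValueError(f"unknown ties_method: {ties_method!r}")

    beta = float(coefs["poor_adherence"])
    se = float(ses["poor_adherence"])
    k = len(used)
    aic = -2.0 * log_pl + 2.0 * k
    with np.errstate(over="ignore"):  # near-degenerate strata can have huge SEs
        hr, ci_low, ci_high = np.exp(
            [beta, beta - 1.96 * se, beta + 1.96 * se]
        )
    return CoxFit(
        threshold=float(c),
        coef=beta,
        se=se,
        hr=float(hr),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        covariate_coefs={name: float(coefs[name]) for name in used},
        log_likelihood=log_pl,
        k=k,
        aic=aic,
    )


def rebaseline_aic(aic_values) -> list[float]:
    """delta-AIC: each AIC minus the minimum of the set."""
    aics = [float(a) for a in aic_values]
    if not aics:
        raise ValueError("empty AIC list")
    best = min(aics)
    return [a - best for a in aics]


def categorize_support(delta_aic: float) -> str:
    """Burnham–Anderson support category for one delta-AIC value."""
    if delta_aic < 0:
        raise ValueError("delta_aic must be >= 0")
    if delta_aic <= 2:
        return "substantial"
    if delta_aic < 4:
        return "retained-borderline"
    if delta_aic <= 7:
        return "considerably-less"
    if delta_aic <= 10:
        return "little"
    return "none"


def compare_thresholds(
    rows,
    thresholds,
    covariates: tuple[str, ...] = (),
    ties_method: str = "efron",
    provenance: dict[float, str] | None = None,
) -> ThresholdComparisonTable:
    """Fit one adjusted Cox model per threshold and re-baseline by AIC.

    All models share the same rows and covariate set, so their partial
    likelihoods are comparable. The reference row is the minimum-AIC model
    (delta-AIC = 0); duplicated thresholds yield duplicated reference rows
    and are flagged.
    """
    thresholds = list(thresholds)
    if len(thresholds) < 2:
        raise ValueError("need >= 2 thresholds to compare")
    provenance = provenance or {}
    fits: list[CoxFit] = []
    for c in sorted(thresholds):
        try:
            fits.append(fit_cox_at_threshold(rows, c, covariates, ties_method))
        except Exception as exc:
            raise RuntimeError(f"Cox fit failed at threshold {c}: {exc}") from exc
    deltas = rebaseline_aic([f.aic for f in fits])
    n_ref = sum(1 for d in deltas if d == 0.0)
    if n_ref > 1:
        logger.warning("%d reference rows (tied minimum AIC)", n_ref)
    table_rows = [
        ComparisonRow(
            threshold=f.threshold,
            hr=f.hr,
            ci_low=f.ci_low,
            ci_high=f.ci_high,
            aic=f.aic,
            delta_aic=d,
            support=categorize_support(d),
            provenance=provenance.get(f.threshold, ""),
        )
        for f, d in zip(fits, deltas)
    ]
    ref = min(fits, key=lambda f: f.aic).threshold
    return ThresholdComparisonTable(
        rows=table_rows,
        reference_threshold=ref,
        duplicate_reference=n_ref > 1,
        fits=fits,
    )


def retain_threshold_range(
    table: ThresholdComparisonTable, cut: float = 4.0
) -> tuple[list[float], tuple[float, float]]:
    """Thresholds retained by the strict delta-AIC < cut rule, plus their range.

    The reference threshold is always retained (its delta-AIC is 0); the
    range is the (min, max) of the retained set.
    """
    if not table.rows:
        raise ValueError("empty comparison table")
    retained = sorted(
        {r.threshold for r in table.rows if r.delta_aic < cut}
        | {table.reference_threshold}
    )
    return retained, (retained[0], retained[-1])
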