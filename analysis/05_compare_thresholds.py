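"""Adjudicate candidate thresholds with adjusted Cox models and delta-AIC.

For each outcome, fits the adjusted proportional-hazards model with
adherence dichotomized at the method cutpoints, at bracketing alternates
and at the conventional 0.80, re-baselines the AICs against the best model
and applies the strict delta-AIC < 4 retention rule.
"""

from pathlib import Path

import pandas as pd

from pdcthresh.claims_io import RunConfig
from pdcthresh.cutpoints import (
    contal_oquigley_scan,
    make_candidate_grid,
    min_distance_threshold,
    roc_points,
    youden_threshold,
)
from pdcthresh.model_comparison import compare_thresholds, retain_threshold_range
from pdcthresh.pdc import OUTCOME_KINDS
from pdcthresh.pipeline import _alternate_thresholds

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = RunConfig()
    RESULTS.mkdir(exist_ok=True)
    for kind in OUTCOME_KINDS:
        df = pd.read_csv(DATA / f"analysis_rows_{kind}.csv")
        grid = make_candidate_grid(df.pdc, "resolution", 0.01, 0.05)
        contal, _ = contal_oquigley_scan(df, grid)
        roc = roc_points(df, grid)
        methods = {
            "contal_oquigley": contal.threshold,
            "youden": youden_threshold(roc).threshold,
            "min_distance": min_distance_threshold(roc).threshold,
        }
        provenance = _alternate_thresholds(methods, cfg, set(grid.candidates))
        table = compare_thresholds(
            df, list(provenance), cfg.covariates[kind], provenance=provenance
        )
        retained, rng = retain_threshold_range(table, cfg.delta_aic_cut)
        out = pd.DataFrame(table.to_records()).round(4)
        out.to_csv(RESULTS / f"05_comparison_{kind}.csv", index=False)
        print(f"\n{kind}: retained thresholds {retained}, range {rng}")
        print(out.to_string(index=False))


if __name__ == "__main__":
    main()
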