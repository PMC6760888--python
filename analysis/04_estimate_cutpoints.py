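"""Estimate the optimal adherence threshold per outcome by three methods.

Maximally selected log-rank (Contal-O'Quigley), Youden J and ROC minimum
distance, all over a 0.01-resolution candidate grid with 5% trimming.
"""

from pathlib import Path

import pandas as pd

from pdcthresh.cutpoints import (
    contal_oquigley_scan,
    make_candidate_grid,
    min_distance_threshold,
    roc_points,
    youden_threshold,
)
from pdcthresh.pdc import OUTCOME_KINDS

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    records = []
    for kind in OUTCOME_KINDS:
        df = pd.read_csv(DATA / f"analysis_rows_{kind}.csv")
        grid = make_candidate_grid(df.pdc, "resolution", 0.01, 0.05)
        contal, scan = contal_oquigley_scan(df, grid)
        roc = roc_points(df, grid)
        for res, extra in (
            (contal, {"p_approx": scan.p_approx}),
            (youden_threshold(roc), {}),
            (min_distance_threshold(roc), {}),
        ):
            records.append(
                {
                    "outcome": kind,
                    "method": res.method.value,
                    "threshold": res.threshold,
                    "statistic": round(res.statistic, 4),
                    **extra,
                }
            )
    out = pd.DataFrame(records)
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "04_cutpoints.csv", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
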