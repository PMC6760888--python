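"""Compute outcome-specific PDC and summarize the adherence distribution.

One analysis table per outcome: the PDC window ends at the event for event
cases, at the patient-specific end for losses, and at the fixed 1825-day
cap for completers; hospital days are removed from numerator and
denominator. Analysis rows go to scratch/ for the next scripts; the
distribution summary goes to results/.
"""

from pathlib import Path

import pandas as pd

from pdcthresh.claims_io import RunConfig
from pdcthresh.cohort import build_cohort
from pdcthresh.pdc import OUTCOME_KINDS, build_analysis_table, rows_to_frame
from pdcthresh.pipeline import InputTables

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    tables = InputTables.from_dir(DATA)
    cfg = RunConfig()
    cohort = build_cohort(tables.dispensations, tables.patients, tables.outcomes)
    summaries = []
    for kind in OUTCOME_KINDS:
        rows = build_analysis_table(
            cohort, tables.dispensations, tables.hospital_stays,
            tables.outcomes, tables.patients, kind, cfg,
        )
        df = rows_to_frame(rows)
        df.to_csv(DATA / f"analysis_rows_{kind}.csv", index=False)
        summaries.append(
            {
                "outcome": kind,
                "n": len(df),
                "n_events": int(df.event.sum()),
                "pdc_median": df.pdc.median(),
                "pdc_q25": df.pdc.quantile(0.25),
                "pdc_q75": df.pdc.quantile(0.75),
            }
        )
    out = pd.DataFrame(summaries).round(3)
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "03_pdc_summary.csv", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
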