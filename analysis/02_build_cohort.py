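"""Apply the new-user inclusion/exclusion rules and report the funnel.

Reads the claims tables from scratch/data/ (run 01_simulate.py first),
identifies index dates (365-day observable clean period), excludes
prior-event and short-follow-up patients, and writes the selection funnel.
"""

from pathlib import Path

import pandas as pd

from pdcthresh.cohort import build_cohort, cohort_summary
from pdcthresh.pipeline import InputTables

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    tables = InputTables.from_dir(DATA)
    entries = build_cohort(tables.dispensations, tables.patients, tables.outcomes)
    funnel = cohort_summary(entries)
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame([funnel]).to_csv(RESULTS / "02_cohort_funnel.csv", index=False)
    print("selection funnel:")
    for k, v in funnel.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
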