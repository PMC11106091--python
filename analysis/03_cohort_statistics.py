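#!/usr/bin/env python
"""Cohort statistics: case/control table and non-perfusion-extent correlations.

Reads results/cohort/eyes.csv and results/features.csv (written by 01/02),
runs Welch t-tests per variable and Pearson correlations of FD/LAC against
the NPA quadrant count, and writes results/cohort_summary.csv plus
results/correlations.json.
"""

import json
from pathlib import Path

import pandas as pd

from octafractal.cohort_analysis import run_cohort_analysis, summary_to_json
from octafractal.slab_io import read_eye_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    records = read_eye_table(ROOT / "results" / "cohort" / "eyes.csv")
    features = pd.read_csv(ROOT / "results" / "features.csv")
    summary = run_cohort_analysis(records, features)

    summary.table.to_csv(ROOT / "results" / "cohort_summary.csv", index=False)
    payload = summary_to_json(summary)
    (ROOT / "results" / "correlations.json").write_text(
        json.dumps(payload["correlations"], indent=2) + "\n", encoding="utf-8"
    )

    print(f"groups: {summary.n_npa} NPA vs {summary.n_wp} well-perfused eyes")
    for _, row in summary.table.iterrows():
        flag = "*" if row.significant else " "
        print(
            f"  {row.variable:22s} NPA {row.npa_mean:8.2f}±{row.npa_sd:6.2f}  "
            f"WP {row.wp_mean:8.2f}±{row.wp_sd:6.2f}  p={row.p_value:.2g} {flag}"
        )
    print("correlations with NPA quadrant count (0-4):")
    for c in summary.correlations:
        print(f"  {c.x:8s} r={c.r:+.2f}  p={c.p_value:.2g}  (n={c.n})")


if __name__ == "__main__":
    main()
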