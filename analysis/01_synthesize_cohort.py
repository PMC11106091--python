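#!/usr/bin/env python
"""Generate the default synthetic DME cohort on disk.

Writes 50 eyes (30 with peripheral non-perfusion in 1-4 quadrants, 20
well-perfused) as SCP/DCP en-face slab PNGs plus eyes.csv under
results/cohort/.  Everything downstream (02, 03) starts from this folder.
"""

from pathlib import Path

import pandas as pd

from octafractal.synthetic_data import CohortSpec, write_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 0


def main() -> None:
    spec = CohortSpec(seed=SEED)
    write_cohort(OUT, spec)
    eyes = pd.read_csv(OUT / "eyes.csv")
    n_npa = (eyes.npa_quadrants >= 1).sum()
    print(f"cohort written to {OUT}")
    print(f"  {len(eyes)} eyes: {n_npa} NPA / {len(eyes) - n_npa} well-perfused")
    counts = eyes[eyes.npa_quadrants >= 1].npa_quadrants.value_counts().sort_index()
    print("  NPA quadrant counts:", {int(k): int(v) for k, v in counts.items()})
    print(f"  image size {spec.image_size_px} px, seed {SEED}")


if __name__ == "__main__":
    main()
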