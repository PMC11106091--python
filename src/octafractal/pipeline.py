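"""In-memory end-to-end helpers tying the generator to the fractal pipeline.

These are the same stages the CLI drives from disk, exposed as functions for
scripted analyses: generate (or accept) a cohort, push every slab through
binarize -> skeletonize -> FD/LAC, and hand back tidy tables.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .cohort_analysis import CohortSummary, run_cohort_analysis
from .fractal import AnalysisConfig, analyze_slab
from .slab_io import EyeRecord, OCTASlab, Plexus
from .synthetic_data import CohortSpec, GroupCalibration, generate_cohort


def feature_table(
    records: Sequence[EyeRecord],
    slabs: Mapping[tuple[str, Plexus], OCTASlab],
    config: AnalysisConfig = AnalysisConfig(),
    plexuses: Sequence[Plexus] = (Plexus.SCP, Plexus.DCP),
) -> pd.DataFrame:
    """Per-slab FD/LAC rows for every eye, SCP before DCP within an eye."""
    rows = []
    for rec in records:
        for plexus in plexuses:
            res = analyze_slab(slabs[(rec.eye_id, plexus)], config)
            rows.append(
                {
                    "eye_id": rec.eye_id,
                    "plexus": plexus.value,
                    "npa_quadrants": rec.npa_quadrants,
                    "fd": res.fd,
                    "lac": res.lac,
                    "fit_r2": res.fit_r2,
                    "n_box_sizes": len(res.curve.box_sizes_px),
                }
            )
    return pd.DataFrame(rows)


def measure_synthetic_cohort(
    seed: int,
    spec: CohortSpec | None = None,
    calib: GroupCalibration = GroupCalibration(),
    config: AnalysisConfig = AnalysisConfig(),
    plexuses: Sequence[Plexus] = (Plexus.SCP, Plexus.DCP),
) -> tuple[list[EyeRecord], pd.DataFrame]:
    """Generate one synthetic cohort and measure FD/LAC on every slab."""
    if spec is None:
        spec = CohortSpec(seed=seed)
    elif spec.seed != seed:
        spec = CohortSpec(**{**spec.__dict__, "seed": seed})
    records, slabs = generate_cohort(spec, calib)
    return records, feature_table(records, slabs, config, plexuses)


def analyze_cohort_features(
    records: Sequence[EyeRecord], features: pd.DataFrame, **kwargs
) -> CohortSummary:
    """Convenience wrapper around :func:`run_cohort_analysis`."""
    return run_cohort_analysis(records, features, **kwargs)
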