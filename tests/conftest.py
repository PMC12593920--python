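"""Shared fixtures: the desk-profile end-to-end run and tabular cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aplscreen import pipeline, synthgram
from aplscreen.quant import FEATURE_NAMES


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """One seeded desk-profile pipeline run shared across the suite."""
    out = tmp_path_factory.mktemp("desk_e2e")
    return pipeline.run_pipeline({"out_dir": str(out), "seed": 1})


def make_tabular_cohort(n_per_class: dict[str, int], seed: int
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Routine table from the generator (tiny event clouds) plus a synthetic
    scattergram-parameter table carrying a planted APL signal, for screening
    tests that do not need the imaging stages."""
    cohort = synthgram.generate_cohort(n_per_class, seed=seed, n_events=10)
    routine = synthgram.cohort_to_frame(cohort)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for s in cohort:
        row = {"sample_id": s.sample_id}
        is_apl = s.class_name == "APL"
        for name in FEATURE_NAMES:
            if "APL-Ratio" in name:
                base = rng.uniform(0.05, 0.30) if is_apl else abs(rng.normal(0, 0.01))
                row[name] = min(base, 1.0)
            elif "Dist" in name:
                shift = 25.0 if is_apl and name.startswith("N-Cluster") else 0.0
                row[name] = abs(rng.normal(60.0 + shift, 15.0))
            else:  # areas
                row[name] = abs(rng.normal(900.0, 200.0))
        rows.append(row)
    scatter = pd.DataFrame(rows)
    return scatter, routine


@pytest.fixture(scope="session")
def tabular_cohort():
    return make_tabular_cohort({"APL": 30, "AML": 25, "ALL": 15, "HC": 30},
                               seed=7)
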