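import numpy as np
import pandas as pd
import pytest

from pulsechase import AbundanceMatrix, SimConfig, make_sample_sheet, simulate_plex

CHASE_TIMES = np.array([0.0, 2.333, 6.333, 13.333])


def toy_matrix(values: dict, groups: dict, timepoints: dict | None = None,
               log2_scale: bool = False) -> AbundanceMatrix:
    """Small hand-built matrix: values maps protein -> {sample: value}."""
    data = pd.DataFrame(values).T
    rows = []
    for s in data.columns:
        rows.append(
            {
                "sample": s,
                "group": groups[s],
                "replicate": 1,
                "timepoint_days": (timepoints or {}).get(s, np.nan),
                "age": "n/a",
                "region": "n/a",
            }
        )
    return AbundanceMatrix(data, make_sample_sheet(rows), log2_scale=log2_scale)


@pytest.fixture(scope="session")
def noisy_plex():
    """Mid-size simulated plex shared by slow-ish tests."""
    cfg = SimConfig(n_proteins=200, noise_cv=0.1, seed=42)
    return simulate_plex(cfg)


@pytest.fixture
def chase_times():
    return CHASE_TIMES.copy()
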