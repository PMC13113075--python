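import numpy as np
import pandas as pd
import pytest

from vocpartition import FeatureTable, default_config, generate_dataset
from vocpartition.datasets import synthetic_study_table


def make_rows(n_animals=2, n_recordings=1, n_samples=3, *, phase="farrowing",
              condition="normal", base=70.0):
    """Tiny valid table builder for unit tests."""
    rows = []
    for a in range(1, n_animals + 1):
        sex = "female" if a % 2 else "male"
        for r in range(1, n_recordings + 1):
            for s in range(1, n_samples + 1):
                rows.append({
                    "animal_id": f"{a:02d}", "sex": sex, "phase": phase,
                    "condition": condition,
                    "recording_id": f"{a:02d}-r{r}", "sample_index": s,
                    "energy": 0.01, "duration": 0.5, "amp_max": 0.5,
                    "amp_min": -0.5, "intensity": base + a, "pitch": 200.0,
                    "f1": 700.0, "f2": 1900.0, "f3": 2900.0, "f4": 3900.0,
                })
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_table():
    return FeatureTable(make_rows())


@pytest.fixture(scope="session")
def study_table():
    """Synthetic stand-in matching the study's recorded count structure
    and per-condition trait moments exactly."""
    return synthetic_study_table(seed=0)


@pytest.fixture(scope="session")
def default_table():
    """One study-like synthetic dataset at the default design size."""
    return generate_dataset(default_config(seed=123))
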