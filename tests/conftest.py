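import numpy as np
import pandas as pd
import pytest

from netqap import NodeTable, SimulationConfig, simulate_study


@pytest.fixture
def toy_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node_id": ["A", "B", "C"],
            "class_label": ["C1", "C1", "C2"],
            "gender": ["M", "F", "M"],
            "ethnicity": ["Italian", "Italian", "Other"],
            "pupil_relevance": [7, 3, 5],
            "parent_relevance": [6, 6, 2],
            "parent_age": [40.0, 43.0, 40.0],
            "medical_visits": [4, 2, 4],
            "positive_response": [1, 1, 0],
        }
    )


@pytest.fixture
def toy_table(toy_frame) -> NodeTable:
    return NodeTable(toy_frame)


@pytest.fixture(scope="session")
def study49():
    """One full synthetic cohort at the default study conditions."""
    cohort, networks = simulate_study(SimulationConfig(seed=11))
    return cohort, networks


def random_hollow(rng: np.random.Generator, n: int, binary: bool = False) -> np.ndarray:
    m = (rng.random((n, n)) < 0.4).astype(float) if binary else rng.normal(size=(n, n))
    np.fill_diagonal(m, 0.0)
    return m
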