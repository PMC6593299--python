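import numpy as np
import pandas as pd
import pytest

from circmir.containers import CountMatrix
from circmir.simulate import SimulationParams, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_counts():
    """3 miRNAs x 4 samples, hand-checkable values."""
    df = pd.DataFrame(
        {
            "s1": [10, 100, 40],
            "s2": [20, 200, 80],
            "s3": [10, 100, 40],
            "s4": [5, 50, 20],
        },
        index=["miR-a", "miR-b", "miR-c"],
    )
    return CountMatrix(df)


@pytest.fixture(scope="session")
def small_dataset():
    """Session-scoped simulated study: 10 vs 11 samples, 120 miRNAs."""
    params = SimulationParams(n_features=120, frac_de=0.05)
    return simulate_dataset(params, seed=42)
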