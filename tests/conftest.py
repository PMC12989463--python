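import numpy as np
import pandas as pd
import pytest

from periphyton import rarefy_matrix, simulate


@pytest.fixture
def tiny_counts():
    """3 taxa x 2 samples with known column sums 15 and 25."""
    return pd.DataFrame(
        [[10, 0], [5, 5], [0, 20]],
        index=["Enceverg", "Mascalca", "Nitamphi"],
        columns=["s1", "s2"],
    )


@pytest.fixture
def tiny_samples():
    return pd.DataFrame(
        {
            "mat_p": [100.0, 800.0, 250.0],
            "region": ["R1", "R2", "R1"],
            "latitude": [26.0, 26.2, 26.1],
            "longitude": [-81.3, -81.5, -81.4],
            "year": [2019, 2019, 2020],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample"),
    )


@pytest.fixture(scope="session")
def marsh():
    """One standardized marsh-gradient assemblage shared across tests."""
    counts, samples, truth = simulate(seed=11)
    std = rarefy_matrix(counts, 600, seed=12)
    return std, samples, truth


@pytest.fixture
def step_taxon():
    """Deterministic decreaser on a 100..800 gradient (abundant iff x < 400)."""
    x = np.linspace(100, 800, 36)
    y = np.where(x < 400, 50.0, 0.0)
    return y, x
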