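import numpy as np
import pandas as pd
import pytest

from cscore import ContrastTable, DualContrast


@pytest.fixture
def small_table():
    return ContrastTable(
        "STB",
        "c1",
        pd.DataFrame(
            {
                "feature": ["g1", "g2", "g3"],
                "effect": [1.0, -2.0, 0.5],
                "fdr": [0.01, 0.2, 1.0],
            }
        ),
    )


@pytest.fixture
def small_dual():
    return DualContrast(
        cell_type="STB",
        features=np.array(["g1", "g2", "g3"]),
        e1=np.array([1.0, -2.0, 0.5]),
        fdr1=np.array([0.01, 0.2, 1.0]),
        e2=np.array([0.8, 1.5, -0.5]),
        fdr2=np.array([0.02, 0.01, 0.5]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
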