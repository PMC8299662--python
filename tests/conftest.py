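import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cernet import simulate
from cernet.data_io import ExpressionMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle() -> simulate.SyntheticBundle:
    """One default synthetic study shared across the suite."""
    return simulate.generate_all(simulate.SyntheticConfig(seed=7))


@pytest.fixture()
def small_matrix() -> ExpressionMatrix:
    """3 features x 6 samples (3 tumor / 3 normal), hand-enterable values."""
    data = pd.DataFrame(
        {
            "T1": [5.0, 1.0, 2.0],
            "T2": [6.0, 1.5, 2.0],
            "T3": [7.0, 0.5, 2.0],
            "N1": [1.0, 1.0, 2.0],
            "N2": [2.0, 1.5, 2.0],
            "N3": [3.0, 0.5, 2.0],
        },
        index=["f_shift", "f_same", "f_const"],
    )
    groups = pd.Series(
        ["tumor", "tumor", "tumor", "normal", "normal", "normal"], index=data.columns
    )
    return ExpressionMatrix(data=data, feature_kind="mRNA", group_labels=groups)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
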