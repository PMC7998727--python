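import numpy as np
import pandas as pd
import pytest

from coexnet.datatypes import ExpressionMatrix
from coexnet.simulate import SimConfig


@pytest.fixture
def small_matrix():
    """5 transcripts x 6 tissues with one all-zero and one constant row."""
    df = pd.DataFrame(
        {
            "t1": [1.0, 2.0, 0.0, 5.0, 3.0],
            "t2": [2.0, 4.0, 0.0, 5.0, 1.0],
            "t3": [3.0, 6.0, 0.0, 5.0, 4.0],
            "t4": [4.0, 8.0, 0.0, 5.0, 2.0],
            "t5": [5.0, 10.0, 0.0, 5.0, 6.0],
            "t6": [6.0, 12.0, 0.0, 5.0, 5.0],
        },
        index=["query", "double", "zeros", "flat", "other"],
    )
    return ExpressionMatrix(df, unit="TPM", col_kind="tissue_median")


@pytest.fixture
def default_config():
    return SimConfig(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
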