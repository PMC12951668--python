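import numpy as np
import pandas as pd
import pytest

from codechron.complexity_metrics import MetricsTable
from codechron.genetic_code import AMINO_ACIDS


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def complete_table(rng):
    """A complete 20 x 16 metrics table with 7 graph / 9 information tags."""
    values = rng.standard_normal((20, 16))
    cols = [f"m{i:02d}" for i in range(16)]
    frameworks = {c: ("graph" if i < 7 else "information") for i, c in enumerate(cols)}
    df = pd.DataFrame(values, index=list(AMINO_ACIDS), columns=cols)
    return MetricsTable(df, frameworks)


@pytest.fixture()
def toy_frame():
    """Six entities, two metrics, hand-checkable distances."""
    return pd.DataFrame(
        {
            "a": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
            "b": [0.0, 0.5, 1.5, 1.0, 2.5, 2.0],
        },
        index=["u", "v", "w", "x", "y", "z"],
    )
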