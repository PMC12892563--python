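import numpy as np
import pandas as pd
import pytest

from hybepi.core import ExpressionMatrix
from hybepi.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=1)


def make_matrix(values: dict, generations: dict, unit="count", feature_meta=None):
    """Small ExpressionMatrix helper: values maps sample -> list."""
    df = pd.DataFrame(values)
    meta = pd.DataFrame(
        {"generation": pd.Series(generations),
         "replicate": pd.Series({s: i + 1 for i, s in enumerate(generations)})}
    )
    return ExpressionMatrix(df, meta, unit=unit, feature_meta=feature_meta)


@pytest.fixture
def three_generation_matrix():
    """2 features × 9 samples, 3 replicates per generation."""
    values = {}
    for gen, base in (("maternal", 10.0), ("paternal", 20.0), ("hybrid", 15.0)):
        for rep in range(1, 4):
            values[f"{gen}_rep{rep}"] = [base, base * 2]
    generations = {s: s.split("_")[0] for s in values}
    df = pd.DataFrame(values, index=["f1", "f2"])
    meta = pd.DataFrame({
        "generation": pd.Series(generations),
        "replicate": pd.Series({s: int(s[-1]) for s in values}),
    })
    return ExpressionMatrix(df, meta, unit="TPM")
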