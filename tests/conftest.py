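import numpy as np
import pandas as pd
import pytest

from hdmrnet import DataTable, normalize_unit_interval


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_table(rng):
    """Five independent uniform inputs plus a nonlinear output, normalized."""
    n = 400
    u = {f"x{i}": rng.uniform(0, 1, n) for i in range(1, 6)}
    y = 0.5 + np.sqrt(3) * (2 * u["x1"] - 1) + 0.3 * rng.standard_normal(n)
    df = pd.DataFrame({**u, "y": y})
    return normalize_unit_interval(DataTable(values=df, condition_id="fixture"))


@pytest.fixture
def tiny_table():
    df = pd.DataFrame({"a": [0.0, 5.0, 10.0], "b": [1.0, 2.0, 4.0]})
    return DataTable(values=df, condition_id="tiny")


def make_unit_table(cols: dict, condition_id: str = "synthetic") -> DataTable:
    """Table whose values are already on the model scale (identity transforms)."""
    df = pd.DataFrame(cols)
    return DataTable(
        values=df,
        condition_id=condition_id,
        normalized=True,
        transforms={c: (0.0, 1.0) for c in df.columns},
    )
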