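import numpy as np
import pandas as pd
import pytest

from pdd.tabular_io import Attribute, CATEGORICAL, NUMERIC, RelationalTable


def make_table(columns: dict, labels=None, modes=None) -> RelationalTable:
    """Build a RelationalTable from plain column lists (test convenience)."""
    n = len(next(iter(columns.values())))
    ids = [f"E{i}" for i in range(1, n + 1)]
    attributes = []
    series = {}
    for name, cells in columns.items():
        mode = (modes or {}).get(name)
        if mode is None:
            mode = NUMERIC if all(
                isinstance(c, (int, float)) for c in cells
            ) else CATEGORICAL
        attributes.append(Attribute(name, mode))
        dtype = float if mode == NUMERIC else object
        series[name] = pd.Series(cells, index=ids, dtype=dtype)
    lab = None
    if labels is not None:
        lab = pd.Series(list(labels), index=ids, dtype=object)
    return RelationalTable(
        entity_ids=ids,
        attributes=attributes,
        values=pd.DataFrame(series),
        labels=lab,
    )


@pytest.fixture
def toy_table():
    """Six printed rows over three categorical attributes."""
    return make_table(
        {
            "A": ["x", "x", "x", "y", "y", "y"],
            "B": ["p", "p", "q", "q", "p", "q"],
            "C": ["m", "m", "m", "n", "n", "m"],
        }
    )


@pytest.fixture
def concordant_table():
    """Two perfectly concordant binary attributes, N=100 (50/50)."""
    return make_table(
        {
            "A": ["a1"] * 50 + ["a2"] * 50,
            "B": ["b1"] * 50 + ["b2"] * 50,
        }
    )


@pytest.fixture
def pair_table():
    """Margins matching the o=20, n=(20,25), N=50 residual example."""
    a = ["a1"] * 20 + ["a2"] * 30
    b = ["b1"] * 25 + ["b2"] * 25
    # a1 rows are the first 20; make exactly 20 of them carry b1
    return make_table({"A": a, "B": b})


def random_table(rng: np.random.Generator, n_rows: int, n_cols: int, n_vals: int = 3):
    cols = {
        f"A{j}": [f"v{rng.integers(n_vals)}" for _ in range(n_rows)]
        for j in range(n_cols)
    }
    return make_table(cols)
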