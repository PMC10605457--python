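import numpy as np
import pandas as pd
import pytest

import qpcrdiff as q


@pytest.fixture(scope="session")
def example():
    """Seeded synthetic replica of the 68×328 four-group experiment."""
    table, truth = q.example_dataset(seed=0)
    return table, truth


@pytest.fixture(scope="session")
def example_norm(example):
    table, _ = example
    report = q.stability_pairs(table, list("ABCDE"))
    return q.delta_ct(table, report.best_pair, exclude=list("ABCDE"))


@pytest.fixture
def small_table():
    """Four samples, two groups, two targets + two housekeeping genes."""
    ct = pd.DataFrame(
        {
            "T1": [25.0, 24.0, 23.0, 22.0],
            "T2": [30.0, 31.0, 29.0, 28.0],
            "H1": [20.0, 20.0, 20.0, 20.0],
            "H2": [22.0, 22.0, 22.0, 22.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series(["g1", "g1", "g2", "g2"], index=ct.index)
    return q.CtTable(ct=ct, group=groups)


@pytest.fixture
def tiny_norm():
    """Normalized table with two clearly separated groups."""
    rng = np.random.default_rng(7)
    vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10)])
    df = pd.DataFrame({"G": vals}, index=[f"s{i}" for i in range(20)])
    groups = pd.Series(["a"] * 10 + ["b"] * 10, index=df.index)
    return q.NormalizedTable(neg_delta_ct=df, group=groups, housekeeping=("H",))
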