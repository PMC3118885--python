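import numpy as np
import pandas as pd
import pytest

import ecosens as es


@pytest.fixture(scope="session")
def scheme():
    return es.load_fixture("table1")


@pytest.fixture(scope="session")
def tree():
    return es.load_fixture("table5")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def slope_spec():
    """A clean, strictly-tiling numeric indicator (raw up, sensitivity up)."""
    return es.IndicatorSpec(
        id="slope",
        kind="numeric",
        direction="benefit",
        intervals=((0.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 25.0), (25.0, float("inf"))),
    )


@pytest.fixture
def b_layer_tree():
    """Four B-layer groups under one root, expert weights."""
    return es.build_weight_tree(
        {
            "id": "root",
            "children": [
                {"id": "soil", "weight": 0.26},
                {"id": "water", "weight": 0.24},
                {"id": "air", "weight": 0.23},
                {"id": "bio", "weight": 0.27},
            ],
        }
    )


def random_matrix(rng, m, n):
    """Random EvaluationMatrix with mixed directions."""
    vals = pd.DataFrame(
        rng.uniform(0.5, 10.0, size=(m, n)),
        index=[f"M{j}" for j in range(m)],
        columns=[f"C{i}" for i in range(n)],
    )
    dirs = {c: ("benefit" if rng.random() < 0.5 else "cost") for c in vals.columns}
    return es.EvaluationMatrix(values=vals, directions=dirs)
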