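from __future__ import annotations

import numpy as np
import pytest

from sbnet.schema import VariableSchema
from sbnet.synthetic_data import GroundTruthModel, default_test_model, sample_categorical


@pytest.fixture(scope="session")
def test_model() -> GroundTruthModel:
    return default_test_model(seed=0)


@pytest.fixture(scope="session")
def test_data(test_model):
    return sample_categorical(test_model, 5000, seed=1)


@pytest.fixture(scope="session")
def chain_model() -> GroundTruthModel:
    """A -> B -> C with hand-written CPTs, all binary except C (3 levels)."""
    schema = [
        VariableSchema("A", "demographic", ("a0", "a1")),
        VariableSchema("B", "demographic", ("b0", "b1")),
        VariableSchema("C", "demographic", ("c0", "c1", "c2")),
    ]
    parents = {"A": (), "B": ("A",), "C": ("B",)}
    cpts = {
        "A": np.array([[0.3, 0.7]]),
        "B": np.array([[0.8, 0.2], [0.25, 0.75]]),
        "C": np.array([[0.6, 0.3, 0.1], [0.1, 0.2, 0.7]]),
    }
    return GroundTruthModel(schema, parents, cpts, n_regions=4)
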