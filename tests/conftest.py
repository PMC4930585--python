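import numpy as np
import pandas as pd
import pytest

import dtalink as dl
from dtalink.io import AssociationTable


@pytest.fixture(scope="session")
def small_dataset() -> dl.SyntheticDataset:
    """50 drugs x 20 targets x 30 ADEs, strong planted signal, seed 0."""
    return dl.generate(dl.small_fixture_config(seed=0))


@pytest.fixture(scope="session")
def reference_dataset() -> dl.SyntheticDataset:
    """The 500 x 100 x 150 strong-signal reference condition, seed 0."""
    return dl.generate(dl.strong_signal_config(seed=0))


@pytest.fixture
def tiny_sim() -> dl.SimilarityMatrix:
    """Hand-laid 4-drug similarity matrix used across scoring tests."""
    ids = ["a", "b", "c", "d"]
    v = np.array(
        [
            [1.0, 0.6, 0.9, 0.1],
            [0.6, 1.0, 0.7, 0.2],
            [0.9, 0.7, 1.0, 0.3],
            [0.1, 0.2, 0.3, 1.0],
        ]
    )
    return dl.SimilarityMatrix(ids, v)


@pytest.fixture
def tiny_dt() -> AssociationTable:
    """Target T1 bound by b and c; target T2 bound by a, b and d."""
    return AssociationTable.from_pairs(
        "drug_target",
        [("b", "T1"), ("c", "T1"), ("a", "T2"), ("b", "T2"), ("d", "T2")],
    )


def assoc_from(kind: str, pairs) -> AssociationTable:
    return AssociationTable.from_pairs(kind, pairs)
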