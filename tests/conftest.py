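import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from rankcorr import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_counts():
    """6 cells x 3 genes; gene_0 perfectly tracks the first three cells.

    gene_0 is constant within each group, so its ranks coincide exactly with
    the ranks of the group indicator and its Spearman correlation is exactly 1.
    """
    values = np.array(
        [
            [5, 0, 3],
            [5, 7, 0],
            [5, 0, 2],
            [0, 6, 1],
            [0, 0, 4],
            [0, 5, 0],
        ]
    )
    return CountMatrix(values=values, gene_ids=["gene_0", "gene_1", "gene_2"])


@pytest.fixture
def toy_tau():
    return np.array([1, 1, 1, -1, -1, -1], dtype=float)


def random_counts(rng, n, p, high=20):
    """Random small count matrix guaranteed to have no constant gene."""
    while True:
        V = rng.integers(0, high, size=(n, p))
        if np.all(V.max(axis=0) > V.min(axis=0)):
            return CountMatrix(values=V, gene_ids=[f"g{j}" for j in range(p)])


@pytest.fixture
def three_class_counts():
    """9 cells in 3 classes; each class has one exclusive high-count gene."""
    rng = np.random.default_rng(7)
    n, p = 9, 6
    y = np.repeat([0, 1, 2], 3)
    V = rng.integers(0, 3, size=(n, p))
    for k in range(3):
        V[:, k] = np.where(y == k, 50 + rng.integers(0, 5, size=n), 0)
    X = CountMatrix(values=V, gene_ids=[f"g{j}" for j in range(p)])
    return X, y
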