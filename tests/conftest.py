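import numpy as np
import pandas as pd
import pytest

from boolgrn import BooleanNetwork, CountMatrix


@pytest.fixture
def toy3():
    """3-gene network: A = B & !C, B = A | C, C = !A (hand-analysed)."""
    return BooleanNetwork(
        genes=["A", "B", "C"],
        parents={"A": ["B", "C"], "B": ["A", "C"], "C": ["A"]},
        truth_tables={
            "A": (0, 0, 1, 0),  # B & !C
            "B": (0, 1, 1, 1),  # A | C
            "C": (1, 0),        # !A
        },
    )


@pytest.fixture
def counts_4x3():
    counts = pd.DataFrame(
        {
            "s1": [10, 20, 5, 100],
            "s2": [30, 10, 8, 50],
            "s3": [20, 40, 2, 80],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    condition = pd.Series(["ND", "ND", "HFD"], index=["s1", "s2", "s3"])
    return CountMatrix(counts, condition)


def make_counts(counts_array, labels, genes=None):
    counts_array = np.asarray(counts_array)
    genes = genes or [f"g{i + 1}" for i in range(counts_array.shape[0])]
    samples = [f"s{j + 1}" for j in range(counts_array.shape[1])]
    return CountMatrix(
        pd.DataFrame(counts_array, index=genes, columns=samples),
        pd.Series(labels, index=samples),
    )


def identity_network(n):
    """Each gene copies itself: every state is a fixed point."""
    genes = [f"g{i}" for i in range(n)]
    return BooleanNetwork(
        genes=genes,
        parents={g: [g] for g in genes},
        truth_tables={g: (0, 1) for g in genes},
    )


def constant_network(n, bits=None):
    genes = [f"g{i}" for i in range(n)]
    bits = bits or [0] * n
    return BooleanNetwork(
        genes=genes,
        parents={g: [] for g in genes},
        truth_tables={g: (b,) for g, b in zip(genes, bits)},
    )


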