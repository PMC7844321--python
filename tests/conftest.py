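import numpy as np
import pandas as pd
import pytest

from mirmark.diffexpr import ExpressionMatrix
from mirmark.network import BipartiteNetwork


@pytest.fixture
def tiny_network() -> BipartiteNetwork:
    """m1 -> {g1, g2}, m2 -> {g2}: NSR(m1)=1 (g1 single-line), NSR(m2)=0."""
    return BipartiteNetwork.from_edges([("m1", "g1"), ("m1", "g2"), ("m2", "g2")])


def random_bipartite(rng: np.random.Generator, n_mirna: int, n_mrna: int, density: float) -> BipartiteNetwork:
    mirnas = [f"m{i}" for i in range(n_mirna)]
    mrnas = [f"g{j}" for j in range(n_mrna)]
    mask = rng.random((n_mirna, n_mrna)) < density
    edges = [(mirnas[i], mrnas[j]) for i, j in zip(*np.nonzero(mask))]
    return BipartiteNetwork.from_edges(edges, mirna_nodes=mirnas, mrna_nodes=mrnas)


@pytest.fixture
def two_group_matrix() -> ExpressionMatrix:
    """Six samples, three groups, four features with known arithmetic."""
    values = pd.DataFrame(
        {
            "n1": [1.0, 5.0, 0.0, 2.0],
            "n2": [1.0, 6.0, 0.0, 2.0],
            "p1": [3.0, 5.5, 0.0, 1.0],
            "p2": [3.0, 4.5, 0.0, 1.0],
            "m1": [3.0, 5.0, 0.0, 4.0],
            "m2": [3.0, 6.0, 0.0, 4.0],
        },
        index=["flat_shift", "noisy", "constant", "progression"],
    )
    groups = pd.Series(
        {"n1": "normal", "n2": "normal", "p1": "pPCa", "p2": "pPCa", "m1": "mPCa", "m2": "mPCa"}
    )
    return ExpressionMatrix(values=values, groups=groups)
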