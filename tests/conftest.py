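import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from profun.structure_graph import ContactGraph


def random_contact_graph(
    rng: np.random.Generator,
    n_nodes: int,
    edge_prob: float = 0.4,
    self_loops: bool = False,
    ensure_connected_walk: bool = True,
) -> ContactGraph:
    """Random undirected graph; optionally guarantee every node a neighbour."""
    edges = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.add((i, j))
    if ensure_connected_walk and n_nodes > 1:
        for i in range(n_nodes):
            if not any(i in e for e in edges):
                j = int(rng.integers(0, n_nodes - 1))
                j = j if j < i else j + 1
                edges.add((min(i, j), max(i, j)))
    if self_loops:
        edges |= {(i, i) for i in range(n_nodes)}
    return ContactGraph("rand", n_nodes, edges, has_self_loops=self_loops)


def random_dense_adjacency(rng: np.random.Generator, n: int, p: float = 0.35) -> np.ndarray:
    """Symmetric {0,1} adjacency with unit diagonal."""
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    np.fill_diagonal(A, 1.0)
    return A


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def helix_chain():
    from profun.synth import generate_chain

    chain, pdb_text = generate_chain(30, "helix", seed=0, protein_id="HLX")
    return chain, pdb_text
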