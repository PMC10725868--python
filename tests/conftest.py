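import numpy as np
import pytest

from multisyn.graph_views import MolecularGraph
from multisyn.synthetic_data import generate_world

ATOM_LABELS = ("C", "N", "O", "S")
BOND_LABELS = ("single", "double", "triple", "aromatic")


def random_labeled_graph(rng: np.random.Generator, max_nodes: int = 8) -> MolecularGraph:
    """Random connected atom/bond-labeled graph for oracle comparisons."""
    n = int(rng.integers(1, max_nodes + 1))
    labels = tuple(rng.choice(ATOM_LABELS) for _ in range(n))
    edges = {}
    for j in range(1, n):  # random spanning tree keeps it connected
        i = int(rng.integers(0, j))
        edges[(i, j)] = str(rng.choice(BOND_LABELS))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        i, j = sorted(rng.choice(n, size=2, replace=False)) if n > 1 else (0, 0)
        if n > 1 and (i, j) not in edges:
            edges[(i, j)] = str(rng.choice(BOND_LABELS))
    return MolecularGraph(labels, edges)


def permute_graph(graph: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Relabel nodes by ``perm`` (node i becomes perm[i]), preserving labels."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    labels = tuple(graph.node_labels[inv[k]] for k in range(len(perm)))
    edges = {}
    for (i, j), lab in graph.edges.items():
        a, b = int(perm[i]), int(perm[j])
        edges[(min(a, b), max(a, b))] = lab
    return MolecularGraph(labels, edges)


@pytest.fixture(scope="session")
def world():
    """Default-condition synthetic world shared by read-only tests."""
    return generate_world(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
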