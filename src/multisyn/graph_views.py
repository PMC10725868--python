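"""Multi-view molecular graph embedding.

A molecule parsed from SMILES becomes a labeled undirected graph (atoms as
nodes, bonds as edges). Four complementary summaries of that graph are
encoded into fixed-length vectors and concatenated into a single drug
descriptor:

I.   node-label codes — each distinct atom symbol gets an integer code and
     the view is the per-node code sequence;
II.  bond-label path counts — every simple path up to ``max_edges`` edges is
     keyed by its bond-label sequence and the occurrences counted;
III. shortest-path-length histogram — for every unordered node pair in a
     connected component, the BFS distance, histogrammed by length;
IV.  atom-label path counts — as view II but keyed by the atom-label
     sequence along the path (endpoints included).

Paths are *simple* (no repeated node) and capped at ``max_edges`` edges
(default 6): unbounded "all paths" diverges on rings. Each undirected path is
counted once; a view keys a path by the lexicographically smaller of the
label sequence and its reverse, which makes the counts invariant under
label-preserving node permutations.

Vector positions for views II–IV come from a corpus-level vocabulary ranked
by total count (ties lexicographic); view-I codes come from a corpus-level
atom-symbol dictionary in first-occurrence order starting at 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem

__all__ = [
    "MolecularGraph",
    "ViewCounts",
    "ViewVocabulary",
    "GraphEmbedding",
    "smiles_to_graph",
    "enumerate_simple_paths",
    "view_node_labels",
    "view_bond_label_paths",
    "view_shortest_path_lengths",
    "view_atom_label_paths",
    "build_view_vocab",
    "build_label_map",
    "embed_graph",
    "DEFAULT_MAX_EDGES",
    "DEFAULT_VIEW_DIMS",
]

DEFAULT_MAX_EDGES = 6
#: per-view vector lengths (I, II, III, IV)
DEFAULT_VIEW_DIMS = (64, 128, 32, 128)

_BOND_LABELS = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class VocabularyError(KeyError):
    """Raised when a graph contains an atom symbol absent from the label map."""


@dataclass(frozen=True)
class MolecularGraph:
    """Atom-labeled, bond-labeled undirected graph.

    ``node_labels[i]`` is the atom symbol of node ``i`` (0-based, parser atom
    order, implicit hydrogens omitted); ``edges`` maps each unordered index
    pair ``(i, j)`` with ``i < j`` to a bond label.
    """

    node_labels: tuple[str, ...]
    edges: dict[tuple[int, int], str]

    def __post_init__(self):
        n = len(self.node_labels)
        for (i, j), label in self.edges.items():
            if i == j:
                raise ValueError(f"self-loop edge ({i},{j})")
            if not (0 <= i < j < n):
                raise ValueError(f"invalid edge ({i},{j}) for {n} nodes")
            if not label:
                raise ValueError("empty bond label")
        if any(not lab for lab in self.node_labels):
            raise ValueError("empty atom label")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        for nbrs in adj:
            nbrs.sort()
        return adj

    def bond_label(self, i: int, j: int) -> str:
        return self.edges[(i, j) if i < j else (j, i)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, lab in enumerate(self.node_labels):
            g.add_node(i, label=lab)
        for (i, j), lab in self.edges.items():
            g.add_edge(i, j, label=lab)
        return g


@dataclass(frozen=True)
class ViewCounts:
    """Key → occurrence-count map for one view (II, III or IV)."""

    view_id: str
    counts: dict

    def __post_init__(self):
        if self.view_id not in {"II", "III", "IV"}:
            raise ValueError(f"unknown view id {self.view_id!r}")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("counts must be >= 1 for present keys")


@dataclass(frozen=True)
class ViewVocabulary:
    """Ordered key → vector-position assignment for one view."""

    view_id: str
    keys: tuple
    dim: int

    def __post_init__(self):
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("vocabulary keys must be unique")
        if len(self.keys) > self.dim:
            raise ValueError("more keys than dimensions")


@dataclass(frozen=True)
class GraphEmbedding:
    """Per-view fixed-length vectors and their concatenation (order I–IV)."""

    view_vectors: dict[str, np.ndarray] = field(repr=False)

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.view_vectors[v] for v in ("I", "II", "III", "IV")])


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Node order follows the rdkit atom order; hydrogens stay implicit and
    aromatic bonds keep their own ``"aromatic"`` label (no kekulization).
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    labels = tuple(atom.GetSymbol() for atom in mol.GetAtoms())
    edges: dict[tuple[int, int], str] = {}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        label = _BOND_LABELS.get(bond.GetBondType(), str(bond.GetBondType()).lower())
        edges[(min(i, j), max(i, j))] = label
    return MolecularGraph(labels, edges)


def enumerate_simple_paths(graph: MolecularGraph, max_edges: int) -> list[tuple[int, ...]]:
    """Every simple path with 1..max_edges edges, one per undirected path.

    The representative direction is the one whose node-label sequence is
    lexicographically <= its reverse; on a tie the direction starting at the
    smaller node index wins. Output is sorted by (length, node sequence).
    """
    if max_edges < 1:
        raise ValueError("max_edges must be >= 1")
    adj = graph.neighbors()
    labels = graph.node_labels
    out: list[tuple[int, ...]] = []

    def canonical(path: tuple[int, ...]) -> bool:
        seq = tuple(labels[i] for i in path)
        rev = seq[::-1]
        if seq < rev:
            return True
        if seq > rev:
            return False
        return path[0] < path[-1]

    def dfs(path: list[int], visited: set[int]) -> None:
        if len(path) > 1 and canonical(tuple(path)):
            out.append(tuple(path))
        if len(path) - 1 >= max_edges:
            return
        for nxt in adj[path[-1]]:
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(path, visited)
                path.pop()
                visited.remove(nxt)

    for start in range(graph.n_nodes):
        dfs([start], {start})
    out.sort(key=lambda p: (len(p), p))
    return out


def view_node_labels(graph: MolecularGraph, label_map: dict[str, int]) -> list[int]:
    """View I: the integer code of each node's atom symbol, in node order."""
    missing = sorted({lab for lab in graph.node_labels if lab not in label_map})
    if missing:
        raise VocabularyError(f"atom labels not in label map: {missing}")
    return [label_map[lab] for lab in graph.node_labels]


def _path_key(seq: tuple) -> tuple:
    rev = seq[::-1]
    return seq if seq <= rev else rev


def view_bond_label_paths(graph: MolecularGraph, max_edges: int = DEFAULT_MAX_EDGES) -> ViewCounts:
    """View II: occurrence counts of bond-label sequences along simple paths."""
    counts: Counter = Counter()
    for path in enumerate_simple_paths(graph, max_edges):
        seq = tuple(graph.bond_label(a, b) for a, b in zip(path, path[1:]))
        counts[_path_key(seq)] += 1
    return ViewCounts("II", dict(counts))


def view_shortest_path_lengths(graph: MolecularGraph) -> ViewCounts:
    """View III: histogram of BFS shortest-path lengths over unordered pairs."""
    counts: Counter = Counter()
    g = graph.to_networkx()
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            if src < dst:  # unordered pairs once; self-pairs excluded
                counts[d] += 1
    return ViewCounts("III", dict(counts))


def view_atom_label_paths(graph: MolecularGraph, max_edges: int = DEFAULT_MAX_EDGES) -> ViewCounts:
    """View IV: occurrence counts of atom-label sequences along simple paths."""
    counts: Counter = Counter()
    labels = graph.node_labels
    for path in enumerate_simple_paths(graph, max_edges):
        seq = tuple(labels[i] for i in path)
        counts[_path_key(seq)] += 1
    return ViewCounts("IV", dict(counts))


def build_view_vocab(corpus: list[ViewCounts], dim: int, view_id: str | None = None) -> ViewVocabulary:
    """Frequency-ranked vocabulary over a corpus of per-graph view counts.

    Keys are ranked by total corpus count descending, ties broken
    lexicographically; the top ``dim`` keys are kept.
    """
    if dim < 1:
        raise ValueError("dim must be positive")
    if corpus:
        ids = {vc.view_id for vc in corpus}
        if len(ids) > 1:
            raise ValueError(f"mixed view ids in corpus: {sorted(ids)}")
        view_id = ids.pop()
    elif view_id is None:
        raise ValueError("view_id required for an empty corpus")
    totals: Counter = Counter()
    for vc in corpus:
        totals.update(vc.counts)
    ranked = sorted(totals, key=lambda k: (-totals[k], k))
    return ViewVocabulary(view_id, tuple(ranked[:dim]), dim)


def build_label_map(graphs: list[MolecularGraph]) -> dict[str, int]:
    """Corpus-level atom-symbol codes, first-occurrence order, starting at 1."""
    codes: dict[str, int] = {}
    for g in graphs:
        for lab in g.node_labels:
            if lab not in codes:
                codes[lab] = len(codes) + 1
    return codes


def _encode_counts(vc: ViewCounts, vocab: ViewVocabulary) -> np.ndarray:
    vec = np.zeros(vocab.dim)
    for pos, key in enumerate(vocab.keys):
        vec[pos] = vc.counts.get(key, 0)
    return vec


def embed_graph(
    graph: MolecularGraph,
    vocabs: dict[str, ViewVocabulary],
    label_map: dict[str, int],
    dims: dict[str, int] | None = None,
    max_edges: int = DEFAULT_MAX_EDGES,
) -> GraphEmbedding:
    """Encode all four views of one graph against corpus vocabularies.

    View I is the node-label code sequence zero-padded or truncated to its
    dimension; views II–IV place each vocabulary key's count at its vocab
    position (unseen keys are dropped). Concatenation order is I, II, III, IV.
    """
    if dims is None:
        dims = {"I": DEFAULT_VIEW_DIMS[0]}
    dim_i = dims["I"]
    if dim_i < 1:
        raise ValueError("view-I dimension must be >= 1")
    seq = view_node_labels(graph, label_map)
    vec_i = np.zeros(dim_i)
    kept = min(len(seq), dim_i)
    vec_i[:kept] = seq[:kept]
    views = {
        "I": vec_i,
        "II": _encode_counts(view_bond_label_paths(graph, max_edges), vocabs["II"]),
        "III": _encode_counts(view_shortest_path_lengths(graph), vocabs["III"]),
        "IV": _encode_counts(view_atom_label_paths(graph, max_edges), vocabs["IV"]),
    }
    return GraphEmbedding(views)
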