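"""Molecular graph parsing and the four-view embedding."""

import networkx as nx
import numpy as np
import pytest

import multisyn.graph_views as gv
from multisyn.graph_views import (MolecularGraph, SmilesParseError,
                                  VocabularyError, build_label_map,
                                  build_view_vocab, embed_graph,
                                  enumerate_simple_paths, smiles_to_graph,
                                  view_atom_label_paths, view_bond_label_paths,
                                  view_node_labels, view_shortest_path_lengths)

from conftest import permute_graph, random_labeled_graph

TRIANGLE = MolecularGraph(("C", "C", "C"),
                          {(0, 1): "single", (1, 2): "single", (0, 2): "single"})


def oracle_view_counts(graph: MolecularGraph, max_edges: int):
    """Brute-force path enumeration via networkx, independent of the package.

    Enumerates every simple path between each unordered node pair with
    ``nx.all_simple_paths`` and keys each path by the lexicographic minimum
    of its label sequence and the reverse.
    """
    g = graph.to_networkx()
    bond_counts, atom_counts = {}, {}
    for u in g.nodes:
        for v in g.nodes:
            if u >= v:
                continue
            for path in nx.all_simple_paths(g, u, v, cutoff=max_edges):
                bonds = tuple(g.edges[a, b]["label"] for a, b in zip(path, path[1:]))
                atoms = tuple(graph.node_labels[i] for i in path)
                bk = min(bonds, bonds[::-1])
                ak = min(atoms, atoms[::-1])
                bond_counts[bk] = bond_counts.get(bk, 0) + 1
                atom_counts[ak] = atom_counts.get(ak, 0) + 1
    return bond_counts, atom_counts


def oracle_shortest_lengths(graph: MolecularGraph):
    """Hand-rolled all-pairs BFS over unordered pairs."""
    adj = graph.neighbors()
    counts = {}
    n = graph.n_nodes
    for src in range(n):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for dst, d in dist.items():
            if src < dst:
                counts[d] = counts.get(d, 0) + 1
    return counts


class TestSmilesParsing:
    def test_ethanol(self):
        g = smiles_to_graph("CCO")
        assert g.node_labels == ("C", "C", "O")
        assert g.edges == {(0, 1): "single", (1, 2): "single"}

    def test_single_atom(self):
        g = smiles_to_graph("C")
        assert g.n_nodes == 1 and not g.edges

    def test_cyclopropane_cycle(self):
        g = smiles_to_graph("C1CC1")
        assert g.node_labels == ("C", "C", "C")
        assert set(g.edges) == {(0, 1), (1, 2), (0, 2)}
        assert set(g.edges.values()) == {"single"}

    def test_aromatic_bonds_keep_label(self):
        g = smiles_to_graph("c1ccccc1")
        assert set(g.edges.values()) == {"aromatic"}

    @pytest.mark.parametrize("bad", ["", "not-a-smiles", "C1CC"])
    def test_parse_error_names_input(self, bad):
        with pytest.raises(SmilesParseError):
            smiles_to_graph(bad)


class TestPathEnumeration:
    def test_ethanol_paths(self):
        g = smiles_to_graph("CCO")
        assert enumerate_simple_paths(g, 6) == [(0, 1), (1, 2), (0, 1, 2)]

    def test_single_node_no_paths(self):
        assert enumerate_simple_paths(MolecularGraph(("C",), {}), 6) == []

    def test_triangle_counts(self):
        paths = enumerate_simple_paths(TRIANGLE, 2)
        assert len(paths) == 6
        assert sum(1 for p in paths if len(p) == 2) == 3
        assert sum(1 for p in paths if len(p) == 3) == 3

    def test_one_representative_per_undirected_path(self, rng):
        for _ in range(20):
            g = random_labeled_graph(rng)
            seen = set()
            for p in enumerate_simple_paths(g, 4):
                assert p[::-1] not in seen
                seen.add(p)

    def test_max_edges_monotonicity(self, rng):
        for _ in range(10):
            g = random_labeled_graph(rng)
            for smaller, larger in [(1, 3), (3, 6)]:
                c_small = view_atom_label_paths(g, smaller).counts
                c_large = view_atom_label_paths(g, larger).counts
                for key, cnt in c_small.items():
                    assert c_large[key] >= cnt
                b_small = view_bond_label_paths(g, smaller).counts
                b_large = view_bond_label_paths(g, larger).counts
                for key, cnt in b_small.items():
                    assert b_large[key] >= cnt


class TestViewExamples:
    def test_view_i_ethanol(self):
        g = smiles_to_graph("CCO")
        assert view_node_labels(g, {"C": 1, "O": 2}) == [1, 1, 2]
        assert view_node_labels(smiles_to_graph("C"), {"C": 1}) == [1]
        assert view_node_labels(TRIANGLE, {"C": 1}) == [1, 1, 1]

    def test_view_i_unseen_label_errors(self):
        with pytest.raises(VocabularyError):
            view_node_labels(smiles_to_graph("CCO"), {"C": 1})

    def test_view_ii(self):
        assert view_bond_label_paths(smiles_to_graph("CCO")).counts == {
            ("single",): 2, ("single", "single"): 1}
        assert view_bond_label_paths(smiles_to_graph("C")).counts == {}
        assert view_bond_label_paths(TRIANGLE).counts == {
            ("single",): 3, ("single", "single"): 3}

    def test_view_iii(self):
        assert view_shortest_path_lengths(smiles_to_graph("CCO")).counts == {1: 2, 2: 1}
        assert view_shortest_path_lengths(smiles_to_graph("C")).counts == {}
        assert view_shortest_path_lengths(TRIANGLE).counts == {1: 3}

    def test_view_iv(self):
        assert view_atom_label_paths(smiles_to_graph("CCO")).counts == {
            ("C", "C"): 1, ("C", "O"): 1, ("C", "C", "O"): 1}
        assert view_atom_label_paths(smiles_to_graph("C")).counts == {}
        assert view_atom_label_paths(TRIANGLE).counts == {
            ("C", "C"): 3, ("C", "C", "C"): 3}


class TestOracleEquivalence:
    def test_views_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            g = random_labeled_graph(rng)
            max_edges = int(rng.integers(1, 7))
            bonds, atoms = oracle_view_counts(g, max_edges)
            assert view_bond_label_paths(g, max_edges).counts == bonds
            assert view_atom_label_paths(g, max_edges).counts == atoms
            assert view_shortest_path_lengths(g).counts == oracle_shortest_lengths(g)

    def test_isomorphism_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(12):
            g = random_labeled_graph(rng)
            for _ in range(20):
                perm = rng.permutation(g.n_nodes)
                h = permute_graph(g, perm)
                assert view_bond_label_paths(h, 5).counts == view_bond_label_paths(g, 5).counts
                assert view_atom_label_paths(h, 5).counts == view_atom_label_paths(g, 5).counts
                assert view_shortest_path_lengths(h).counts == view_shortest_path_lengths(g).counts


class TestVocabulary:
    def test_rank_by_corpus_totals(self):
        corpus = [gv.ViewCounts("III", {1: 3, 2: 1}), gv.ViewCounts("III", {2: 4})]
        vocab = build_view_vocab(corpus, dim=2)
        assert vocab.keys == (2, 1)  # totals 5 > 3

    def test_empty_corpus_is_valid(self):
        vocab = build_view_vocab([], dim=4, view_id="II")
        assert vocab.keys == ()

    def test_lexicographic_tie_break(self):
        corpus = [gv.ViewCounts("IV", {("C", "N"): 1, ("C", "C"): 1})]
        assert build_view_vocab(corpus, dim=1).keys == (("C", "C"),)

    def test_label_map_first_occurrence_from_one(self):
        graphs = [smiles_to_graph("CCO"), smiles_to_graph("N")]
        assert build_label_map(graphs) == {"C": 1, "O": 2, "N": 3}


class TestEmbedding:
    def _vocabs_for(self, g, max_edges=6, dims=(4, 3, 4)):
        return {
            "II": build_view_vocab([view_bond_label_paths(g, max_edges)], dims[0]),
            "III": build_view_vocab([view_shortest_path_lengths(g)], dims[1]),
            "IV": build_view_vocab([view_atom_label_paths(g, max_edges)], dims[2]),
        }

    def test_ethanol_view_iii_segment(self):
        g = smiles_to_graph("CCO")
        vocabs = self._vocabs_for(g)
        emb = embed_graph(g, vocabs, {"C": 1, "O": 2}, {"I": 5})
        assert vocabs["III"].keys == (1, 2)
        np.testing.assert_array_equal(emb.view_vectors["III"], [2, 1, 0])
        np.testing.assert_array_equal(emb.view_vectors["I"], [1, 1, 2, 0, 0])
        assert emb.vector.shape == (5 + 4 + 3 + 4,)

    def test_single_atom_only_view_i_nonzero(self):
        g = smiles_to_graph("C")
        vocabs = {
            "II": build_view_vocab([], 4, "II"),
            "III": build_view_vocab([], 3, "III"),
            "IV": build_view_vocab([], 4, "IV"),
        }
        emb = embed_graph(g, vocabs, {"C": 1}, {"I": 3})
        assert emb.view_vectors["I"][0] == 1
        assert np.count_nonzero(emb.vector) == 1

    def test_isomorphic_relabelings_share_count_views(self, rng):
        g = random_labeled_graph(rng, max_nodes=6)
        h = permute_graph(g, rng.permutation(g.n_nodes))
        vocabs = self._vocabs_for(g)
        lm = build_label_map([g, h])
        e1 = embed_graph(g, vocabs, lm, {"I": 6})
        e2 = embed_graph(h, vocabs, lm, {"I": 6})
        for view in ("II", "III", "IV"):
            np.testing.assert_array_equal(e1.view_vectors[view], e2.view_vectors[view])

    def test_encoding_conservation(self, rng):
        # encoded view-II mass never exceeds the total path count; equal when
        # the vocabulary covers every observed key
        for _ in range(10):
            g = random_labeled_graph(rng)
            counts = view_bond_label_paths(g, 4).counts
            full = {
                "II": build_view_vocab([gv.ViewCounts("II", counts)], max(len(counts), 1))
                if counts else build_view_vocab([], 1, "II"),
                "III": build_view_vocab([view_shortest_path_lengths(g)], 8)
                if view_shortest_path_lengths(g).counts else build_view_vocab([], 1, "III"),
                "IV": build_view_vocab([view_atom_label_paths(g, 4)], 64)
                if view_atom_label_paths(g, 4).counts else build_view_vocab([], 1, "IV"),
            }
            emb = embed_graph(g, full, build_label_map([g]), {"I": 8}, max_edges=4)
            assert emb.view_vectors["II"].sum() == sum(counts.values())
            truncated = {**full, "II": build_view_vocab(
                [gv.ViewCounts("II", counts)], 1) if counts else full["II"]}
            emb2 = embed_graph(g, truncated, build_label_map([g]), {"I": 8}, max_edges=4)
            assert emb2.view_vectors["II"].sum() <= sum(counts.values())
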