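"""Graph construction, largest component, modularity and Louvain clustering.

The modularity formula is checked three ways: hand-computed fixtures,
agreement with networkx's implementation on random (graph, partition)
pairs, and conservation identities; Louvain is checked against brute-force
partition enumeration on small graphs and against planted communities.
"""

from __future__ import annotations

import random

import networkx as nx
import pytest

from litescan.corpus import Article, Corpus
from litescan.graph import (Partition, build_graph, edge_fractions,
                            largest_component, louvain_cluster, modularity,
                            read_partition, renumber_by_size, write_partition)
from conftest import exhaustive_best_modularity


def corpus_of(ids_years):
    return Corpus([Article(id=i, year=y) for i, y in ids_years], {})


class TestBuildGraph:
    def test_nodes_edges_and_isolates(self):
        c = corpus_of([("A", 2010), ("B", 2011), ("C", 2012)])
        g = build_graph(c, [("B", "A"), ("C", "A")])
        assert set(g.nodes) == {"A", "B", "C"}
        assert g.number_of_edges() == 2
        g2 = build_graph(c, [])
        assert g2.number_of_edges() == 0 and g2.number_of_nodes() == 3

    def test_duplicate_edge_collapses_and_unknown_endpoint_raises(self):
        c = corpus_of([("A", 2010), ("B", 2011)])
        g = build_graph(c, [("B", "A"), ("B", "A")])
        assert g.number_of_edges() == 1
        with pytest.raises(ValueError, match="endpoint"):
            build_graph(c, [("B", "Z")])

    def test_year_attribute_carried(self):
        c = corpus_of([("A", 2010), ("B", None)])
        g = build_graph(c, [])
        assert g.nodes["A"]["year"] == 2010
        assert g.nodes["B"]["year"] is None


class TestLargestComponent:
    def test_largest_weak_component_wins(self):
        c = corpus_of([(i, 2010) for i in "abcde"])
        g = build_graph(c, [("b", "a"), ("c", "a"), ("e", "d")])
        assert set(largest_component(g).nodes) == {"a", "b", "c"}

    def test_connected_graph_is_identity(self):
        c = corpus_of([(i, 2010) for i in "abc"])
        g = build_graph(c, [("b", "a"), ("c", "b")])
        assert set(largest_component(g).nodes) == set(g.nodes)

    def test_size_tie_broken_by_smallest_id(self):
        c = corpus_of([(i, 2010) for i in ("a1", "a2", "b1", "b2")])
        g = build_graph(c, [("a2", "a1"), ("b2", "b1")])
        assert set(largest_component(g).nodes) == {"a1", "a2"}

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            largest_component(nx.DiGraph())


class TestModularity:
    def test_triangle_bridge_equals_hand_value(self, triangle_bridge):
        part = {0: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2}
        assert modularity(triangle_bridge, part) == pytest.approx(5 / 14, abs=1e-15)

    def test_singleton_triangle(self):
        g = nx.cycle_graph(3)
        assert modularity(g, {0: 1, 1: 2, 2: 3}) == pytest.approx(-1 / 3, abs=1e-15)

    def test_identity_partition_is_zero_on_random_graphs(self):
        rng = random.Random(11)
        for _ in range(50):
            g = nx.gnp_random_graph(rng.randint(3, 20), 0.3,
                                    seed=rng.randint(0, 10 ** 6))
            if g.number_of_edges() == 0:
                continue
            assert modularity(g, {n: 1 for n in g}) == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_networkx_on_random_pairs(self):
        rng = random.Random(5)
        checked = 0
        while checked < 100:
            g = nx.gnp_random_graph(rng.randint(4, 18), 0.35,
                                    seed=rng.randint(0, 10 ** 6))
            if g.number_of_edges() == 0:
                continue
            labels = {v: rng.randint(1, 4) for v in g}
            groups = {}
            for v, lab in labels.items():
                groups.setdefault(lab, set()).add(v)
            assert modularity(g, labels) == pytest.approx(
                nx.community.modularity(g, groups.values()), abs=1e-12)
            checked += 1

    def test_conservation_identities(self):
        rng = random.Random(23)
        for _ in range(25):
            g = nx.gnp_random_graph(rng.randint(4, 15), 0.4,
                                    seed=rng.randint(0, 10 ** 6))
            if g.number_of_edges() == 0:
                continue
            labels = {v: rng.randint(1, 3) for v in g}
            e, a, cross = edge_fractions(g, labels)
            assert sum(e.values()) + cross == pytest.approx(1.0, abs=1e-12)
            assert sum(a.values()) == pytest.approx(1.0, abs=1e-12)

    def test_edgeless_graph_errors(self):
        g = nx.empty_graph(3)
        with pytest.raises(ValueError):
            modularity(g, {n: 1 for n in g})


class TestLouvain:
    def test_recovers_two_cliques(self, two_cliques):
        part = louvain_cluster(two_cliques, seed=3)
        assert len(part) == 2
        assert {part.assignment[i] for i in range(5)} != \
            {part.assignment[i] for i in range(5, 10)}
        assert len({part.assignment[i] for i in range(5)}) == 1

    def test_q_value_matches_independent_recomputation(self, two_cliques):
        part = louvain_cluster(two_cliques, seed=3)
        assert part.q_value == pytest.approx(modularity(two_cliques, part), abs=1e-12)

    def test_single_node_graph(self):
        g = nx.empty_graph(1)
        part = louvain_cluster(g, seed=0)
        assert part.assignment == {0: 1}
        assert part.q_value == 0.0

    def test_same_seed_is_bit_reproducible(self, two_cliques):
        a = louvain_cluster(two_cliques, seed=9)
        b = louvain_cluster(two_cliques, seed=9)
        assert a.assignment == b.assignment and a.q_value == b.q_value

    def test_seed_invariant_q_on_well_separated_fixture(self, two_cliques):
        qs = {louvain_cluster(two_cliques, seed=s).q_value for s in range(5)}
        assert len(qs) == 1

    def test_never_beats_exhaustive_search_and_attains_it_on_cliques(self):
        """On all small connected fixtures Louvain's Q is bounded by the
        brute-force maximum; on paired-clique fixtures it attains it."""
        rng = random.Random(41)
        fixtures = []
        while len(fixtures) < 12:
            g = nx.gnp_random_graph(rng.randint(4, 7), 0.5,
                                    seed=rng.randint(0, 10 ** 6))
            if g.number_of_edges() and nx.is_connected(g):
                fixtures.append(("random", g))
        pair3 = nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (0, 3)])
        k3 = nx.complete_graph(3)
        k4 = nx.complete_graph(4)
        pair34 = nx.disjoint_union(k3, k4)
        pair34.add_edge(0, 3)
        fixtures += [("cliques", pair3), ("cliques", pair34)]
        for kind, g in fixtures:
            q_best = exhaustive_best_modularity(g)
            q_louvain = louvain_cluster(g, seed=17).q_value
            assert q_louvain <= q_best + 1e-12
            if kind == "cliques":
                assert q_louvain == pytest.approx(q_best, abs=1e-12)


class TestRenumber:
    def test_descending_size(self):
        p = renumber_by_size(Partition({"a": 7, "b": 3, "c": 3, "d": 3, "e": 7}))
        sizes = p.sizes()
        assert sizes[1] == 3 and sizes[2] == 2
        assert sorted(p.labels) == [1, 2]

    def test_already_ordered_is_identity(self):
        p = Partition({"a": 1, "b": 1, "c": 2})
        assert renumber_by_size(p).assignment == p.assignment

    def test_size_tie_broken_by_smallest_member_id(self):
        p = renumber_by_size(Partition({"z1": 5, "z2": 5, "a1": 9, "a2": 9}))
        assert p.assignment["a1"] == 1 and p.assignment["z1"] == 2

    def test_labels_contiguous_from_one(self):
        p = renumber_by_size(Partition({"a": 10, "b": 20, "c": 30}))
        assert sorted(set(p.assignment.values())) == [1, 2, 3]


def test_graphml_export_carries_cluster_labels(tmp_path):
    from litescan.graph import write_graphml
    c = corpus_of([("A", 2010), ("B", 2011)])
    g = build_graph(c, [("B", "A")])
    path = tmp_path / "g.graphml"
    write_graphml(g, path, Partition({"A": 1, "B": 1}))
    back = nx.read_graphml(path)
    assert back.nodes["A"]["cluster"] == 1
    assert back.nodes["A"]["year"] == 2010


def test_partition_tsv_round_trip(tmp_path):
    p = Partition({"a": 1, "b": 2, "c": 1}, q_value=0.5)
    path = tmp_path / "part.tsv"
    write_partition(p, path)
    assert read_partition(path).assignment == p.assignment
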