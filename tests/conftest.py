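"""Shared fixtures: tiny handmade corpora, oracle graphs, synthetic runs."""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from litescan.corpus import Article, Corpus, ReferenceDescriptor


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Five articles with id-resolvable references and two obvious groups."""
    def art(i, year, refs, title="", keywords=()):
        return Article(id=i, year=year, title=title, keywords=list(keywords),
                       refs=[ReferenceDescriptor(raw=r) for r in refs])

    return Corpus([
        art("p1", 2010, [], title="organ printing"),
        art("p2", 2012, ["p1"], title="printing tissue constructs"),
        art("p3", 2014, ["p1", "p2"], title="bioprinting hydrogel scaffolds"),
        art("p4", 2011, [], title="stem cell niche"),
        art("p5", 2015, ["p4"], title="stem cell differentiation"),
    ], {"source": "fixture"})


@pytest.fixture
def two_cliques() -> nx.Graph:
    """Two 5-cliques joined by a single bridge edge; the canonical
    two-community graph whose optimal partition is the two cliques."""
    g = nx.Graph()
    for base in (0, 5):
        g.add_edges_from((base + i, base + j)
                         for i, j in itertools.combinations(range(5), 2))
    g.add_edge(0, 5)
    return g


@pytest.fixture
def triangle_bridge() -> nx.Graph:
    """Two triangles joined by one bridge edge (m = 7)."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (0, 3)])
    return g


def all_partitions(items):
    """Every set partition of ``items`` (Bell number of them)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_modularity(graph: nx.Graph) -> float:
    """Brute-force maximum modularity over all partitions (independent oracle)."""
    best = -1.0
    nodes = list(graph.nodes)
    for part in all_partitions(nodes):
        q = nx.community.modularity(graph, [set(g) for g in part])
        best = max(best, q)
    return best
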