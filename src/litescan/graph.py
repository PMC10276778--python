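"""Citation-graph construction, largest component, modularity and Louvain.

The citation graph is a :class:`networkx.DiGraph` whose nodes are article
ids (with a ``year`` attribute) and whose edges point citing -> cited.
Community structure is computed on the *undirected simple projection* of
that graph: the modularity formula used throughout is the undirected
Newman form

    Q = sum_i (e_ii - a_i**2)

with e_ii the fraction of edges inside cluster i and a_i the fraction of
edge endpoints attached to cluster i.  Citation direction is retained only
for citation counting (hub papers, within-cluster citation counts).

Louvain is the greedy two-phase heuristic (local moving + graph
aggregation) run to convergence.  Node visit order is shuffled by a seed,
ties are broken toward the lowest community id, and all internal orderings
are sorted, so a fixed seed gives bit-identical partitions.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import networkx as nx

__all__ = [
    "Partition",
    "build_graph",
    "largest_component",
    "undirected_projection",
    "modularity",
    "edge_fractions",
    "louvain_cluster",
    "renumber_by_size",
    "write_partition",
    "read_partition",
    "write_graphml",
]


@dataclass(frozen=True)
class Partition:
    """A hard assignment of article ids to positive-integer cluster labels.

    After :func:`renumber_by_size` the labels are exactly ``1..K`` with
    cluster sizes non-increasing in label order.  ``q_value`` is the
    modularity of the assignment on the undirected projection of the graph
    it was computed on (0.0 by convention for edgeless graphs).
    """

    assignment: dict[Hashable, int]
    q_value: float = 0.0

    def members(self, label: int) -> set:
        return {n for n, lab in self.assignment.items() if lab == label}

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = defaultdict(int)
        for lab in self.assignment.values():
            out[lab] += 1
        return dict(out)

    def __len__(self) -> int:
        return len(set(self.assignment.values()))


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_graph(corpus, edges: Iterable[tuple[str, str]]) -> nx.DiGraph:
    """Build the directed citation graph over all corpus articles.

    Isolated articles are retained as isolated nodes.  Duplicate edges
    collapse and self-loops are dropped; an edge endpoint not present in
    the corpus raises ``ValueError``.
    """
    g = nx.DiGraph()
    for a in corpus:
        g.add_node(a.id, year=a.year)
    for citing, cited in edges:
        if citing not in g or cited not in g:
            raise ValueError(f"edge endpoint not in corpus: ({citing!r}, {cited!r})")
        if citing == cited:
            continue
        g.add_edge(citing, cited)
    return g


def largest_component(graph: nx.DiGraph) -> nx.DiGraph:
    """Node-induced subgraph of the largest weakly connected component.

    Connectivity ignores citation direction (a direction-sensitive notion
    would shatter a citation DAG).  Ties on size are broken toward the
    component containing the lexicographically smallest node id.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("largest_component of an empty graph is undefined")
    comps = nx.weakly_connected_components(graph) if graph.is_directed() \
        else nx.connected_components(graph)
    best = min(comps, key=lambda c: (-len(c), min(map(str, c))))
    return graph.subgraph(best).copy()


def undirected_projection(graph: nx.Graph) -> nx.Graph:
    """Undirected simple projection: antiparallel edge pairs collapse."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes(data=True))
    for u, v in graph.edges():
        if u != v:
            g.add_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def edge_fractions(graph: nx.Graph, partition: Partition | Mapping
                   ) -> tuple[dict[int, float], dict[int, float], float]:
    """Per-cluster (e_ii, a_i) fractions and the inter-cluster edge fraction.

    e_ii is the fraction of (undirected, simple) edges with both endpoints
    in cluster i; a_i is the fraction of edge endpoints in cluster i.
    ``sum(e) + cross == 1`` and ``sum(a) == 1`` for every partition.
    """
    assignment = partition.assignment if isinstance(partition, Partition) else dict(partition)
    g = undirected_projection(graph)
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity fractions undefined for a graph with no edges")
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ValueError(f"partition does not cover {len(missing)} node(s), e.g. {missing[0]!r}")
    intra: dict[int, int] = defaultdict(int)
    cross = 0
    for u, v in g.edges():
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            intra[cu] += 1
        else:
            cross += 1
    degsum: dict[int, int] = defaultdict(int)
    for n, d in g.degree():
        degsum[assignment[n]] += d
    labels = set(assignment[n] for n in g.nodes)
    e = {i: intra.get(i, 0) / m for i in labels}
    a = {i: degsum.get(i, 0) / (2 * m) for i in labels}
    return e, a, cross / m


def modularity(graph: nx.Graph, partition: Partition | Mapping) -> float:
    """Newman modularity Q = sum_i (e_ii - a_i^2) on the undirected projection."""
    e, a, _ = edge_fractions(graph, partition)
    return sum(e[i] - a[i] ** 2 for i in e)


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

_GAIN_EPS = 1e-12  # strict-improvement threshold keeps moves deterministic


def _one_level(nodes: list, adj: dict, rng: random.Random, resolution: float,
               m2: float) -> tuple[dict, bool]:
    """One local-moving phase.  ``adj[v][v]`` holds 2x the self-loop weight."""
    comm = {v: i for i, v in enumerate(nodes)}
    deg = {v: sum(adj[v].values()) for v in nodes}
    comm_tot = {comm[v]: deg[v] for v in nodes}
    order = list(nodes)
    rng.shuffle(order)
    moved_any = False
    moved = True
    while moved:
        moved = False
        for v in order:
            c_old = comm[v]
            links = defaultdict(float)
            for u, w in adj[v].items():
                if u != v:
                    links[comm[u]] += w
            comm_tot[c_old] -= deg[v]
            best_c = c_old
            best_gain = links.get(c_old, 0.0) - resolution * comm_tot[c_old] * deg[v] / m2
            for c in sorted(links):
                if c == c_old:
                    continue
                gain = links[c] - resolution * comm_tot[c] * deg[v] / m2
                if gain > best_gain + _GAIN_EPS:
                    best_gain = gain
                    best_c = c
            comm[v] = best_c
            comm_tot[best_c] += deg[v]
            if best_c != c_old:
                moved = True
                moved_any = True
    return comm, moved_any


def _aggregate(nodes: list, adj: dict, comm: dict) -> tuple[list, dict, dict]:
    """Collapse communities into super-nodes; intra weight becomes a self-loop."""
    labels = sorted(set(comm.values()))
    relabel = {c: i for i, c in enumerate(labels)}
    new_nodes = list(range(len(labels)))
    new_adj: dict[int, dict[int, float]] = {i: defaultdict(float) for i in new_nodes}
    for v in nodes:
        cv = relabel[comm[v]]
        for u, w in adj[v].items():
            cu = relabel[comm[u]]
            if cu == cv:
                # both (v,u) and (u,v) pass through here, plus self-loops
                # already carrying 2x weight, so this sums to 2x intra weight
                new_adj[cv][cv] += w
            else:
                new_adj[cv][cu] += w
    mapping = {v: relabel[comm[v]] for v in nodes}
    return new_nodes, {i: dict(d) for i, d in new_adj.items()}, mapping


def _louvain(graph: nx.Graph, seed: int, resolution: float) -> dict:
    """Full two-phase Louvain on an undirected simple graph; returns node -> community."""
    rng = random.Random(seed)
    nodes = sorted(graph.nodes, key=str)
    adj: dict = {v: {} for v in nodes}
    for u, v in graph.edges():
        adj[u][v] = adj[u].get(v, 0.0) + 1.0
        adj[v][u] = adj[v].get(u, 0.0) + 1.0
    m2 = sum(sum(d.values()) for d in adj.values())  # = 2m, invariant across levels
    node_to_comm = {v: v for v in nodes}
    cur_nodes, cur_adj = nodes, adj
    while True:
        comm, moved = _one_level(cur_nodes, cur_adj, rng, resolution, m2)
        if not moved:
            break
        cur_nodes, cur_adj, mapping = _aggregate(cur_nodes, cur_adj, comm)
        node_to_comm = {v: mapping[c] for v, c in node_to_comm.items()}
        if len(cur_nodes) <= 1:
            break
    return node_to_comm


def louvain_cluster(graph: nx.Graph, seed: int, resolution: float = 1.0,
                    restarts: int = 1) -> Partition:
    """Cluster the graph's undirected projection with seeded Louvain.

    The returned partition is renumbered by descending cluster size
    (:func:`renumber_by_size`) and carries ``q_value``; with a fixed seed
    the output is bit-reproducible.  With ``restarts > 1`` the run with the
    highest Q wins (seeds ``seed, seed+1, ...``).  Graphs without edges get
    the singleton partition and ``q_value = 0.0`` by convention.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    und = undirected_projection(graph)
    if und.number_of_edges() == 0:
        assignment = {n: i + 1 for i, n in enumerate(sorted(und.nodes, key=str))}
        return renumber_by_size(Partition(assignment, q_value=0.0))
    best: Partition | None = None
    for r in range(max(1, restarts)):
        raw = _louvain(und, seed + r, resolution)
        part = Partition({n: c + 1 for n, c in _compact(raw).items()})
        q = modularity(und, part)
        part = replace(part, q_value=q)
        if best is None or q > best.q_value + _GAIN_EPS:
            best = part
    return renumber_by_size(best)


def _compact(assignment: Mapping) -> dict:
    labels = sorted(set(assignment.values()))
    relabel = {c: i for i, c in enumerate(labels)}
    return {n: relabel[c] for n, c in assignment.items()}


def renumber_by_size(partition: Partition) -> Partition:
    """Relabel clusters 1..K by descending size; ties go to the cluster
    containing the smallest member id (lexicographic)."""
    groups: dict[int, list] = defaultdict(list)
    for n, lab in partition.assignment.items():
        groups[lab].append(n)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(map(str, g))))
    assignment = {n: i + 1 for i, grp in enumerate(ordered) for n in grp}
    return Partition(assignment, q_value=partition.q_value)


# ---------------------------------------------------------------------------
# Import / export
# ---------------------------------------------------------------------------

def write_partition(partition: Partition, path: str | Path) -> None:
    """Partition export as TSV (id, cluster), sorted by id."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("id\tcluster\n")
        for n in sorted(partition.assignment, key=str):
            fh.write(f"{n}\t{partition.assignment[n]}\n")


def read_partition(path: str | Path) -> Partition:
    assignment: dict = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: missing partition header")
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln:
                n, lab = ln.split("\t")
                assignment[n] = int(lab)
    return Partition(assignment)


def write_node_table(graph: nx.Graph, path: str | Path) -> None:
    """Node table TSV (id, year)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("id\tyear\n")
        for n in sorted(graph.nodes, key=str):
            year = graph.nodes[n].get("year")
            fh.write(f"{n}\t{'' if year is None else year}\n")


def write_graphml(graph: nx.Graph, path: str | Path,
                  partition: Partition | None = None) -> None:
    """GraphML export for external visualization tools."""
    g = graph.copy()
    for n, data in g.nodes(data=True):
        if data.get("year") is None:
            data.pop("year", None)
        if partition is not None and n in partition.assignment:
            data["cluster"] = partition.assignment[n]
    nx.write_graphml(g, str(path))
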