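"""Yearly-snapshot re-clustering and key-article tracking.

The full pipeline (resolve citations -> largest weakly connected
component -> seeded Louvain -> renumber by size) is re-run on cumulative
snapshots (all articles published up to each year), and designated key
articles are followed through those re-clusterings: presence, cluster
label, within-cluster citation count and cluster size per year, plus
which key articles share a cluster (co-membership).

Cluster labels are *not* matched across years — each snapshot renumbers
its own clusters by size — so trends are read from co-membership groups
and citation counts, not from label identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .corpus import Corpus, resolve_citations
from .graph import Partition, build_graph, largest_component, louvain_cluster

__all__ = [
    "KeyArticleStatus",
    "KeyArticleTrack",
    "snapshot",
    "within_cluster_citations",
    "track_key_articles",
    "write_track",
]


def snapshot(corpus: Corpus, year: int) -> Corpus:
    """Sub-corpus of articles published in or before ``year``.

    Articles without a publication year are excluded from every snapshot;
    references are kept as-is (resolution later drops dangling ones).
    """
    articles = [a for a in corpus if a.year is not None and a.year <= year]
    prov = dict(corpus.provenance)
    prov.update({"snapshot_year": year, "n_articles": len(articles)})
    return Corpus(articles, prov)


def within_cluster_citations(graph: nx.DiGraph, partition: Partition, article_id: str) -> int:
    """Number of citing articles that share ``article_id``'s cluster."""
    if article_id not in graph:
        raise KeyError(f"article {article_id!r} not in graph")
    lab = partition.assignment.get(article_id)
    return sum(1 for p in graph.predecessors(article_id)
               if partition.assignment.get(p) == lab)


@dataclass(frozen=True)
class KeyArticleStatus:
    """One key article's record in one snapshot."""

    present: bool                    # in the snapshot corpus at all
    in_component: bool = False       # in the largest component that year
    cluster: int | None = None
    within_cluster_citations: int | None = None
    cluster_size: int | None = None


@dataclass
class KeyArticleTrack:
    """Key-article trajectories over snapshot years."""

    years: list[int]
    key_ids: list[str]
    status: dict[tuple[int, str], KeyArticleStatus]
    co_membership: dict[int, list[frozenset[str]]] = field(default_factory=dict)
    partitions: dict[int, Partition] = field(default_factory=dict)

    def co_members(self, year: int, a: str, b: str) -> bool:
        """Whether key articles a and b share a cluster in ``year``'s snapshot."""
        return any(a in grp and b in grp for grp in self.co_membership.get(year, []))


def track_key_articles(corpus: Corpus, key_ids: list[str], years: list[int],
                       seed: int, resolution: float = 1.0) -> KeyArticleTrack:
    """Run the snapshot pipeline for each year and record key-article status.

    One seed governs every snapshot's Louvain run.  A key article outside
    the snapshot corpus is marked not present ("not retrieved"); one in
    the corpus but outside that year's largest component has no cluster
    label.  Raises ``ValueError`` if no key id is ever present.
    """
    if not key_ids:
        raise ValueError("key_ids must be nonempty")
    if list(years) != sorted(years):
        raise ValueError("years must be ascending")
    track = KeyArticleTrack(years=list(years), key_ids=list(key_ids), status={})
    any_present = False
    for year in years:
        sub = snapshot(corpus, year)
        present_ids = {k for k in key_ids if k in sub}
        any_present = any_present or bool(present_ids)
        if len(sub) == 0:
            for k in key_ids:
                track.status[(year, k)] = KeyArticleStatus(present=False)
            track.co_membership[year] = []
            continue
        res = resolve_citations(sub)
        g = build_graph(sub, res.edges)
        comp = largest_component(g)
        part = louvain_cluster(comp, seed=seed, resolution=resolution)
        sizes = part.sizes()
        track.partitions[year] = part
        groups: dict[int, set[str]] = {}
        for k in key_ids:
            if k not in sub:
                track.status[(year, k)] = KeyArticleStatus(present=False)
                continue
            if k not in comp:
                track.status[(year, k)] = KeyArticleStatus(present=True, in_component=False)
                continue
            lab = part.assignment[k]
            track.status[(year, k)] = KeyArticleStatus(
                present=True, in_component=True, cluster=lab,
                within_cluster_citations=within_cluster_citations(comp, part, k),
                cluster_size=sizes[lab],
            )
            groups.setdefault(lab, set()).add(k)
        track.co_membership[year] = [frozenset(g) for _, g in sorted(groups.items())]
    if not any_present:
        raise ValueError("none of the key articles is present in any snapshot")
    return track


def write_track(track: KeyArticleTrack, path: str | Path,
                co_path: str | Path | None = None) -> None:
    """Long-format TSV export (year, key_id, present, cluster,
    within_cluster_citations, cluster_size) plus optional co-membership TSV
    (year, group, key ids)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("year\tkey_id\tpresent\tcluster\twithin_cluster_citations\tcluster_size\n")
        for year in track.years:
            for k in track.key_ids:
                s = track.status[(year, k)]
                fh.write("\t".join([
                    str(year), k, "1" if s.present else "0",
                    "" if s.cluster is None else str(s.cluster),
                    "" if s.within_cluster_citations is None else str(s.within_cluster_citations),
                    "" if s.cluster_size is None else str(s.cluster_size),
                ]) + "\n")
    if co_path is not None:
        with Path(co_path).open("w", encoding="utf-8") as fh:
            fh.write("year\tgroup\tkey_ids\n")
            for year in track.years:
                for gi, grp in enumerate(track.co_membership.get(year, []), start=1):
                    fh.write(f"{year}\t{gi}\t{'; '.join(sorted(grp))}\n")


def plot_track(track: KeyArticleTrack, path: str | Path) -> None:
    """Bubble-chart rendering of a track (year vs cluster, bubble area =
    within-cluster citations).  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 5))
    for k in track.key_ids:
        xs, ys, ss = [], [], []
        for year in track.years:
            s = track.status[(year, k)]
            if s.cluster is not None:
                xs.append(year)
                ys.append(s.cluster)
                ss.append(20 + 4 * (s.within_cluster_citations or 0))
        ax.scatter(xs, ys, s=ss, alpha=0.6, label=k)
    ax.set_xlabel("snapshot year")
    ax.set_ylabel("cluster number (per-year numbering)")
    ax.invert_yaxis()
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
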