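"""Sub-clustering, recency statistics and the emerging-topic filter.

Each large top-level cluster is re-clustered with the identical pipeline
(induced citation subgraph -> largest weakly connected component ->
seeded Louvain -> renumber by size), giving sub-clusters labeled
"parent-child" (e.g. "1-10").  A sub-cluster counts as an emerging-topic
candidate when it contains strictly more than ``min_size`` articles and
strictly more than ``min_recent`` of its dated members were published
inside the recency window (default: the trailing three years of the
corpus).  The final relevance judgment (e.g. "related to healthcare") is
a human step; the toolkit surfaces TFICF keywords and hub papers for it,
optionally pre-screened by a term allow-list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .corpus import Corpus
from .graph import Partition, largest_component, louvain_cluster
from .keywords import TermConfig, average_year, hub_paper, tficf_table, top_keywords

__all__ = [
    "SubClusterRecord",
    "subcluster",
    "recent_fraction",
    "filter_emerging",
    "select_parents",
    "build_subcluster_records",
    "cluster_summary",
    "markdown_table",
]


def subcluster(graph: nx.DiGraph, partition: Partition, parent: int,
               seed: int, resolution: float = 1.0, restarts: int = 1) -> Partition:
    """Re-cluster one top-level cluster's internal citation graph.

    The induced subgraph of the parent's members is restricted to its own
    largest weakly connected component before Louvain; members outside
    that component stay unassigned.  Child labels are 1..k by descending
    size.  Raises ``ValueError`` for parents of size < 2 or without any
    internal edge ("no sub-structure").
    """
    members = partition.members(parent)
    if len(members) < 2:
        raise ValueError(f"cluster {parent} has fewer than 2 members; cannot sub-cluster")
    sub = graph.subgraph(members).copy()
    if sub.number_of_edges() == 0:
        raise ValueError(f"cluster {parent} has no internal citation edges: no sub-structure")
    comp = largest_component(sub)
    return louvain_cluster(comp, seed=seed, resolution=resolution, restarts=restarts)


def recent_fraction(years: Iterable[int | None], window: tuple[int, int]) -> float | None:
    """Fraction of dated members published inside [start, end] (inclusive).

    Year-absent members are excluded from numerator and denominator; if
    no member has a known year the fraction is undefined (``None``).
    """
    start, end = window
    known = [y for y in years if y is not None]
    if not known:
        return None
    return sum(1 for y in known if start <= y <= end) / len(known)


@dataclass(frozen=True)
class SubClusterRecord:
    """One emerging-topic candidate."""

    parent: int
    child: int
    size: int
    recent_fraction: float | None
    window: tuple[int, int]
    average_year: float | None
    top_terms: tuple[str, ...]
    hub: str
    members: frozenset[str]

    @property
    def label(self) -> str:
        return f"{self.parent}-{self.child}"


def filter_emerging(records: Sequence[SubClusterRecord], min_size: int = 100,
                    min_recent: float = 0.40) -> list[SubClusterRecord]:
    """Keep sub-clusters with size > min_size AND recent_fraction > min_recent.

    Both thresholds are strict ("over 100 articles", "over 40%"); records
    with an undefined recent fraction are never retained.  Output is
    ordered by parent, then child label.
    """
    kept = [r for r in records
            if r.size > min_size
            and r.recent_fraction is not None
            and r.recent_fraction > min_recent]
    return sorted(kept, key=lambda r: (r.parent, r.child))


def select_parents(partition: Partition, share: float = 0.80) -> list[int]:
    """Smallest prefix 1..P of size-ordered clusters covering >= ``share``
    of all clustered articles."""
    if not 0 < share <= 1:
        raise ValueError("share must be in (0, 1]")
    sizes = partition.sizes()
    total = sum(sizes.values())
    parents: list[int] = []
    cum = 0
    for lab in sorted(sizes):
        parents.append(lab)
        cum += sizes[lab]
        if cum / total >= share:
            break
    return parents


def build_subcluster_records(corpus: Corpus, graph: nx.DiGraph, partition: Partition,
                             parents: Sequence[int], window: tuple[int, int], seed: int,
                             term_config: TermConfig = TermConfig(), k_terms: int = 10,
                             resolution: float = 1.0, restarts: int = 1
                             ) -> list[SubClusterRecord]:
    """Sub-cluster each parent and assemble candidate records.

    TFICF for sub-cluster keywords is computed within each parent (N = the
    parent's number of sub-clusters), so keywords discriminate between
    sibling sub-clusters.  Parents without internal sub-structure are
    skipped.
    """
    records: list[SubClusterRecord] = []
    for parent in parents:
        try:
            sub_part = subcluster(graph, partition, parent, seed=seed,
                                  resolution=resolution, restarts=restarts)
        except ValueError:
            continue
        sub_corpus = Corpus([corpus[i] for i in sorted(sub_part.assignment) if i in corpus],
                            {"parent": parent})
        table = tficf_table(sub_corpus, sub_part, term_config)
        sizes = sub_part.sizes()
        for child in sorted(sizes):
            members = frozenset(sub_part.members(child))
            years = [corpus[m].year for m in members if m in corpus]
            records.append(SubClusterRecord(
                parent=parent,
                child=child,
                size=sizes[child],
                recent_fraction=recent_fraction(years, window),
                window=window,
                average_year=average_year(sub_corpus, sub_part, child),
                top_terms=tuple(top_keywords(table, child, k_terms)),
                hub=hub_paper(graph, sub_part, child),
                members=members,
            ))
    return records


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def cluster_summary(corpus: Corpus, partition: Partition, graph: nx.DiGraph,
                    table, k_terms: int = 10) -> pd.DataFrame:
    """Table-style cluster summary: one row per cluster with label, size,
    average year (1 decimal), top-k TFICF keywords, hub paper id and title."""
    rows = []
    for lab in sorted(partition.sizes()):
        hub = hub_paper(graph, partition, lab)
        rows.append({
            "cluster": lab,
            "size": partition.sizes()[lab],
            "average_year": average_year(corpus, partition, lab),
            "top_keywords": ", ".join(top_keywords(table, lab, k_terms)),
            "hub_id": hub,
            "hub_title": corpus[hub].title if hub in corpus else "",
        })
    return pd.DataFrame(rows)


def subcluster_report(records: Sequence[SubClusterRecord]) -> pd.DataFrame:
    """Emerging-candidate report frame (recent fraction to 3 decimals)."""
    rows = [{
        "subcluster": r.label,
        "size": r.size,
        "recent_fraction": None if r.recent_fraction is None else round(r.recent_fraction, 3),
        "window": f"{r.window[0]}-{r.window[1]}",
        "average_year": r.average_year,
        "top_keywords": ", ".join(r.top_terms),
        "hub_id": r.hub,
    } for r in records]
    cols = ["subcluster", "size", "recent_fraction", "window", "average_year",
            "top_keywords", "hub_id"]
    return pd.DataFrame(rows, columns=cols)


def markdown_table(df: pd.DataFrame) -> str:
    """Minimal GitHub-style Markdown rendering of a frame."""
    cols = [str(c) for c in df.columns]

    def fmt(v) -> str:
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return ""
        return str(v)

    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def screen_by_terms(records: Sequence[SubClusterRecord],
                    allow_terms: Iterable[str]) -> list[SubClusterRecord]:
    """Optional relevance pre-screen: keep records whose top terms contain
    at least one allow-listed term (substring match, case-insensitive).
    This mechanizes only the lookup; the relevance judgment itself stays
    with the analyst."""
    allow = [t.lower() for t in allow_terms]
    out = []
    for r in records:
        joined = " ".join(r.top_terms).lower()
        if any(t in joined for t in allow):
            out.append(r)
    return out


def write_report(df: pd.DataFrame, tsv_path: str | Path,
                 md_path: str | Path | None = None) -> None:
    df.to_csv(tsv_path, sep="\t", index=False)
    if md_path is not None:
        Path(md_path).write_text(markdown_table(df), encoding="utf-8")
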