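"""Term extraction and TFICF cluster keywords.

TFICF (term frequency - inverse cluster frequency) is the cluster-level
analogue of TFIDF: for word j in cluster i,

    TFICF(i, j) = tf_ij * log(N / cf_j)

where tf_ij is the appearance ratio of word j among all words of cluster
i (pooled over the cluster's articles), N the number of clusters and cf_j
the number of clusters containing j at least once.  The log is the
natural log; any base only rescales every score by the same factor, so
rankings are base-independent.  A term appearing in every cluster scores
exactly zero, and with a single cluster all scores are zero.

Cluster characterization additionally uses the hub paper (the member most
cited by other members of the same cluster) and the average publication
year of members.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .corpus import Article, Corpus
from .graph import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "TermConfig",
    "TficfTable",
    "DEFAULT_STOPWORDS",
    "extract_terms",
    "tficf_table",
    "top_keywords",
    "hub_paper",
    "average_year",
    "load_stopwords",
]

# A compact English stopword list covering function words that dominate
# titles/abstracts; domain terms are never stopworded.
DEFAULT_STOPWORDS = frozenset("""
a about above after again against all also although among an and any are as at
be because been before being below between both but by can could did do does
doing down during each few for from further had has have having he her here
hers herself him himself his how i if in into is it its itself just me more
most my myself no nor not now of off on once only or other our ours ourselves
out over own same she should so some such than that the their theirs them
themselves then there these they this those through to too under until up upon
using very was we were what when where which while who whom why will with would
you your yours yourself yourselves
""".split())


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a plain-text stopword file, one term per line (# comments allowed)."""
    words = set()
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        ln = ln.strip().lower()
        if ln and not ln.startswith("#"):
            words.add(ln)
    return frozenset(words)


@dataclass(frozen=True)
class TermConfig:
    """Tokenization settings for term extraction.

    ``ngram_max`` n-grams (1-3) are emitted when neither end token is a
    stopword; author-keyword phrases always enter intact as single terms.
    ``min_term_count`` drops terms rarer than that across the whole corpus
    before any TFICF computation.
    """

    ngram_max: int = 2
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    lowercase: bool = True
    min_term_count: int = 1
    fields: tuple[str, ...] = ("title", "abstract", "keywords")

    def __post_init__(self) -> None:
        if self.ngram_max < 1:
            raise ValueError("ngram_max must be >= 1")
        if self.min_term_count < 1:
            raise ValueError("min_term_count must be >= 1")
        unknown = set(self.fields) - {"title", "abstract", "keywords"}
        if unknown:
            raise ValueError(f"unknown term fields: {sorted(unknown)}")


_TOKEN_RE = re.compile(r"[a-z0-9][a-z0-9'\-]*")


def _tokenize(text: str, lowercase: bool) -> list[str]:
    if lowercase:
        text = text.lower()
    return _TOKEN_RE.findall(text)


def extract_terms(article: Article, config: TermConfig = TermConfig()) -> Counter:
    """Term multiset of one article under the given configuration."""
    terms: Counter = Counter()
    for fld in ("title", "abstract"):
        if fld not in config.fields:
            continue
        tokens = _tokenize(getattr(article, fld), config.lowercase)
        for n in range(1, config.ngram_max + 1):
            for i in range(len(tokens) - n + 1):
                gram = tokens[i:i + n]
                if gram[0] in config.stopwords or gram[-1] in config.stopwords:
                    continue
                terms[" ".join(gram)] += 1
    if "keywords" in config.fields:
        for phrase in article.keywords:
            phrase = phrase.strip()
            if config.lowercase:
                phrase = phrase.lower()
            if phrase:
                terms[phrase] += 1
    return terms


@dataclass
class TficfTable:
    """Per-cluster term statistics: tf, cluster frequency cf and TFICF score."""

    tf: dict[int, dict[str, float]]
    cf: dict[str, int]
    n_clusters: int
    scores: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scores:
            self.scores = {
                i: {t: tf_ij * math.log(self.n_clusters / self.cf[t])
                    for t, tf_ij in row.items()}
                for i, row in self.tf.items()
            }

    @property
    def clusters(self) -> list[int]:
        return sorted(self.tf)

    def score(self, cluster: int, term: str) -> float:
        return self.scores[cluster].get(term, 0.0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: cluster, term, tf, cf, score."""
        rows = [
            (i, t, self.tf[i][t], self.cf[t], self.scores[i][t])
            for i in sorted(self.tf) for t in sorted(self.tf[i])
        ]
        return pd.DataFrame(rows, columns=["cluster", "term", "tf", "cf", "score"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def tficf_table(corpus: Corpus, partition: Partition,
                config: TermConfig = TermConfig()) -> TficfTable:
    """Compute the full TFICF table for a clustered corpus.

    tf is pooled over each cluster's term multiset (not averaged per
    article); terms with corpus-wide count below ``min_term_count`` are
    dropped before anything else is computed.
    """
    cluster_counts: dict[int, Counter] = defaultdict(Counter)
    corpus_counts: Counter = Counter()
    for art in corpus:
        lab = partition.assignment.get(art.id)
        if lab is None:
            continue
        terms = extract_terms(art, config)
        cluster_counts[lab].update(terms)
        corpus_counts.update(terms)
    labels = sorted(set(partition.assignment.values()))
    n_clusters = len(labels)
    if n_clusters < 1:
        raise ValueError("partition has no clusters")
    keep = {t for t, c in corpus_counts.items() if c >= config.min_term_count}
    tf: dict[int, dict[str, float]] = {}
    cf: Counter = Counter()
    for lab in labels:
        counts = {t: c for t, c in cluster_counts.get(lab, Counter()).items() if t in keep}
        total = sum(counts.values())
        if total == 0:
            logger.warning("cluster %s has no extracted terms; TFICF row is empty", lab)
            tf[lab] = {}
            continue
        tf[lab] = {t: c / total for t, c in counts.items()}
        for t in counts:
            cf[t] += 1
    return TficfTable(tf=tf, cf=dict(cf), n_clusters=n_clusters)


def top_keywords(table: TficfTable, cluster: int, k: int) -> list[str]:
    """The k highest-TFICF terms of one cluster.

    Ties on score break toward higher tf, then lexicographic term order.
    If the cluster vocabulary is smaller than k, all terms are returned.
    """
    if cluster not in table.tf:
        raise KeyError(f"cluster {cluster!r} not in TFICF table")
    row = table.scores[cluster]
    ranked = sorted(row, key=lambda t: (-row[t], -table.tf[cluster][t], t))
    return ranked[:k]


def hub_paper(graph, partition: Partition, cluster: int) -> str:
    """The cluster member most cited by members of the same cluster.

    Ties break toward the earlier publication year (unknown years sort
    last), then the smaller article id.
    """
    members = partition.members(cluster)
    if not members:
        raise ValueError(f"cluster {cluster!r} is empty")
    assignment = partition.assignment

    def in_cluster_citations(n) -> int:
        if n not in graph:
            return 0
        return sum(1 for p in graph.predecessors(n) if assignment.get(p) == cluster)

    def sort_key(n):
        year = graph.nodes[n].get("year") if n in graph else None
        return (-in_cluster_citations(n), year if year is not None else float("inf"), str(n))

    return min(members, key=sort_key)


def average_year(corpus: Corpus, partition: Partition, cluster: int) -> float | None:
    """Mean publication year of cluster members, to one decimal.

    Year-absent members are skipped; if no member has a year the average
    is undefined and ``None`` is returned.
    """
    members = partition.members(cluster)
    if not members:
        raise ValueError(f"cluster {cluster!r} is empty")
    years = [corpus[m].year for m in members if m in corpus and corpus[m].year is not None]
    if not years:
        return None
    return round(sum(years) / len(years), 1)
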