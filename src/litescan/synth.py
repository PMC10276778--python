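"""Synthetic bibliographic corpora with planted ground truth.

The generator emulates the statistical structure the pipeline analyzes:
time-ordered records, community-structured direct citations, community
vocabularies, and (optionally) a late-onset burst community whose
production rate jumps inside a recency window.

Model sketch
------------
Articles are created in year order (equal yearly volume across
``year_range``).  Each article draws a planted community from
``community_weights``; from the burst onset year the burst community's
weight is multiplied by its rate multiplier (weights renormalized).  Each
article then draws Poisson(``refs_per_article``) citations to strictly
earlier-year articles: with probability ``1 - mixing`` the target comes
from the article's own community pool, otherwise from all communities.
Within the eligible pool, targets are sampled uniformly or by
preferential attachment (weight ``1 + in-degree``), which produces the
hub papers real citation data has.  Because citations only point to
strictly earlier years, the graph is a DAG, as real citation networks
essentially are.

A burst community may be *nested* inside a host community
(``burst.host``): its members split their in-pool citations between the
burst itself (``burst.within_prob``) and the host's pool.  The resulting
burst-to-host citation mass glues the burst onto the host's top-level
cluster while the burst's internal citations keep it separable as a
sub-cluster — the structure the emerging-topic filter is designed to
find.  (A free-standing burst community would surface as its own
top-level cluster instead of as a sub-cluster.)

Titles and abstracts are term sequences from a Zipf-weighted background
vocabulary with each community's topic terms boosted, so TFICF keyword
recovery has ground truth too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Article, Corpus, ReferenceDescriptor

__all__ = [
    "BurstSpec",
    "SynthConfig",
    "GroundTruth",
    "generate_corpus",
    "planted_burst_stats",
    "merge_scenario",
    "write_ground_truth",
]


@dataclass(frozen=True)
class BurstSpec:
    """A community whose production rate jumps at ``onset_year``.

    With ``host`` set, the burst community is nested inside the host for
    citation purposes (see module docstring); ``within_prob`` is the
    probability that a burst member's in-pool citation stays inside the
    burst rather than going to the host pool, and ``host_coupling`` the
    probability that a host member's in-pool citation targets the burst
    (the parent field citing its rising subtopic).
    """

    community: int
    onset_year: int
    rate_multiplier: float = 3.0
    host: int | None = None
    within_prob: float = 0.45
    host_coupling: float = 0.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic corpus generator (see module docstring)."""

    n_articles: int = 2000
    year_range: tuple[int, int] = (2010, 2021)
    n_communities: int = 4
    community_weights: tuple[float, ...] | None = None
    mixing: float = 0.05
    refs_per_article: float = 6.0
    attachment: str = "preferential"
    vocab_size: int = 500
    topic_terms_per_community: int = 8
    topic_term_boost: float = 20.0
    zipf_exponent: float = 1.1
    title_len: int = 8
    abstract_len: int = 50
    n_keywords: int = 2
    burst: BurstSpec | None = None
    seed: int = 0

    def violations(self) -> list[str]:
        bad: list[str] = []
        if self.n_articles < 1:
            bad.append("n_articles must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            bad.append("year_range start must be <= end")
        if not (1900 <= self.year_range[0] and self.year_range[1] <= 2100):
            bad.append("year_range must lie in [1900, 2100]")
        if self.n_communities < 1:
            bad.append("n_communities must be >= 1")
        if self.community_weights is not None:
            w = self.community_weights
            if len(w) != self.n_communities:
                bad.append("community_weights length must equal n_communities")
            elif min(w) < 0 or abs(sum(w) - 1.0) > 1e-9:
                bad.append("community_weights must be nonnegative and sum to 1")
        if not 0 <= self.mixing <= 1:
            bad.append("mixing must be in [0, 1]")
        if self.refs_per_article < 0:
            bad.append("refs_per_article must be >= 0")
        if self.attachment not in ("uniform", "preferential"):
            bad.append("attachment must be 'uniform' or 'preferential'")
        if self.vocab_size < 1:
            bad.append("vocab_size must be >= 1")
        if self.zipf_exponent <= 0:
            bad.append("zipf_exponent must be > 0")
        if self.burst is not None:
            b = self.burst
            if not 0 <= b.community < self.n_communities:
                bad.append("burst.community out of range")
            if not self.year_range[0] <= b.onset_year <= self.year_range[1]:
                bad.append("burst.onset_year outside year_range")
            if b.rate_multiplier <= 0:
                bad.append("burst.rate_multiplier must be > 0")
            if b.host is not None and (not 0 <= b.host < self.n_communities
                                       or b.host == b.community):
                bad.append("burst.host must be a different valid community")
            if not 0 <= b.within_prob <= 1:
                bad.append("burst.within_prob must be in [0, 1]")
            if not 0 <= b.host_coupling <= 1:
                bad.append("burst.host_coupling must be in [0, 1]")
        return bad

    def validate(self) -> None:
        bad = self.violations()
        if bad:
            raise ValueError("invalid SynthConfig: " + "; ".join(bad))


@dataclass
class GroundTruth:
    """Planted labels of a synthetic corpus."""

    community: dict[str, int]
    burst_members: set[str] = field(default_factory=set)


def _vocab(config: SynthConfig) -> tuple[list[str], np.ndarray, list[list[str]]]:
    """Vocabulary, per-community sampling distributions, topic-term lists."""
    bg = [f"term{r:04d}" for r in range(1, config.vocab_size + 1)]
    topic: list[list[str]] = [
        [f"topic{c:02d}term{t:02d}" for t in range(config.topic_terms_per_community)]
        for c in range(config.n_communities)
    ]
    vocab = bg + [t for terms in topic for t in terms]
    w_bg = np.arange(1, config.vocab_size + 1, dtype=float) ** (-config.zipf_exponent)
    w_topic_each = config.topic_term_boost * w_bg.mean()
    dists = np.zeros((config.n_communities, len(vocab)))
    for c in range(config.n_communities):
        w = np.zeros(len(vocab))
        w[:config.vocab_size] = w_bg
        start = config.vocab_size + c * config.topic_terms_per_community
        w[start:start + config.topic_terms_per_community] = w_topic_each
        dists[c] = w / w.sum()
    return vocab, dists, topic


def generate_corpus(config: SynthConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its ground truth; fully reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_articles
    y0, y1 = config.year_range
    n_years = y1 - y0 + 1
    years = np.array([y0 + (i * n_years) // n for i in range(n)])

    base_w = np.asarray(config.community_weights if config.community_weights is not None
                        else [1.0 / config.n_communities] * config.n_communities)
    communities = np.empty(n, dtype=int)
    for i in range(n):
        w = base_w.copy()
        if config.burst is not None and years[i] >= config.burst.onset_year:
            w[config.burst.community] *= config.burst.rate_multiplier
        w = w / w.sum()
        communities[i] = rng.choice(config.n_communities, p=w)

    vocab, dists, topic_terms = _vocab(config)
    vocab_idx = np.arange(len(vocab))

    burst = config.burst
    nested = burst is not None and burst.host is not None

    indeg = np.zeros(n)
    # pools of strictly-earlier articles, refreshed at year boundaries
    pool_all = np.empty(0, dtype=int)
    pool_comm = [np.empty(0, dtype=int) for _ in range(config.n_communities)]
    pending: list[int] = []  # current-year articles, not yet citable
    cur_year = years[0]

    def draw(pool: np.ndarray, count: int) -> np.ndarray:
        if pool.size == 0 or count == 0:
            return np.empty(0, dtype=int)
        if config.attachment == "preferential":
            w = 1.0 + indeg[pool]
            p = w / w.sum()
            return rng.choice(pool, size=count, replace=True, p=p)
        return rng.choice(pool, size=count, replace=True)

    articles: list[Article] = []
    truth = GroundTruth(community={})
    for i in range(n):
        if years[i] != cur_year:
            flushed = np.array(pending, dtype=int)
            pool_all = np.concatenate([pool_all, flushed])
            for c in range(config.n_communities):
                members = flushed[communities[flushed] == c]
                pool_comm[c] = np.concatenate([pool_comm[c], members])
            pending = []
            cur_year = years[i]
        c = int(communities[i])
        k = rng.poisson(config.refs_per_article)
        targets: set[int] = set()
        for _ in range(k):
            if rng.random() < config.mixing:
                pool = pool_all
            elif nested and c == burst.community:
                if rng.random() < burst.within_prob:
                    pool = pool_comm[burst.community]
                else:
                    pool = pool_comm[burst.host]
            elif nested and c == burst.host and rng.random() < burst.host_coupling:
                pool = pool_comm[burst.community]
            else:
                pool = pool_comm[c]
            if pool.size == 0:
                continue
            # reference lists cite distinct works: redraw a few times on collision
            for _attempt in range(4):
                t = int(draw(pool, 1)[0])
                if t not in targets:
                    targets.add(t)
                    indeg[t] += 1
                    break
        art_id = f"A{i:05d}"
        tokens = rng.choice(vocab_idx, size=config.title_len + config.abstract_len,
                            p=dists[c])
        words = [vocab[j] for j in tokens]
        kw = list(rng.choice(topic_terms[c],
                             size=min(config.n_keywords, len(topic_terms[c])),
                             replace=False)) if topic_terms[c] else []
        articles.append(Article(
            id=art_id,
            year=int(years[i]),
            title=" ".join(words[:config.title_len]),
            abstract=" ".join(words[config.title_len:]),
            keywords=kw,
            refs=[ReferenceDescriptor(raw=f"A{t:05d}") for t in sorted(targets)],
        ))
        truth.community[art_id] = c
        if burst is not None and c == burst.community:
            truth.burst_members.add(art_id)
        pending.append(i)

    corpus = Corpus(articles, {"source": "synthetic", "format": "generic",
                               "seed": config.seed, "n_articles": n})
    return corpus, truth


def planted_burst_stats(corpus: Corpus, truth: GroundTruth,
                        window: tuple[int, int]) -> dict[int, dict[str, float]]:
    """Exact per-planted-community size and recent fraction (filter oracle)."""
    start, end = window
    stats: dict[int, dict[str, float]] = {}
    by_comm: dict[int, list[int]] = {}
    for art in corpus:
        c = truth.community[art.id]
        by_comm.setdefault(c, []).append(art.year)
    for c, years in sorted(by_comm.items()):
        known = [y for y in years if y is not None]
        recent = sum(1 for y in known if start <= y <= end)
        stats[c] = {
            "size": float(len(years)),
            "recent_fraction": recent / len(known) if known else float("nan"),
        }
    return stats


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth TSV (id, community, is_burst)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("id\tcommunity\tis_burst\n")
        for art_id in sorted(truth.community):
            fh.write(f"{art_id}\t{truth.community[art_id]}\t"
                     f"{1 if art_id in truth.burst_members else 0}\n")


def burst_scenario(seed: int) -> tuple[SynthConfig, tuple[int, int]]:
    """Reference configuration of the planted-burst study: a 2,000-article
    corpus over 2012-2021 with three mature communities and one burst
    community (10% base arrival share) nested in the largest, whose
    production rate triples over the trailing three years.

    Reference lists are long (mean 10) as in recent, review-heavy fields;
    the within-burst citation share of 0.45 reflects a young subfield that
    still draws nearly half its references from its parent literature —
    and keeps the burst attached to the host's top-level cluster while
    remaining separable as a sub-cluster.  Returns the config and the
    recency window.
    """
    cfg = SynthConfig(
        seed=seed, n_communities=4, year_range=(2012, 2021),
        refs_per_article=10.0, community_weights=(0.30, 0.31, 0.29, 0.10),
        burst=BurstSpec(community=3, onset_year=2019, rate_multiplier=3.0,
                        host=0, within_prob=0.45),
    )
    return cfg, (2019, 2021)


# ---------------------------------------------------------------------------
# Merge scenario for temporal tracking
# ---------------------------------------------------------------------------

def merge_scenario(seed: int, pre_years: tuple[int, int] = (2000, 2012),
                   post_years: tuple[int, int] = (2013, 2020),
                   n_pre_per_year: int = 12, n_post_per_year: int = 80,
                   refs_pre: float = 4.0, refs_post_extra: float = 2.0,
                   cross_prob: float = 0.05) -> tuple[Corpus, str, str, int]:
    """Two planted communities that merge via bridge citations.

    Before the merge year, two communities ("X", "Y") publish nearly in
    isolation, citing within themselves (preferential attachment, so the
    founding article of each community becomes its hub) with only a
    ``cross_prob`` trickle of cross-community citations — enough to keep
    one weakly connected component without blurring the clusters.  From the
    merge year on, every new "bridge" article cites *both* founding hub
    articles plus a small preferential sample of all earlier work — the
    literature stops respecting the old boundary, and the jointly-cited
    hubs end up in one cluster.  The extra sample is kept small
    (``refs_post_extra``) so the bridge literature stays star-shaped
    around the two hubs; dense bridge-internal citation would let the
    bridge cohort fragment into sub-communities that can pull the two
    hubs apart in intermediate years.

    Returns ``(corpus, key_x, key_y, merge_year)`` where the key ids are
    the two founding hubs and ``merge_year`` is the first bridge year.
    """
    rng = np.random.default_rng(seed)
    articles: list[Article] = []
    indeg: dict[str, int] = {}
    by_year_ids: list[str] = []       # citable (strictly earlier years)
    comm_ids: dict[str, list[str]] = {"X": [], "Y": []}
    pending: list[tuple[str, str]] = []
    counter = 0

    def flush() -> None:
        for art_id, comm in pending:
            by_year_ids.append(art_id)
            if comm in comm_ids:
                comm_ids[comm].append(art_id)
        pending.clear()

    def pref_draw(pool: list[str], k: int) -> list[str]:
        if not pool or k == 0:
            return []
        w = np.array([1.0 + indeg[p] for p in pool])
        return list(rng.choice(pool, size=k, replace=True, p=w / w.sum()))

    def add(comm: str, year: int, refs: list[str]) -> str:
        nonlocal counter
        art_id = f"{comm}{counter:05d}"
        counter += 1
        uniq = sorted(set(refs))
        for r in uniq:
            indeg[r] += 1
        articles.append(Article(
            id=art_id, year=year,
            title=f"{comm.lower()} community study {counter}",
            abstract="",
            keywords=[f"topic-{comm.lower()}"],
            refs=[ReferenceDescriptor(raw=r) for r in uniq],
        ))
        indeg[art_id] = 0
        pending.append((art_id, comm))
        return art_id

    key: dict[str, str] = {}
    for year in range(pre_years[0], pre_years[1] + 1):
        for j in range(n_pre_per_year):
            for comm in ("X", "Y"):
                other = "Y" if comm == "X" else "X"
                k = int(rng.poisson(refs_pre))
                refs: list[str] = []
                for _ in range(k):
                    pool = comm_ids[other] if rng.random() < cross_prob else comm_ids[comm]
                    refs += pref_draw(pool, 1)
                art_id = add(comm, year, refs)
                if comm not in key:
                    key[comm] = art_id
        flush()

    merge_year = post_years[0]
    for year in range(post_years[0], post_years[1] + 1):
        for j in range(n_post_per_year):
            k = int(rng.poisson(refs_post_extra))
            refs = [key["X"], key["Y"]] + pref_draw(by_year_ids, k)
            add("C", year, refs)
        flush()

    corpus = Corpus(articles, {"source": "synthetic-merge", "format": "generic",
                               "seed": seed})
    return corpus, key["X"], key["Y"], merge_year
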