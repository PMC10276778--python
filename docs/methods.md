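# Methods

This note documents the models, conventions and design choices behind
`litescan`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Citation graph and resolution

Records become nodes of a directed graph with edges citing → cited.
Cited-reference strings (the Web of Science `CR` dialect stores
references as free text, not record ids) are resolved in strict priority
order: exact id match, then normalized DOI (lowercased, URL/label
prefixes stripped), then the (first-author surname, year, source) triple
when it matches **exactly one** record. Ambiguous triples and duplicate
DOIs produce no edge: for downstream clustering, a missing edge is noise
but a wrong edge is structure, so resolution favors precision over
recall. Unresolved references are counted, not errors — a corpus
retrieved by a topical query never contains all cited work.
Self-citations are dropped and duplicate pairs collapsed; the edge list
is sorted, so resolution is independent of record order. Duplicate
record ids keep the first occurrence, making parses order-stable.

## Connectivity and modularity conventions

"Largest network" means the largest **weakly** connected component:
citation graphs are (near-)DAGs, and any direction-sensitive notion of
connectivity would shatter them into fragments. Ties on component size
go to the component containing the lexicographically smallest id.

Modularity and Louvain operate on the undirected simple projection
(antiparallel edge pairs collapse to one link); direction is kept only
for counting citations (hub papers, within-cluster citation counts).
Q = Σᵢ(eᵢᵢ − aᵢ²) in the standard undirected form; the identities
Σᵢ eᵢᵢ + (cross fraction) = 1 and Σᵢ aᵢ = 1 are asserted in tests to
1e-12, and the implementation is cross-checked against networkx's
modularity on random graph/partition pairs. Q is undefined for edgeless
graphs; cluster reports use the convention q = 0 there to avoid a
special error path.

## Louvain

The clustering is the greedy two-phase Louvain heuristic: local moving
to strict positive modularity gain (threshold 1e-12), then aggregation,
repeated to convergence, at resolution 1 by default. Node visit order is
shuffled by a caller-supplied seed; all other iteration orders are
sorted and ties break toward the lowest community id, so a fixed seed
yields a bit-identical partition. Optional restarts (seeds s, s+1, …)
keep the highest-Q run. Clusters are renumbered 1..K by descending size,
ties to the cluster containing the smallest member id. On small graphs
the result is checked against brute-force enumeration of all partitions
(Louvain's Q never exceeds the true maximum, and attains it on
two-clique fixtures); on planted-partition corpora recovery is checked
by NMI. Louvain is a local-optimum heuristic: partitions of real corpora
are seed-sensitive in the fine structure even though Q is stable.

## TFICF

TFICF(i, j) = tf_ij · ln(N / cf_j): tf_ij is term j's share of cluster
i's pooled term multiset (pooled, not per-article-averaged, so long
abstracts weigh more — matching the "share of all words in the cluster"
reading); cf_j is the number of clusters containing j; N the number of
clusters. The log base is the natural log: any base rescales all scores
by one constant and leaves rankings unchanged. Consequences worth
knowing: a term present in every cluster scores exactly 0 everywhere,
and with a single cluster all scores are 0. Terms rarer than
`min_term_count` corpus-wide are dropped before anything is computed.

Tokenization is a deliberately plain regex tokenizer: lowercased
alphanumeric tokens, n-grams up to `ngram_max` (default 2) that do not
start or end with a stopword (a built-in ~130-word English function-word
list; replaceable by file). Author-keyword phrases always enter intact
as single terms, so multi-word domain keywords can surface without
phrase mining. No stemming or lemmatization: for ranking within a
homogeneous scientific corpus, inflectional collapse buys little and
costs transparency.

## Hub papers, years, recency

The hub paper of a cluster is the member with the most citations **from
members of the same cluster** (not global citation count); ties break to
the earlier year, then the smaller id. Average year is the mean over
members with a known year, reported to one decimal; a cluster with no
dated members reports it as missing. The recent fraction of a member set
is (members in the window) / (members with a known year); undated
members are excluded from both sides, and a set with no dated members
has an undefined fraction which the emerging filter never retains.

## Temporal tracking

Snapshots are cumulative (all articles with year ≤ y; undated articles
appear in no snapshot) and each snapshot re-runs the full pipeline —
re-resolution, re-restriction to its own largest component, re-clustered
with the **same seed**. Cluster labels are not matched across years:
each year renumbers by size, so trends are read from co-membership
groups and citation counts rather than label identity. This avoids an
alignment heuristic whose failure modes would be invisible in the
output.

## Emerging-topic detection

Parents for sub-clustering are the minimal size-ordered prefix of
clusters covering a configurable cumulative share (default 0.80) of
clustered articles — a corpus-independent generalization of "the
clusters that contain 80% or more of the articles". Each parent's
induced citation subgraph is restricted to its own largest weak
component (the identical pipeline applied recursively) and re-clustered;
children are labeled `parent-child` by descending size. The filter keeps
sub-clusters with size **strictly greater than** `min_size` (default
100) and recent fraction **strictly greater than** `min_recent` (default
0.40) over the window, default the trailing three corpus years
(end−2 … end): three years is long enough for stable sub-cluster
extraction and short enough that recent growth still separates
candidates. Both thresholds and the window are configurable because they
are empirical choices, not constants of nature. The final
relevance judgment (e.g. "is this healthcare-related?") is explicitly
human; `screen_by_terms` only mechanizes an allow-list lookup over the
reported keywords.

## Synthetic corpus generator

The generator emulates the statistical structure the pipeline consumes:
time-ordered records (equal yearly volume over `year_range`), a planted
community per article (categorical draw from `community_weights`),
Poisson(`refs_per_article`) citations per article to strictly
earlier-year articles — own community with probability 1 − `mixing`,
any community otherwise — sampled uniformly or by preferential
attachment (weight 1 + in-degree, which produces realistic hub papers).
Within an article, reference targets are drawn distinct (up to three
redraws on collision), as real reference lists are. Citations never
point forward in time, so the graph is a DAG, as in real citation data.
Text is sampled from a Zipf(1.1) background vocabulary with each
community's topic terms boosted (`topic_term_boost` × the mean
background weight); keywords are drawn from the community's topic terms.
Everything is reproducible byte-for-byte from the config seed.

**Burst community.** A burst multiplies one community's arrival weight
by `rate_multiplier` from `onset_year`. For the burst to be findable by
the *sub-cluster* filter it must live **inside** a top-level cluster, so
a burst may be nested in a `host` community: burst members split their
in-community citations between the burst itself (`within_prob`) and the
host's pool. The reference configuration (`burst_scenario`) was sized
analytically rather than by trial: merging burst into host is the
modularity optimum when the burst→host citation mass exceeds
≈ 2aₕ/(1−aₕ) times the burst-internal mass (≈ 0.86 at the host's ~0.3
degree share), giving `within_prob` = 0.45; and individual members stay
attached to the burst sub-cluster only when they carry ≥ 3 unique
internal links, giving mean reference-list length 10. A `host_coupling`
knob (host citing into the burst) exists but defaults to 0: preferential
host→burst citation concentrates on burst hubs and blurs the sub-cluster
boundary.

**Merge scenario.** Two communities publish in near-isolation (a 5%
cross-citation trickle keeps one weak component); from the merge year
every new "bridge" article cites both founding hub articles plus a
small preferential sample of older work. The bridge literature is kept
star-shaped around the two hubs (mean 2 extra references): denser
bridge-internal citation lets the bridge cohort fragment into
sub-communities that can pull the two hubs apart in intermediate years.

**What the benchmarks do not show.** The generator has no reference-
string noise (synthetic references are exact ids, so WoS-style string
resolution is exercised only by unit fixtures), no author or journal
structure, no retractions or errata, and equal yearly volume outside the
burst. Passing the planted-structure benchmarks shows the pipeline
recovers the structure it is designed to find under clean conditions; it
does not bound performance on real corpora, where community boundaries
are soft and resolution errors correlate with field conventions.

## Benchmark problem sizes

Planted-community recovery uses 2,000-article corpora (4 communities,
mixing 0.05, mean 6 references) over five seeds; the burst benchmark
uses the 2,000-article `burst_scenario`; the merge benchmark tracks two
hubs over ~950 articles and 9 snapshots. These sizes put Louvain well
past its small-graph noise regime while keeping the full suite fast
enough to run routinely.

## Numerical and degenerate-input conventions

Strict-gain threshold 1e-12 in Louvain (float-noise moves would break
determinism); oracle comparisons at 1e-12; single-node and edgeless
graphs cluster to singletons with q = 0; empty clusters and unknown
labels raise; a cluster with no extracted terms gets an empty TFICF row
and a warning rather than an error. Reports contain no timestamps, so
byte-identical reruns are a testable contract.
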