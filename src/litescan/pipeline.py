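"""End-to-end orchestration: parse -> resolve -> component -> Louvain ->
TFICF -> reports, plus the emerging-topic pass, with YAML configuration
and machine-readable run logs.

All randomness flows from the single config seed.  Outputs carry no
timestamps, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import emerging as em
from .corpus import (Corpus, ParseError, parse_generic_corpus, parse_wos_export,
                     resolve_citations, write_edge_list)
from .graph import (Partition, build_graph, largest_component, louvain_cluster,
                    write_node_table, write_partition)
from .keywords import DEFAULT_STOPWORDS, TermConfig, load_stopwords, tficf_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "DataError", "run_pipeline", "run_emerging"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class DataError(ValueError):
    """Input data cannot be processed."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str
    seed: int
    output_dir: str
    input_format: str = "generic"          # "generic" | "wos"
    resolution: float = 1.0
    restarts: int = 1
    # term extraction
    ngram_max: int = 2
    min_term_count: int = 1
    stopword_file: str | None = None
    term_fields: tuple[str, ...] = ("title", "abstract", "keywords")
    k_terms: int = 10
    # emerging-topic pass
    parent_share: float = 0.80
    min_size: int = 100
    min_recent: float = 0.40
    window: tuple[int, int] | None = None  # default: trailing 3 corpus years
    allow_terms: tuple[str, ...] = ()
    # temporal tracking
    snapshot_years: tuple[int, ...] = ()
    key_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.input_format not in ("generic", "wos"):
            raise ConfigError(f"unknown input_format {self.input_format!r}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed is required and must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        for key in ("window", "snapshot_years", "key_ids", "term_fields", "allow_terms"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def term_config(self) -> TermConfig:
        stop = (load_stopwords(self.stopword_file) if self.stopword_file
                else DEFAULT_STOPWORDS)
        return TermConfig(ngram_max=self.ngram_max, stopwords=stop,
                          min_term_count=self.min_term_count,
                          fields=tuple(self.term_fields))


def _load_corpus(config: RunConfig) -> Corpus:
    path = Path(config.input_path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    try:
        if config.input_format == "wos":
            return parse_wos_export(path)
        return parse_generic_corpus(path)
    except ParseError as exc:
        raise DataError(str(exc)) from exc


def _jsonable(obj):
    if isinstance(obj, (tuple, set)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def run_pipeline(config: RunConfig) -> Path:
    """Execute the one-shot analysis and write all artifacts to the run dir.

    Artifacts: ``corpus.jsonl`` is *not* rewritten (the input is the
    corpus of record); the run dir contains ``edges.tsv``, ``nodes.tsv``,
    ``partition.tsv``, ``tficf.tsv``, ``summary.tsv``/``summary.md`` and
    ``run_log.json`` with parameters and per-stage counts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": _jsonable(asdict(config)), "stages": {}}

    corpus = _load_corpus(config)
    log["stages"]["parse"] = dict(corpus.provenance)
    if len(corpus) == 0:
        raise DataError("corpus is empty")

    res = resolve_citations(corpus)
    log["stages"]["resolve"] = {
        "n_refs": res.n_refs, "n_edges": len(res.edges),
        "by_id": res.n_resolved_by_id, "by_doi": res.n_resolved_by_doi,
        "by_triple": res.n_resolved_by_triple, "ambiguous": res.n_ambiguous,
        "unresolved": res.n_unresolved, "self_dropped": res.n_self_dropped,
    }

    graph = build_graph(corpus, res.edges)
    comp = largest_component(graph)
    log["stages"]["component"] = {
        "n_nodes": graph.number_of_nodes(),
        "component_size": comp.number_of_nodes(),
        "component_fraction": comp.number_of_nodes() / graph.number_of_nodes(),
    }

    partition = louvain_cluster(comp, seed=config.seed, resolution=config.resolution,
                                restarts=config.restarts)
    log["stages"]["cluster"] = {"n_clusters": len(partition),
                                "q_value": partition.q_value}

    comp_corpus = Corpus([corpus[i] for i in sorted(partition.assignment)],
                         {"source": "largest-component"})
    table = tficf_table(comp_corpus, partition, config.term_config())
    summary = em.cluster_summary(comp_corpus, partition, comp, table,
                                 k_terms=config.k_terms)

    write_edge_list(res.edges, out / "edges.tsv")
    write_node_table(graph, out / "nodes.tsv")
    write_partition(partition, out / "partition.tsv")
    table.write_tsv(out / "tficf.tsv")
    em.write_report(summary, out / "summary.tsv", out / "summary.md")
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n",
                                      encoding="utf-8")
    return out


def run_emerging(config: RunConfig, run_dir: str | Path | None = None) -> Path:
    """Emerging-topic pass over a completed :func:`run_pipeline` output.

    Parents are the size-ordered clusters covering ``parent_share`` of
    clustered articles; each is re-clustered and the size/recency filter
    applied.  Writes ``emerging.tsv``/``emerging.md``/``subclusters.tsv``
    and ``emerging_log.json`` to the run dir.
    """
    from .corpus import read_edge_list
    from .graph import read_partition

    out = Path(run_dir) if run_dir is not None else Path(config.output_dir)
    for name in ("partition.tsv", "edges.tsv"):
        if not (out / name).exists():
            raise DataError(f"missing upstream artifact {out / name}; run the pipeline first")
    corpus = _load_corpus(config)
    edges = read_edge_list(out / "edges.tsv")
    partition = read_partition(out / "partition.tsv")
    graph = build_graph(corpus, edges)

    years = [a.year for a in corpus if a.year is not None]
    if not years:
        raise DataError("no publication years in corpus; recency window undefined")
    window = tuple(config.window) if config.window else (max(years) - 2, max(years))

    parents = em.select_parents(partition, share=config.parent_share)
    records = em.build_subcluster_records(
        corpus, graph, partition, parents, window, seed=config.seed,
        term_config=config.term_config(), k_terms=config.k_terms,
        resolution=config.resolution)
    kept = em.filter_emerging(records, min_size=config.min_size,
                              min_recent=config.min_recent)
    if config.allow_terms:
        kept = em.screen_by_terms(kept, config.allow_terms)
    if not kept:
        logger.info("no sub-cluster passed the emerging filter "
                    "(size > %d and recent fraction > %.2f in %s)",
                    config.min_size, config.min_recent, window)

    em.write_report(em.subcluster_report(records), out / "subclusters.tsv")
    em.write_report(em.subcluster_report(kept), out / "emerging.tsv",
                    out / "emerging.md")
    log = {
        "config": _jsonable(asdict(config)),
        "window": list(window),
        "parents": parents,
        "n_subclusters": len(records),
        "n_emerging": len(kept),
        "emerging_labels": [r.label for r in kept],
    }
    (out / "emerging_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n",
                                           encoding="utf-8")
    return out
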