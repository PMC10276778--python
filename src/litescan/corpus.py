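"""Bibliographic corpus I/O and citation-edge resolution.

Two on-disk dialects are supported:

* the Web of Science Core Collection tab-delimited export ("savedrecs"
  style): one header row of two-letter field tags, one record per row,
  multi-valued cells joined by ``"; "``.  Cited references arrive as
  free-text strings ("Smith J, 2009, BIOMATERIALS, DOI 10.1/x") and are
  kept verbatim in :class:`ReferenceDescriptor.raw`;
* a generic JSON Lines format (one record per line with keys ``id``,
  ``year``, ``title``, ``abstract``, ``keywords``, ``refs``) in which
  references are already article ids.  This is the interchange format the
  synthetic generator writes and the tests use.

:func:`resolve_citations` turns reference descriptors into a clean set of
directed (citing, cited) article-id pairs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "Article",
    "Corpus",
    "ReferenceDescriptor",
    "ResolutionResult",
    "ParseError",
    "normalize_doi",
    "parse_wos_export",
    "parse_generic_corpus",
    "write_generic_corpus",
    "resolve_citations",
    "write_edge_list",
    "read_edge_list",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed as a corpus."""


_DOI_PREFIXES = ("https://doi.org/", "http://doi.org/", "http://dx.doi.org/",
                 "doi:", "doi ")


def normalize_doi(doi: str | None) -> str | None:
    """Lowercase a DOI and strip common URL/label prefixes."""
    if doi is None:
        return None
    d = doi.strip().lower()
    changed = True
    while changed:
        changed = False
        for prefix in _DOI_PREFIXES:
            if d.startswith(prefix):
                d = d[len(prefix):].strip()
                changed = True
    return d or None


@dataclass(frozen=True)
class ReferenceDescriptor:
    """One cited-reference entry of an article.

    ``raw`` preserves the input string byte-for-byte; the remaining fields
    are whatever could be parsed out of it (or, for the generic format,
    nothing — ``raw`` is already an article id).
    """

    raw: str
    doi: str | None = None
    first_author: str | None = None
    year: int | None = None
    source: str | None = None


@dataclass
class Article:
    """One bibliographic record."""

    id: str
    year: int | None = None
    title: str = ""
    abstract: str = ""
    keywords: list[str] = field(default_factory=list)
    doi: str | None = None
    first_author: str | None = None
    source: str | None = None
    refs: list[ReferenceDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Article id must be nonempty")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise ValueError(f"Article {self.id}: year {self.year} outside [1900, 2100]")


@dataclass
class Corpus:
    """An ordered, id-unique collection of articles plus parse statistics."""

    articles: list[Article]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.id for a in self.articles]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate article ids in Corpus")
        self._by_id = {a.id: a for a in self.articles}

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self) -> Iterator[Article]:
        return iter(self.articles)

    def __contains__(self, article_id: str) -> bool:
        return article_id in self._by_id

    def __getitem__(self, article_id: str) -> Article:
        return self._by_id[article_id]

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.articles]

    def years(self) -> dict[str, int | None]:
        return {a.id: a.year for a in self.articles}


# ---------------------------------------------------------------------------
# Web of Science tab-delimited export
# ---------------------------------------------------------------------------

#: field tags of the WoS Core Collection export dialect
_WOS_ID = "UT"
_WOS_YEAR = "PY"
_WOS_TITLE = "TI"
_WOS_ABSTRACT = "AB"
_WOS_KEYWORDS = "DE"
_WOS_REFS = "CR"
_WOS_DOI = "DI"
_WOS_AUTHORS = "AU"
_WOS_SOURCE = "SO"

_WOS_SEP = "; "

_YEAR_RE = re.compile(r"^(1[89]|20|21)\d\d$")


def _parse_year(cell: str) -> int | None:
    cell = cell.strip()
    if _YEAR_RE.match(cell):
        return int(cell)
    return None


def _parse_cr_string(raw: str) -> ReferenceDescriptor:
    """Parse one WoS cited-reference string.

    The dialect is loosely "First Author, Year, Source, Volume, Page, DOI":
    comma-separated, with the author first, a 4-digit year, the source title
    after the year, and an optional trailing "DOI ..." element.
    """
    parts = [p.strip() for p in raw.split(",")]
    doi = None
    year = None
    year_idx = None
    first_author = None
    source = None
    for i, p in enumerate(parts):
        if p.upper().startswith("DOI ") or p.upper().startswith("DOI:"):
            doi = normalize_doi(p[4:] if p[3] in " :" else p)
        elif year is None and _YEAR_RE.match(p):
            year = int(p)
            year_idx = i
    if parts and parts[0] and not _YEAR_RE.match(parts[0]):
        first_author = parts[0]
    if year_idx is not None and year_idx + 1 < len(parts):
        nxt = parts[year_idx + 1]
        if nxt and not nxt.upper().startswith("DOI"):
            source = nxt
    return ReferenceDescriptor(raw=raw, doi=doi, first_author=first_author,
                               year=year, source=source)


def parse_wos_export(path: str | Path) -> Corpus:
    """Parse a Web of Science tab-delimited export file into a :class:`Corpus`.

    Rows without the unique-id (``UT``) cell are skipped and counted;
    duplicate ids keep the first occurrence; an unparseable publication year
    leaves ``year`` absent with a logged warning.  Raises
    :class:`ParseError` if the header row or the ``UT``/``PY`` columns are
    missing.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8-sig", errors="replace")
    lines = [ln for ln in text.splitlines() if ln.strip("\x00 \t")]
    if not lines:
        raise ParseError(f"{path}: empty file, no header row")
    header = lines[0].rstrip("\n").split("\t")
    tags = [h.strip() for h in header]
    if _WOS_ID not in tags:
        raise ParseError(f"{path}: header has no unique-id column ({_WOS_ID})")
    if _WOS_YEAR not in tags:
        raise ParseError(f"{path}: header has no publication-year column ({_WOS_YEAR})")
    col = {tag: i for i, tag in enumerate(tags)}

    def cell(row: list[str], tag: str) -> str:
        i = col.get(tag)
        if i is None or i >= len(row):
            return ""
        return row[i].strip()

    articles: list[Article] = []
    seen: set[str] = set()
    n_skipped_no_id = 0
    n_duplicates = 0
    n_bad_year = 0
    for ln in lines[1:]:
        row = ln.split("\t")
        uid = cell(row, _WOS_ID)
        if not uid:
            n_skipped_no_id += 1
            continue
        if uid in seen:
            n_duplicates += 1
            continue
        seen.add(uid)
        year_cell = cell(row, _WOS_YEAR)
        year = _parse_year(year_cell)
        if year is None and year_cell:
            n_bad_year += 1
            logger.warning("%s: article %s has malformed year %r; year left absent",
                           path.name, uid, year_cell)
        kw_cell = cell(row, _WOS_KEYWORDS)
        keywords = [k.strip() for k in kw_cell.split(_WOS_SEP) if k.strip()] if kw_cell else []
        cr_cell = cell(row, _WOS_REFS)
        refs = [_parse_cr_string(r) for r in cr_cell.split(_WOS_SEP) if r.strip()] if cr_cell else []
        au_cell = cell(row, _WOS_AUTHORS)
        first_author = au_cell.split(_WOS_SEP)[0].strip() or None if au_cell else None
        articles.append(Article(
            id=uid,
            year=year,
            title=cell(row, _WOS_TITLE),
            abstract=cell(row, _WOS_ABSTRACT),
            keywords=keywords,
            doi=normalize_doi(cell(row, _WOS_DOI) or None),
            first_author=first_author,
            source=cell(row, _WOS_SOURCE) or None,
            refs=refs,
        ))
    provenance = {
        "source": str(path),
        "format": "wos",
        "n_rows": len(lines) - 1,
        "n_articles": len(articles),
        "skipped_no_id": n_skipped_no_id,
        "duplicates_dropped": n_duplicates,
        "malformed_years": n_bad_year,
    }
    return Corpus(articles, provenance)


# ---------------------------------------------------------------------------
# Generic JSON Lines corpus
# ---------------------------------------------------------------------------

def _ref_from_json(obj) -> ReferenceDescriptor:
    if isinstance(obj, str):
        return ReferenceDescriptor(raw=obj)
    return ReferenceDescriptor(
        raw=obj["raw"],
        doi=obj.get("doi"),
        first_author=obj.get("first_author"),
        year=obj.get("year"),
        source=obj.get("source"),
    )


def _ref_to_json(ref: ReferenceDescriptor):
    if ref.doi is None and ref.first_author is None and ref.year is None and ref.source is None:
        return ref.raw
    d = asdict(ref)
    return {k: v for k, v in d.items() if v is not None}


def parse_generic_corpus(path: str | Path) -> Corpus:
    """Parse the generic JSON Lines corpus format.

    Each nonempty line is a JSON object with keys ``id``, ``year``,
    ``title``, ``abstract``, ``keywords``, ``refs`` (cited ids or reference
    objects) and optionally ``doi``, ``first_author``, ``source``.  An
    unparseable line raises :class:`ParseError` naming the line number;
    an empty file yields an empty corpus.
    """
    path = Path(path)
    articles: list[Article] = []
    seen: set[str] = set()
    n_duplicates = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                art = Article(
                    id=obj["id"],
                    year=obj.get("year"),
                    title=obj.get("title", ""),
                    abstract=obj.get("abstract", ""),
                    keywords=list(obj.get("keywords", [])),
                    doi=obj.get("doi"),
                    first_author=obj.get("first_author"),
                    source=obj.get("source"),
                    refs=[_ref_from_json(r) for r in obj.get("refs", [])],
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: unparseable record: {exc}") from exc
            if art.id in seen:
                n_duplicates += 1
                continue
            seen.add(art.id)
            articles.append(art)
    provenance = {
        "source": str(path),
        "format": "generic",
        "n_articles": len(articles),
        "duplicates_dropped": n_duplicates,
    }
    return Corpus(articles, provenance)


def write_generic_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the generic JSON Lines format (stable key order)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for a in corpus:
            obj = {"id": a.id, "year": a.year, "title": a.title,
                   "abstract": a.abstract, "keywords": a.keywords,
                   "refs": [_ref_to_json(r) for r in a.refs]}
            if a.doi is not None:
                obj["doi"] = a.doi
            if a.first_author is not None:
                obj["first_author"] = a.first_author
            if a.source is not None:
                obj["source"] = a.source
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Citation resolution
# ---------------------------------------------------------------------------

@dataclass
class ResolutionResult:
    """Resolved citation edges plus resolution statistics."""

    edges: list[tuple[str, str]]
    n_refs: int = 0
    n_resolved_by_id: int = 0
    n_resolved_by_doi: int = 0
    n_resolved_by_triple: int = 0
    n_ambiguous: int = 0
    n_unresolved: int = 0
    n_self_dropped: int = 0
    n_duplicate_pairs: int = 0

    def __iter__(self):
        return iter(self.edges)

    def __len__(self):
        return len(self.edges)


def _surname(name: str | None) -> str | None:
    if not name:
        return None
    head = name.split(",")[0].strip()
    head = head.split()[0] if head.split() else head
    return head.lower() or None


def resolve_citations(corpus: Corpus) -> ResolutionResult:
    """Resolve every reference descriptor to a (citing, cited) id pair.

    A reference matches an in-corpus article by, in priority order:

    1. ``raw`` equal to an article id;
    2. normalized DOI equal to an article's DOI (unique in the corpus);
    3. the (first-author surname, year, source) triple matching exactly one
       article (case-insensitive surname/source); an ambiguous triple
       produces no edge and increments ``n_ambiguous``.

    Self-citations are dropped and duplicate pairs collapsed; the returned
    edge list is sorted, so the result is independent of article order.
    """
    doi_index: dict[str, list[str]] = {}
    triple_index: dict[tuple, list[str]] = {}
    for a in corpus:
        if a.doi:
            doi_index.setdefault(normalize_doi(a.doi), []).append(a.id)
        surname = _surname(a.first_author)
        if surname and a.year is not None and a.source:
            triple_index.setdefault((surname, a.year, a.source.lower()), []).append(a.id)

    res = ResolutionResult(edges=[])
    pairs: set[tuple[str, str]] = set()
    for a in corpus:
        for ref in a.refs:
            res.n_refs += 1
            target: str | None = None
            if ref.raw in corpus:
                target = ref.raw
                res.n_resolved_by_id += 1
            elif ref.doi and normalize_doi(ref.doi) in doi_index:
                hits = doi_index[normalize_doi(ref.doi)]
                if len(hits) == 1:
                    target = hits[0]
                    res.n_resolved_by_doi += 1
                else:
                    res.n_ambiguous += 1
                    continue
            else:
                surname = _surname(ref.first_author)
                key = (surname, ref.year, ref.source.lower() if ref.source else None)
                hits = triple_index.get(key, []) if all(k is not None for k in key) else []
                if len(hits) == 1:
                    target = hits[0]
                    res.n_resolved_by_triple += 1
                elif len(hits) > 1:
                    res.n_ambiguous += 1
                    continue
                else:
                    res.n_unresolved += 1
                    continue
            if target == a.id:
                res.n_self_dropped += 1
                continue
            pair = (a.id, target)
            if pair in pairs:
                res.n_duplicate_pairs += 1
            else:
                pairs.add(pair)
    res.edges = sorted(pairs)
    return res


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write citation edges as a 2-column TSV (citing_id, cited_id)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("citing_id\tcited_id\n")
        for citing, cited in sorted(set(edges)):
            fh.write(f"{citing}\t{cited}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if header and not header.startswith("citing_id"):
            raise ParseError(f"{path}: missing edge-list header")
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln:
                continue
            citing, cited = ln.split("\t")
            edges.append((citing, cited))
    return edges
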