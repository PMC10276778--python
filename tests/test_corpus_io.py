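"""Corpus parsing (WoS export and generic JSON Lines) and citation resolution."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from litescan.corpus import (Article, Corpus, ParseError, ReferenceDescriptor,
                             normalize_doi, parse_generic_corpus,
                             parse_wos_export, resolve_citations,
                             write_generic_corpus, write_edge_list,
                             read_edge_list)

WOS_HEADER = "UT\tPY\tTI\tDE\tAB\tCR\tDI\tAU\tSO"


def wos_file(tmp_path, rows, header=WOS_HEADER):
    path = tmp_path / "savedrecs.txt"
    path.write_text("\n".join([header] + rows) + "\n", encoding="utf-8")
    return path


class TestParseWos:
    def test_two_rows_with_reference_strings(self, tmp_path):
        rows = [
            "WOS:1\t2015\tOrgan printing\tbioprinting; scaffold\tAn abstract.\t"
            "Smith J, 2009, BIOMATERIALS, DOI 10.1/x; Lee K, 2003, TRENDS BIOTECH\t"
            "10.99/aa\tDoe, J\tBIOFABRICATION",
            "WOS:2\t2016\tSecond paper\t\t\t\t\t\t",
        ]
        corpus = parse_wos_export(wos_file(tmp_path, rows))
        assert len(corpus) == 2
        a = corpus["WOS:1"]
        assert a.year == 2015
        assert a.keywords == ["bioprinting", "scaffold"]
        assert [r.raw for r in a.refs] == [
            "Smith J, 2009, BIOMATERIALS, DOI 10.1/x",
            "Lee K, 2003, TRENDS BIOTECH",
        ]
        first = a.refs[0]
        assert (first.first_author, first.year, first.source, first.doi) == \
            ("Smith J", 2009, "BIOMATERIALS", "10.1/x")

    def test_malformed_year_kept_with_year_absent(self, tmp_path):
        corpus = parse_wos_export(wos_file(
            tmp_path, ["WOS:1\tn.d.\tTitle\t\t\t\t\t\t"]))
        assert corpus["WOS:1"].year is None
        assert corpus.provenance["malformed_years"] == 1

    def test_duplicate_ids_first_wins(self, tmp_path):
        rows = ["WOS:1\t2010\tfirst\t\t\t\t\t\t",
                "WOS:1\t2011\tsecond\t\t\t\t\t\t"]
        corpus = parse_wos_export(wos_file(tmp_path, rows))
        assert len(corpus) == 1
        assert corpus["WOS:1"].title == "first"
        assert corpus.provenance["duplicates_dropped"] == 1

    def test_row_without_id_skipped_and_counted(self, tmp_path):
        corpus = parse_wos_export(wos_file(
            tmp_path, ["\t2010\tno id\t\t\t\t\t\t", "WOS:9\t2011\tok\t\t\t\t\t\t"]))
        assert corpus.ids == ["WOS:9"]
        assert corpus.provenance["skipped_no_id"] == 1

    @pytest.mark.parametrize("header", ["PY\tTI", "UT\tTI"])
    def test_missing_required_column_is_hard_error(self, tmp_path, header):
        with pytest.raises(ParseError, match="savedrecs"):
            parse_wos_export(wos_file(tmp_path, ["x\ty"], header=header))

    def test_utf8_bom_tolerated(self, tmp_path):
        path = tmp_path / "bom.txt"
        path.write_bytes("﻿UT\tPY\nWOS:1\t2010\n".encode("utf-8"))
        corpus = parse_wos_export(path)
        assert corpus.ids == ["WOS:1"]


class TestGenericCorpus:
    def test_three_lines(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(
            '{"id": "a", "year": 2010, "title": "t", "abstract": "", '
            '"keywords": [], "refs": []}\n'
            '{"id": "b", "year": 2011, "title": "", "abstract": "", '
            '"keywords": ["k"], "refs": ["a"]}\n'
            '{"id": "c", "year": 2012, "title": "", "abstract": "", '
            '"keywords": [], "refs": ["a", "zzz-not-here"]}\n')
        corpus = parse_generic_corpus(path)
        assert len(corpus) == 3
        # dangling reference ids parse fine; resolution is a later stage
        assert [r.raw for r in corpus["c"].refs] == ["a", "zzz-not-here"]

    def test_empty_file_gives_empty_corpus(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert len(parse_generic_corpus(path)) == 0

    def test_bad_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"id": "a", "year": 2010, "refs": []}\nnot json\n')
        with pytest.raises(ParseError, match=":2:"):
            parse_generic_corpus(path)

    def test_round_trip_preserves_articles(self, tmp_path):
        arts = [
            Article(id="x1", year=2001, title="Títle ünicode", abstract="A b c.",
                    keywords=["k one", "k two"], doi="10.5/x",
                    first_author="Roe, R", source="J THING",
                    refs=[ReferenceDescriptor(raw="x2"),
                          ReferenceDescriptor(raw="Smith J, 1999, J X, DOI 10.1/z",
                                              doi="10.1/z", first_author="Smith J",
                                              year=1999, source="J X")]),
            Article(id="x2", year=None, title="", abstract="", keywords=[]),
        ]
        corpus = Corpus(arts, {})
        path = tmp_path / "rt.jsonl"
        write_generic_corpus(corpus, path)
        back = parse_generic_corpus(path)
        assert back.articles == arts

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(
        st.builds(
            Article,
            id=st.uuids().map(str),
            year=st.one_of(st.none(), st.integers(1900, 2100)),
            title=st.text(max_size=30),
            abstract=st.text(max_size=30),
            keywords=st.lists(st.text(min_size=1, max_size=10), max_size=3),
            refs=st.lists(st.builds(ReferenceDescriptor,
                                    raw=st.text(min_size=1, max_size=15)),
                          max_size=3),
        ),
        max_size=5, unique_by=lambda a: a.id))
    def test_round_trip_property(self, tmp_path_factory, articles):
        path = tmp_path_factory.mktemp("rt") / "c.jsonl"
        write_generic_corpus(Corpus(articles, {}), path)
        assert parse_generic_corpus(path).articles == articles


class TestResolveCitations:
    def art(self, i, refs=(), **kw):
        return Article(id=i, refs=list(refs), **kw)

    def test_resolution_by_id_doi_then_triple(self):
        corpus = Corpus([
            self.art("A", year=2009, doi="10.1/x", first_author="Smith, J",
                     source="BIOMATERIALS"),
            self.art("B", refs=[ReferenceDescriptor(raw="A")], year=2015),
            self.art("C", refs=[ReferenceDescriptor(raw="ref str", doi="DOI 10.1/X")],
                     year=2016),
            self.art("D", refs=[ReferenceDescriptor(raw="r", first_author="Smith J",
                                                    year=2009, source="Biomaterials")],
                     year=2017),
        ], {})
        res = resolve_citations(corpus)
        assert res.edges == [("B", "A"), ("C", "A"), ("D", "A")]
        assert (res.n_resolved_by_id, res.n_resolved_by_doi, res.n_resolved_by_triple) \
            == (1, 1, 1)

    def test_ambiguous_triple_gives_no_edge(self):
        twin = dict(year=2009, first_author="Smith, J", source="J X")
        corpus = Corpus([
            self.art("A1", **twin), self.art("A2", **twin),
            self.art("B", refs=[ReferenceDescriptor(raw="r", first_author="Smith J",
                                                    year=2009, source="J X")]),
        ], {})
        res = resolve_citations(corpus)
        assert res.edges == []
        assert res.n_ambiguous == 1

    def test_self_citation_dropped(self):
        corpus = Corpus([self.art("A", refs=[ReferenceDescriptor(raw="A")])], {})
        res = resolve_citations(corpus)
        assert res.edges == []
        assert res.n_self_dropped == 1

    def test_duplicate_pairs_collapse(self):
        corpus = Corpus([
            self.art("A"),
            self.art("B", refs=[ReferenceDescriptor(raw="A"),
                                ReferenceDescriptor(raw="A")]),
        ], {})
        res = resolve_citations(corpus)
        assert res.edges == [("B", "A")]
        assert res.n_duplicate_pairs == 1

    def test_edge_count_bounded_by_reference_count(self, tiny_corpus):
        res = resolve_citations(tiny_corpus)
        assert len(res.edges) <= res.n_refs
        assert len(set(res.edges)) == len(res.edges)
        assert all(u != v for u, v in res.edges)

    def test_resolution_independent_of_article_order(self, tiny_corpus):
        reversed_corpus = Corpus(list(reversed(tiny_corpus.articles)), {})
        assert resolve_citations(tiny_corpus).edges == \
            resolve_citations(reversed_corpus).edges


def test_doi_normalization_variants():
    for raw in ("10.1/A", "https://doi.org/10.1/a", "DOI 10.1/a", "doi:10.1/a"):
        assert normalize_doi(raw) == "10.1/a"
    assert normalize_doi(None) is None


def test_edge_list_round_trip(tmp_path):
    edges = [("b", "a"), ("c", "a")]
    path = tmp_path / "edges.tsv"
    write_edge_list(edges, path)
    assert read_edge_list(path) == sorted(edges)
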