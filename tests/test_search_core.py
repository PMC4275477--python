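"""Indexing, scoring, ranked retrieval, facets."""

import pytest

from medlingua import (
    CitationRecord,
    MeshAnnotation,
    SearchConfig,
    StructuredQuery,
    build_index,
    interpret_query,
    refine_facet,
    score_citation,
    search,
)
from medlingua.query_engine import ConceptTerm, normalize_text


def _first_planted(store, relevance_key):
    query = sorted(relevance_key)[0]
    ui = next(
        ui for ui, d in store.descriptors.items() if d.labels["fre"] == query
    )
    return query, ui


def test_empty_corpus_returns_nothing(store):
    index = build_index([], store, "fre")
    q = StructuredQuery(word_terms=["anything"], tokens=["anything"],
                        raw_text="anything")
    assert search(q, index, "semantic").total_hits == 0
    assert search(q, index, "title_only").total_hits == 0
    assert search(q, index, "all_fields").total_hits == 0


def test_title_postings_match_linear_scan(fre_index):
    """Posting sizes equal a brute-force token scan over all records."""
    for field in ("title", "transliterated_title", "abstract"):
        oracle: dict[str, set[str]] = {}
        for pmid, record in fre_index.records.items():
            for token in set(normalize_text(getattr(record, field) or "", "fre")):
                oracle.setdefault(token, set()).add(pmid)
        postings = {t: s for t, s in fre_index.word_postings[field].items() if s}
        assert postings == oracle


def test_concept_postings_cover_every_annotation(fre_index):
    for pmid, record in fre_index.records.items():
        for annotation in record.annotations:
            posting = fre_index.concept_postings[annotation.descriptor_ui]
            assert annotation in posting[pmid]


def test_major_flag_preserved_in_postings(fre_index):
    majors = [
        (pmid, a)
        for pmid, record in fre_index.records.items()
        for a in record.annotations
        if a.major
    ]
    assert majors, "fixture corpus should contain major topics"
    pmid, annotation = majors[0]
    assert annotation in fre_index.concept_postings[annotation.descriptor_ui][pmid]


def test_unknown_annotation_strict_vs_lenient(store, caplog):
    record = CitationRecord(
        pmid="77", title="t", languages=["fre"], pub_year=2000,
        annotations=[MeshAnnotation("D999999")],
    )
    with pytest.raises(ValueError, match="D999999"):
        build_index([record], store, "fre", strict=True)
    with caplog.at_level("WARNING"):
        index = build_index([record], store, "fre", strict=False)
    assert "D999999" not in index.concept_postings


class TestScoring:
    """Hand-computed credit-table checks on a two-record micro corpus."""

    @pytest.fixture()
    def micro(self, store):
        ui = sorted(store.descriptors)[0]
        label_fr = store.descriptors[ui].labels["fre"]
        records = [
            CitationRecord(
                pmid="1", title="x", transliterated_title=label_fr,
                languages=["fre"], pub_year=2010,
                annotations=[MeshAnnotation(ui, major=True)],
            ),
            CitationRecord(
                pmid="2", title="autre chose", abstract=f"blah {label_fr} blah",
                languages=["fre"], pub_year=2012,
                annotations=[MeshAnnotation(ui, major=False)],
            ),
            CitationRecord(
                pmid="3", title="y", transliterated_title=label_fr,
                languages=["fre"], pub_year=2011,
                annotations=[MeshAnnotation(ui, major=True, origin="automatic")],
            ),
        ]
        return ui, label_fr, build_index(records, store, "fre")

    def test_perfect_title_and_major_scores_100(self, micro, store):
        ui, label_fr, index = micro
        q = interpret_query(label_fr, "fre", store)
        assert score_citation(q, index.records["1"], index) == 100.0

    def test_minor_topic_only_scores_70(self, micro, store):
        ui, label_fr, index = micro
        q = StructuredQuery(
            concept_terms=[ConceptTerm(ui=ui, kind="descriptor")],
            tokens=[], raw_text=label_fr,
        )
        assert score_citation(q, index.records["2"], index) == pytest.approx(70.0)

    def test_automatic_origin_damps_concept_credit(self, micro, store):
        ui, label_fr, index = micro
        q = StructuredQuery(
            concept_terms=[ConceptTerm(ui=ui, kind="descriptor")],
            tokens=[], raw_text=label_fr,
        )
        # major but automatic: 1.0 * 0.8 -> 80
        assert score_citation(q, index.records["3"], index) == pytest.approx(80.0)

    def test_title_plus_abstract_word_mix_scores_75(self, store):
        records = [
            CitationRecord(
                pmid="1", title="alpha autre", abstract="contient beta ici",
                languages=["fre"], pub_year=2000,
            )
        ]
        index = build_index(records, store, "fre")
        q = StructuredQuery(word_terms=["alpha", "beta"],
                            tokens=["alpha", "beta"], raw_text="alpha beta")
        # title word 1.0 + abstract-only word 0.5 over 2 terms -> 75
        assert score_citation(q, index.records["1"], index) == pytest.approx(75.0)


class TestSearch:
    def test_semantic_retrieves_all_planted(self, fre_index, store, relevance_key):
        query, ui = _first_planted(store, relevance_key)
        q = interpret_query(query, "fre", store)
        result = search(q, fre_index, "semantic", "relevance", k=20)
        assert {p for p, _ in result.all_hits} == set(relevance_key[query])

    def test_title_only_retrieves_title_evidence_subset(
        self, fre_index, store, relevance_key
    ):
        query, ui = _first_planted(store, relevance_key)
        q = interpret_query(query, "fre", store)
        result = search(q, fre_index, "title_only", "lifo", k=20)
        title_evidence = {
            p for p, info in relevance_key[query].items()
            if info["evidence"] == "title"
        }
        assert {p for p, _ in result.all_hits} == title_evidence

    def test_abstract_only_term_invisible_to_title_only(self, store):
        records = [
            CitationRecord(pmid="1", title="autre", transliterated_title="autre",
                           abstract="cible ici", languages=["fre"], pub_year=2001)
        ]
        index = build_index(records, store, "fre")
        q = StructuredQuery(word_terms=["cible"], tokens=["cible"], raw_text="cible")
        assert search(q, index, "semantic").total_hits == 1
        assert search(q, index, "title_only").total_hits == 0

    def test_equal_scores_break_by_recency(self, store):
        records = [
            CitationRecord(pmid="10", title="cible", languages=["fre"], pub_year=2010),
            CitationRecord(pmid="11", title="cible", languages=["fre"], pub_year=2013),
        ]
        index = build_index(records, store, "fre")
        q = StructuredQuery(word_terms=["cible"], tokens=["cible"], raw_text="cible")
        result = search(q, index, "semantic", "relevance")
        assert result.pmids == ["11", "10"]

    def test_lifo_equals_sort_oracle(self, fre_index, store, relevance_key):
        query, _ = _first_planted(store, relevance_key)
        q = interpret_query(query, "fre", store)
        result = search(q, fre_index, "semantic", "lifo", k=500)
        oracle = sorted(
            (p for p, _ in result.all_hits),
            key=lambda p: (-fre_index.records[p].pub_year, -int(p)),
        )
        assert [p for p, _ in result.all_hits] == oracle

    def test_relevance_and_lifo_same_match_set(self, fre_index, store, relevance_key):
        for query in sorted(relevance_key):
            q = interpret_query(query, "fre", store)
            rel = search(q, fre_index, "semantic", "relevance")
            lifo = search(q, fre_index, "semantic", "lifo")
            assert rel.total_hits == lifo.total_hits
            assert {p for p, _ in rel.all_hits} == {p for p, _ in lifo.all_hits}

    def test_scores_non_increasing_under_relevance(self, fre_index, store, relevance_key):
        query, _ = _first_planted(store, relevance_key)
        q = interpret_query(query, "fre", store)
        scores = [s for _, s in search(q, fre_index, "semantic", "relevance").all_hits]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert all(0 <= s <= 100 for s in scores)

    def test_adding_a_term_never_adds_matches(self, fre_index, store, relevance_key):
        """AND semantics monotonicity."""
        query, _ = _first_planted(store, relevance_key)
        q1 = interpret_query(query, "fre", store)
        q2 = interpret_query(query + " xyzzy", "fre", store)
        hits1 = {p for p, _ in search(q1, fre_index, "semantic").all_hits}
        hits2 = {p for p, _ in search(q2, fre_index, "semantic").all_hits}
        assert hits2 <= hits1

    def test_all_fields_misses_elided_and_accented_queries(self, store):
        """The case-fold-only emulation loses exactly the French queries the
        normalizing engine handles (elision, diacritics)."""
        records = [
            CitationRecord(pmid="1", title="x", transliterated_title="Angine grave",
                           languages=["fre"], pub_year=2000),
            CitationRecord(pmid="2", title="x", transliterated_title="Maladie cœliaque",
                           languages=["fre"], pub_year=2001),
        ]
        index = build_index(records, store, "fre")
        q_elision = interpret_query("l'angine", "fre", store)
        q_elision.raw_text = "l'angine"
        assert search(q_elision, index, "semantic").total_hits == 1
        assert search(q_elision, index, "all_fields").total_hits == 0
        q_accent = interpret_query("maladie coeliaque", "fre", store)
        q_accent.raw_text = "maladie coeliaque"
        assert search(q_accent, index, "semantic").total_hits == 1
        assert search(q_accent, index, "all_fields").total_hits == 0

    def test_explode_widens_semantic_match(self, store):
        parent = next(
            ui for ui, d in store.descriptors.items()
            if len(store.explode(ui)) > 1
        )
        child = next(ui for ui in store.explode(parent) if ui != parent)
        records = [
            CitationRecord(pmid="1", title="a", languages=["fre"], pub_year=2000,
                           annotations=[MeshAnnotation(child, major=True)])
        ]
        index = build_index(records, store, "fre")
        q = StructuredQuery(
            concept_terms=[ConceptTerm(ui=parent, kind="descriptor")],
            tokens=[], raw_text="",
        )
        assert search(q, index, "semantic").total_hits == 1
        off = SearchConfig(explode=False)
        assert search(q, index, "semantic", config=off).total_hits == 0

    def test_unknown_strategy_or_ranking(self, fre_index):
        q = StructuredQuery(word_terms=["x"], tokens=["x"], raw_text="x")
        with pytest.raises(ValueError):
            search(q, fre_index, "bogus")
        with pytest.raises(ValueError):
            search(q, fre_index, "semantic", "fifo")


class TestFacets:
    @pytest.fixture()
    def result(self, fre_index, store, relevance_key):
        query, _ = _first_planted(store, relevance_key)
        q = interpret_query(query, "fre", store)
        return q, search(q, fre_index, "semantic", "relevance", k=20)

    def test_refine_by_year(self, result, fre_index):
        _, res = result
        years = {fre_index.records[p].pub_year for p, _ in res.all_hits}
        year = sorted(years)[0]
        refined = refine_facet(res, fre_index, "year", year)
        assert refined.total_hits == sum(
            1 for p, _ in res.all_hits if fre_index.records[p].pub_year == year
        )
        assert all(fre_index.records[p].pub_year == year for p, _ in refined.all_hits)

    def test_absent_value_empty(self, result, fre_index):
        _, res = result
        refined = refine_facet(res, fre_index, "country", "Atlantis")
        assert refined.total_hits == 0 and refined.hits == []

    def test_refinements_commute(self, result, fre_index):
        _, res = result
        year = fre_index.records[res.all_hits[0][0]].pub_year
        country = fre_index.records[res.all_hits[0][0]].journal_country
        ab = refine_facet(refine_facet(res, fre_index, "year", year),
                          fre_index, "country", country)
        ba = refine_facet(refine_facet(res, fre_index, "country", country),
                          fre_index, "year", year)
        assert ab.all_hits == ba.all_hits and ab.total_hits == ba.total_hits

    def test_order_preserved(self, result, fre_index):
        _, res = result
        year = fre_index.records[res.all_hits[0][0]].pub_year
        refined = refine_facet(res, fre_index, "year", year)
        original_order = [p for p, _ in res.all_hits
                          if fre_index.records[p].pub_year == year]
        assert [p for p, _ in refined.all_hits] == original_order

    def test_unknown_facet(self, result, fre_index):
        _, res = result
        with pytest.raises(ValueError):
            refine_facet(res, fre_index, "color", "blue")
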