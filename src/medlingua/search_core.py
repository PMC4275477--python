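"""Inverted-index retrieval over a monolingual citation subset.

Implements the three search strategies compared in the evaluation harness:

``semantic``
    the terminology-aware engine — concept terms hit the MeSH annotations
    (with optional hierarchy explosion) or their own label tokens in the
    title, residual word terms hit a configurable field set; queries are
    normalized (diacritics, elision) before indexing and matching;
``title_only``
    a free-text search restricted to the original-language (transliterated)
    title, emulating a PubMed ``[TT]`` field query;
``all_fields``
    a PubMed ``[All Fields]`` emulation: tokens across every field plus the
    labels of annotated concepts, but *case folding only* — no diacritic
    stripping, no elision handling — because that weaker normalization is
    precisely what costs PubMed coverage on French queries.

Two rankings are available: ``relevance`` (score, then year, then PMID, all
descending) and ``lifo`` (year then PMID descending — the classic PubMed
last-in-first-out proxy).  Both rankings always return the same boolean match
set and hence the same total-hits count.

Relevance scores live on a 0–100 scale.  A query whose every term is found
in the title or as a human-assigned major topic scores exactly 100; weaker
evidence earns partial credit per term (minor topic 0.7, abstract-only word
0.5, automatic-origin annotations damped by 0.8) — the credit table is
configurable.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .medline_io import CitationRecord
from .query_engine import ConceptTerm, StructuredQuery, normalize_text

__all__ = [
    "ScoringConfig",
    "SearchConfig",
    "SubsetIndex",
    "SearchResult",
    "build_index",
    "score_citation",
    "search",
    "refine_facet",
    "STRATEGIES",
    "RANKINGS",
    "FACETS",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("semantic", "title_only", "all_fields")
RANKINGS = ("relevance", "lifo")
FACETS = ("year", "country", "publication_type", "journal")

_TITLE_FIELDS = ("title", "transliterated_title")
_ALL_FIELDS = ("title", "transliterated_title", "abstract")

# Case-fold-only tokenizer for the all_fields emulation: apostrophes bind
# (so "l'angine" stays one token) and diacritics survive.
_RAW_TOKEN_RE = re.compile(r"[^\W_]+(?:['’][^\W_]+)*", re.UNICODE)


def _raw_tokens(text: str | None) -> list[str]:
    if not text:
        return []
    return _RAW_TOKEN_RE.findall(text.casefold())


@dataclass(frozen=True)
class ScoringConfig:
    """Per-term credit table for relevance scoring.

    The 100% anchor (title word / major topic) is fixed by design; the
    partial credits order the weaker evidence channels strictly:
    title = major > minor > abstract, with automatic-origin annotations
    multiplied by ``automatic_factor``.
    """

    title_word: float = 1.0
    major_concept: float = 1.0
    minor_concept: float = 0.7
    abstract_word: float = 0.5
    automatic_factor: float = 0.8


@dataclass(frozen=True)
class SearchConfig:
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    explode: bool = True  # hierarchy-expand concept terms at query time
    word_fields: tuple[str, ...] = _ALL_FIELDS  # fields residual words search


class SubsetIndex:
    """Inverted index over one language subset.

    Word postings are kept per field under the engine's normalization; a
    parallel set of case-fold-only postings (plus annotated-concept label
    tokens) backs the ``all_fields`` emulation.  Concept postings map each
    descriptor ui to the citations annotated with it, with the major flag,
    qualifiers and annotation origin needed for scoring.
    """

    def __init__(self, lang: str, store) -> None:
        self.lang = lang
        self.store = store
        self.records: dict[str, CitationRecord] = {}
        self.word_postings: dict[str, dict[str, set[str]]] = {
            f: defaultdict(set) for f in _ALL_FIELDS
        }
        self.raw_postings: dict[str, set[str]] = defaultdict(set)
        self.concept_label_postings: dict[str, set[str]] = defaultdict(set)
        self.concept_postings: dict[str, dict[str, list]] = defaultdict(dict)
        self.facets: dict[str, dict] = {f: defaultdict(set) for f in FACETS}

    # -- helpers ----------------------------------------------------------

    def field_tokens(self, record: CitationRecord, field_name: str) -> set[str]:
        text = getattr(record, field_name) or ""
        return set(normalize_text(text, self.lang))

    def title_tokens(self, record: CitationRecord) -> set[str]:
        return self.field_tokens(record, "title") | self.field_tokens(
            record, "transliterated_title"
        )

    def postings_for_word(self, token: str, fields: Sequence[str]) -> set[str]:
        out: set[str] = set()
        for f in fields:
            out |= self.word_postings[f].get(token, set())
        return out

    def _facet_value(self, record: CitationRecord, facet: str):
        if facet == "year":
            return record.pub_year
        if facet == "country":
            return record.journal_country
        if facet == "journal":
            return record.journal_title
        raise ValueError(f"unknown facet {facet!r}")


def build_index(
    records: Iterable[CitationRecord],
    store,
    lang: str,
    strict: bool = False,
) -> SubsetIndex:
    """Build a :class:`SubsetIndex` from one language subset.

    Deterministic for a given input order.  An annotation whose descriptor
    ui is absent from the terminology is an error under ``strict``,
    otherwise logged and skipped.
    """
    index = SubsetIndex(lang, store)
    for record in records:
        if record.pmid in index.records:
            raise ValueError(f"duplicate PMID {record.pmid} in subset")
        index.records[record.pmid] = record
        for f in _ALL_FIELDS:
            text = getattr(record, f) or ""
            for token in normalize_text(text, lang):
                index.word_postings[f][token].add(record.pmid)
            for token in _raw_tokens(text):
                index.raw_postings[token].add(record.pmid)
        for annotation in record.annotations:
            ui = annotation.descriptor_ui
            known = ui in store.descriptors or ui in store.supplementary
            if not known:
                if strict:
                    raise ValueError(
                        f"PMID {record.pmid}: unknown descriptor ui {ui!r}"
                    )
                logger.warning(
                    "PMID %s: unknown descriptor ui %r skipped", record.pmid, ui
                )
                continue
            index.concept_postings[ui].setdefault(record.pmid, []).append(annotation)
            concept = store.descriptors.get(ui) or store.supplementary.get(ui)
            for labels in (concept.labels, getattr(concept, "synonyms", {})):
                for _lang, value in labels.items():
                    forms = value if isinstance(value, list) else [value]
                    for form in forms:
                        for token in _raw_tokens(form):
                            index.concept_label_postings[token].add(record.pmid)
        index.facets["year"][record.pub_year].add(record.pmid)
        if record.journal_country:
            index.facets["country"][record.journal_country].add(record.pmid)
        if record.journal_title:
            index.facets["journal"][record.journal_title].add(record.pmid)
        for pt in record.pub_types:
            index.facets["publication_type"][pt].add(record.pmid)
    return index


# -- concept-term expansion ------------------------------------------------


def _expanded_concept_uis(term: ConceptTerm, index: SubsetIndex, config: SearchConfig):
    """Resolve a concept term to (descriptor uis, qualifier-only uis)."""
    store = index.store
    descriptor_uis: set[str] = set()
    qualifier_uis: set[str] = set()
    if term.kind == "metaterm":
        for ui in store.expand_metaterm(term.ui, index.lang):
            if ui in store.qualifiers:
                qualifier_uis.add(ui)
            else:
                descriptor_uis.add(ui)
    elif term.kind == "qualifier":
        qualifier_uis.add(term.ui)
    else:
        descriptor_uis.add(term.ui)
    if config.explode:
        exploded: set[str] = set()
        for ui in descriptor_uis:
            if ui in store.descriptors:
                exploded |= store.explode(ui)
            else:
                exploded.add(ui)  # supplementary concepts have no tree
        descriptor_uis = exploded
    return descriptor_uis, qualifier_uis


def _concept_annotation_hits(
    term: ConceptTerm, pmid: str, index: SubsetIndex, config: SearchConfig
):
    """Annotations of ``pmid`` satisfying the concept term (with explosion
    and qualifier constraint).  Yields (major, origin) evidence pairs."""
    descriptor_uis, qualifier_uis = _expanded_concept_uis(term, index, config)
    record = index.records[pmid]
    for annotation in record.annotations:
        if annotation.descriptor_ui in descriptor_uis:
            if term.qualifier_ui is not None:
                for q_ui, q_major in annotation.qualifiers:
                    if q_ui == term.qualifier_ui:
                        yield (annotation.major or q_major, annotation.origin)
            else:
                yield (annotation.major, annotation.origin)
        elif qualifier_uis:
            for q_ui, q_major in annotation.qualifiers:
                if q_ui in qualifier_uis:
                    yield (annotation.major or q_major, annotation.origin)


def _concept_match_set(
    term: ConceptTerm, index: SubsetIndex, config: SearchConfig
) -> set[str]:
    """Citations matching one concept term: annotated with the (exploded)
    concept, or carrying all of the term's matched tokens in the title."""
    descriptor_uis, qualifier_uis = _expanded_concept_uis(term, index, config)
    pmids: set[str] = set()
    for ui in descriptor_uis:
        posting = index.concept_postings.get(ui)
        if not posting:
            continue
        if term.qualifier_ui is None:
            pmids |= set(posting)
        else:
            for pmid, annotations in posting.items():
                if any(
                    q_ui == term.qualifier_ui
                    for a in annotations
                    for q_ui, _ in a.qualifiers
                ):
                    pmids.add(pmid)
    if qualifier_uis:
        for posting in index.concept_postings.values():
            for pmid, annotations in posting.items():
                if any(
                    q_ui in qualifier_uis
                    for a in annotations
                    for q_ui, _ in a.qualifiers
                ):
                    pmids.add(pmid)
    if term.matched_tokens:
        title_hits: set[str] | None = None
        for token in term.matched_tokens:
            hits = index.postings_for_word(token, _TITLE_FIELDS)
            title_hits = hits if title_hits is None else title_hits & hits
            if not title_hits:
                break
        if title_hits:
            pmids |= title_hits
    return pmids


# -- scoring ---------------------------------------------------------------


def score_citation(
    query: StructuredQuery,
    record: CitationRecord,
    index: SubsetIndex,
    config: SearchConfig | None = None,
) -> float:
    """Relevance score in [0, 100] for a citation already known to satisfy
    the query's boolean condition.

    Each term contributes the credit of the best channel it matched — title
    word or human major topic 1.0, minor topic 0.7, abstract-only word 0.5,
    concept credit damped by 0.8 when the annotation origin is automatic —
    and the score is 100 × (sum of credits) / (number of terms).  A perfect
    title + major-topic match therefore scores exactly 100.
    """
    config = config or SearchConfig()
    credits_table = config.scoring
    title_tokens = index.title_tokens(record)
    abstract_tokens = index.field_tokens(record, "abstract")
    total = 0.0
    n_terms = query.n_terms
    if n_terms == 0:
        return 0.0
    for term in query.concept_terms:
        best = 0.0
        if term.matched_tokens and all(t in title_tokens for t in term.matched_tokens):
            best = credits_table.title_word
        for major, origin in _concept_annotation_hits(term, record.pmid, index, config):
            credit = credits_table.major_concept if major else credits_table.minor_concept
            if origin == "automatic":
                credit *= credits_table.automatic_factor
            best = max(best, credit)
        total += best
    for token in query.word_terms:
        if token in title_tokens:
            total += credits_table.title_word
        elif token in abstract_tokens:
            total += credits_table.abstract_word
    return max(0.0, min(100.0, 100.0 * total / n_terms))


# -- search ----------------------------------------------------------------


@dataclass
class SearchResult:
    """Ranked hit list.  ``hits`` is the top-k page; ``all_hits`` keeps the
    full ordered match list so facet refinement can recount coverage."""

    hits: list[tuple[str, float]]
    total_hits: int
    strategy: str
    ranking: str
    k: int
    all_hits: list[tuple[str, float]] = field(default_factory=list, repr=False)

    @property
    def pmids(self) -> list[str]:
        return [pmid for pmid, _ in self.hits]


def _boolean_match_set(
    query: StructuredQuery, index: SubsetIndex, strategy: str, config: SearchConfig
) -> set[str]:
    if strategy == "semantic":
        matched: set[str] | None = None
        for term in query.concept_terms:
            hits = _concept_match_set(term, index, config)
            matched = hits if matched is None else matched & hits
        for token in query.word_terms:
            hits = index.postings_for_word(token, config.word_fields)
            matched = hits if matched is None else matched & hits
        return matched or set()
    if strategy == "title_only":
        matched = None
        for token in query.tokens:
            hits = index.word_postings["transliterated_title"].get(token, set())
            matched = hits if matched is None else matched & hits
        return matched or set()
    if strategy == "all_fields":
        matched = None
        for token in _raw_tokens(query.raw_text):
            hits = index.raw_postings.get(token, set()) | index.concept_label_postings.get(
                token, set()
            )
            matched = hits if matched is None else matched & hits
        return matched or set()
    raise ValueError(f"unknown strategy {strategy!r}")


def _strategy_score(
    query: StructuredQuery,
    pmid: str,
    index: SubsetIndex,
    strategy: str,
    config: SearchConfig,
) -> float:
    if strategy == "semantic":
        return score_citation(query, index.records[pmid], index, config)
    if strategy == "title_only":
        return 100.0  # every token matched in the title by construction
    # all_fields: word-channel analogue over raw tokens
    record = index.records[pmid]
    raw_title = set(_raw_tokens(record.title)) | set(
        _raw_tokens(record.transliterated_title or "")
    )
    tokens = _raw_tokens(query.raw_text)
    if not tokens:
        return 0.0
    total = 0.0
    for token in tokens:
        if token in raw_title:
            total += config.scoring.title_word
        elif pmid in index.concept_label_postings.get(token, set()):
            total += config.scoring.minor_concept
        else:
            total += config.scoring.abstract_word
    return max(0.0, min(100.0, 100.0 * total / len(tokens)))


def _pmid_sort_key(pmid: str):
    return int(pmid) if pmid.isdigit() else 0


def search(
    query: StructuredQuery,
    index: SubsetIndex,
    strategy: str = "semantic",
    ranking: str = "relevance",
    k: int = 20,
    config: SearchConfig | None = None,
) -> SearchResult:
    """Execute a structured query and return the ranked top-``k``.

    ``total_hits`` counts the whole boolean match set (the coverage number),
    regardless of ``k``.  ``relevance`` orders by score, then publication
    year, then PMID, all descending; ``lifo`` by year then PMID descending.
    The match set — and hence coverage — is identical under both rankings.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r} (expected {STRATEGIES})")
    if ranking not in RANKINGS:
        raise ValueError(f"unknown ranking {ranking!r} (expected {RANKINGS})")
    if k < 1:
        raise ValueError("k must be >= 1")
    config = config or SearchConfig()
    matched = _boolean_match_set(query, index, strategy, config)
    scored = [
        (pmid, _strategy_score(query, pmid, index, strategy, config))
        for pmid in matched
    ]
    if ranking == "relevance":
        scored.sort(
            key=lambda it: (
                -it[1],
                -index.records[it[0]].pub_year,
                -_pmid_sort_key(it[0]),
            )
        )
    else:
        scored.sort(
            key=lambda it: (-index.records[it[0]].pub_year, -_pmid_sort_key(it[0]))
        )
    return SearchResult(
        hits=scored[:k],
        total_hits=len(scored),
        strategy=strategy,
        ranking=ranking,
        k=k,
        all_hits=scored,
    )


def refine_facet(
    result: SearchResult, index: SubsetIndex, facet: str, value
) -> SearchResult:
    """Refine a result by one facet value, preserving order and recomputing
    coverage.  Facet refinements commute."""
    if facet not in FACETS:
        raise ValueError(f"unknown facet {facet!r} (expected {FACETS})")
    if facet == "year" and not isinstance(value, int):
        value = int(value)
    member = index.facets[facet].get(value, set())
    kept = [(pmid, score) for pmid, score in result.all_hits if pmid in member]
    return SearchResult(
        hits=kept[: result.k],
        total_hits=len(kept),
        strategy=result.strategy,
        ranking=result.ranking,
        k=result.k,
        all_hits=kept,
    )
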