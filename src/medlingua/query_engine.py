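"""Query normalization and interpretation.

Free text in the subset language is normalized (case folding, diacritic
stripping, ligature expansion, elision-aware apostrophe handling) and then
interpreted against the loaded terminology into a structured query: a
conjunction of concept terms (descriptors, possibly qualified, metaterms,
predefined expressions) and residual word terms.

French is the primary target: elided articles (l', d', j', n', s', t', qu')
are dropped and the apostrophe acts as a separator, so ``l'angine``
normalizes to the single token ``angine``.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "ConceptTerm",
    "StructuredQuery",
    "normalize_text",
    "interpret_query",
    "load_stopwords",
    "KIND_PRIORITY",
]

logger = logging.getLogger(__name__)

# Segmentation tie-break between equal-length matches: lower rank wins.
KIND_PRIORITY: dict[str, int] = {
    "predefined": 0,
    "metaterm": 1,
    "descriptor": 2,
    "supplementary": 3,
    "qualifier": 4,
}

_APOSTROPHES = "'’ʼ′"
_ELIDED = ("qu", "l", "d", "j", "n", "s", "t")
_ELISION_RE = re.compile(
    r"(?:(?<=^)|(?<=[^a-z0-9]))(?:%s)[%s]" % ("|".join(_ELIDED), _APOSTROPHES)
)
_LIGATURES = {"œ": "oe", "æ": "ae"}
_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _strip_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFD", text)
    return "".join(ch for ch in decomposed if unicodedata.category(ch) != "Mn")


def normalize_text(text: str, lang: str = "fre") -> list[str]:
    """Normalize free text into a token sequence.

    Case-folds, expands the oe/ae ligatures, removes elided articles in front
    of apostrophes (treating the apostrophe as a separator), strips combining
    diacritics, and tokenizes on anything that is not an ASCII letter or
    digit.  Stop words are *not* removed here: they may be part of a concept
    label ("maladie de Crohn") and are only dropped from residual words after
    concept matching.

    Idempotent: ``normalize_text(" ".join(normalize_text(x)))`` equals
    ``normalize_text(x)``.
    """
    text = text.casefold()
    for lig, repl in _LIGATURES.items():
        text = text.replace(lig, repl)
    text = _ELISION_RE.sub(" ", text)
    text = _strip_diacritics(text)
    return _TOKEN_RE.findall(text)


def load_stopwords(lang: str) -> frozenset[str]:
    """Load the small shipped stop-word list for ``lang`` (normalized forms)."""
    name = f"stopwords_{lang}.txt"
    try:
        raw = resources.files("medlingua.data").joinpath(name).read_text("utf-8")
    except FileNotFoundError:
        return frozenset()
    words: set[str] = set()
    for line in raw.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.update(normalize_text(line, lang))
    return frozenset(words)


@dataclass(frozen=True)
class ConceptTerm:
    """One concept term of a structured query.

    ``kind`` is one of descriptor / qualifier / supplementary / metaterm;
    ``source`` records how the term was recognized (label, synonym, acronym,
    metaterm, predefined).  ``matched_tokens`` are the normalized query tokens
    the term consumed — the basis for title-word matching at search time.
    """

    ui: str
    kind: str
    qualifier_ui: str | None = None
    source: str = "label"
    matched_tokens: tuple[str, ...] = ()


@dataclass
class StructuredQuery:
    """Interpreted query: conjunction of concept terms and residual words."""

    concept_terms: list[ConceptTerm] = field(default_factory=list)
    word_terms: list[str] = field(default_factory=list)
    tokens: list[str] = field(default_factory=list)
    raw_text: str = ""
    lang: str = "fre"
    connective: str = "AND"

    @property
    def n_terms(self) -> int:
        return len(self.concept_terms) + len(self.word_terms)


def interpret_query(text: str, lang: str, store) -> StructuredQuery:
    """Interpret free text into a :class:`StructuredQuery`.

    Resolution order:

    1. a whole-string predefined-query match wins outright;
    2. otherwise the token sequence is segmented greedily left to right
       against terminology labels, synonyms, acronyms and metaterm names,
       always preferring the longest match (ties between kinds broken by
       :data:`KIND_PRIORITY`; ambiguous acronyms resolve to the first listed
       sense, logged);
    3. unconsumed tokens that are not stop words become word terms.

    All terms are combined conjunctively.

    Raises ``ValueError`` on empty input.
    """
    tokens = normalize_text(text, lang)
    if not tokens:
        raise ValueError("empty query")

    predef = store.resolve_predefined_query(text, lang)
    if predef is not None:
        predef.tokens = tokens
        predef.raw_text = text
        predef.lang = lang
        return predef

    stopwords = store.stopwords(lang)
    max_len = max(1, store.max_phrase_tokens(lang))
    concept_terms: list[ConceptTerm] = []
    word_terms: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        term = None
        for j in range(min(n, i + max_len), i, -1):
            phrase = " ".join(tokens[i:j])
            matches = store.lookup_phrase(phrase, lang)
            if not matches:
                continue
            matches = sorted(matches, key=lambda m: KIND_PRIORITY.get(m.kind, 99))
            best = matches[0]
            if best.ambiguous and len(matches) > 1:
                logger.info(
                    "ambiguous match %r: keeping first sense %s/%s of %d candidates",
                    phrase, best.kind, best.ui, len(matches),
                )
            if best.kind == "predefined":
                term = [
                    ConceptTerm(
                        ui=d,
                        kind="descriptor",
                        qualifier_ui=q,
                        source="predefined",
                        matched_tokens=tuple(tokens[i:j]),
                    )
                    for d, q in store.expand_predefined(best.ui)
                ]
            else:
                term = [
                    ConceptTerm(
                        ui=best.ui,
                        kind=best.kind,
                        source=best.source,
                        matched_tokens=tuple(tokens[i:j]),
                    )
                ]
            i = j
            break
        if term is not None:
            concept_terms.extend(term)
        else:
            if tokens[i] not in stopwords:
                word_terms.append(tokens[i])
            i += 1

    return StructuredQuery(
        concept_terms=concept_terms,
        word_terms=word_terms,
        tokens=tokens,
        raw_text=text,
        lang=lang,
    )
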