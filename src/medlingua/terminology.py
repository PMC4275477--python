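"""Multilingual MeSH-style terminology store.

Houses descriptors, qualifiers and supplementary concepts with per-language
labels, synonyms and acronyms, plus two retrieval aids curated on top of the
thesaurus: metaterms (specialty-level superconcepts semantically linked to one
or more descriptors/qualifiers, e.g. *psychiatry* → {psychiatry, psychiatric
hospital}) and predefined queries (lay labels mapped to boolean MeSH
expressions, e.g. *natremia* → sodium/blood).

File format — a directory of UTF-8 tab-separated tables with header rows;
lines starting with ``#`` are comments:

``descriptors.tsv``
    ui, tree_numbers (``;``-separated), see_also (``;``-separated uis)
``qualifiers.tsv``
    ui
``supplementary.tsv``
    ui, mapped_descriptors (``;``-separated)
``metaterms.tsv``
    ui, linked (``;``-separated descriptor/qualifier uis)
``predefined.tsv``
    ui, expression — ``AND``-joined ``D…[/Q…]`` terms
``labels.tsv``
    kind, ui, lang, label, synonyms (``|``-separated), acronyms
    (``|``-separated; a trailing ``*`` marks an ambiguous acronym),
    scope_note

Every label, synonym and acronym is entered into a per-language
normalized-phrase lookup table (normalization shared with the query engine),
exactly once per (normalized form, concept) pair.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .query_engine import (
    ConceptTerm,
    StructuredQuery,
    load_stopwords,
    normalize_text,
)

__all__ = [
    "Descriptor",
    "Qualifier",
    "SupplementaryConcept",
    "Metaterm",
    "PredefinedQuery",
    "ConceptMatch",
    "TerminologyStore",
    "TerminologyError",
    "load_terminology",
]


class TerminologyError(ValueError):
    """Raised for malformed or inconsistent terminology files."""


@dataclass
class Descriptor:
    ui: str
    tree_numbers: list[str]
    labels: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, list[str]] = field(default_factory=dict)
    acronyms: dict[str, list[tuple[str, bool]]] = field(default_factory=dict)
    scope_notes: dict[str, str] = field(default_factory=dict)
    see_also: list[str] = field(default_factory=list)


@dataclass
class Qualifier:
    ui: str
    labels: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SupplementaryConcept:
    """Chemical/substance concept mapped onto descriptors; translations are
    incomplete, so it matches only in languages where a label exists (plus
    English, which is always present)."""

    ui: str
    mapped_descriptors: list[str]
    labels: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class Metaterm:
    ui: str
    linked: list[str]
    labels: dict[str, str] = field(default_factory=dict)


@dataclass
class PredefinedQuery:
    ui: str
    expression: list[tuple[str, str | None]]  # (descriptor_ui, qualifier_ui)
    labels: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ConceptMatch:
    """One hit of a normalized-phrase lookup."""

    ui: str
    kind: str  # descriptor | qualifier | supplementary | metaterm | predefined
    matched_form: str
    source: str  # label | synonym | acronym
    ambiguous: bool = False


def _parse_expression(expr: str) -> list[tuple[str, str | None]]:
    terms: list[tuple[str, str | None]] = []
    for part in expr.split(" AND "):
        part = part.strip()
        if not part:
            continue
        if "/" in part:
            d, q = part.split("/", 1)
            terms.append((d.strip(), q.strip()))
        else:
            terms.append((part, None))
    return terms


class TerminologyStore:
    """In-memory terminology with per-language normalized lookup tables."""

    def __init__(self) -> None:
        self.descriptors: dict[str, Descriptor] = {}
        self.qualifiers: dict[str, Qualifier] = {}
        self.supplementary: dict[str, SupplementaryConcept] = {}
        self.metaterms: dict[str, Metaterm] = {}
        self.predefined: dict[str, PredefinedQuery] = {}
        self.languages: set[str] = set()
        self._phrase_tables: dict[str, dict[str, list[ConceptMatch]]] = {}
        self._predef_tables: dict[str, dict[str, str]] = {}
        self._metaterm_tables: dict[str, dict[str, str]] = {}
        self._max_phrase_tokens: dict[str, int] = {}
        self._stopwords: dict[str, frozenset[str]] = {}

    # -- lookup -----------------------------------------------------------

    def stopwords(self, lang: str) -> frozenset[str]:
        if lang not in self._stopwords:
            self._stopwords[lang] = load_stopwords(lang)
        return self._stopwords[lang]

    def max_phrase_tokens(self, lang: str) -> int:
        return self._max_phrase_tokens.get(lang, 1)

    def lookup_phrase(self, normalized_phrase: str, lang: str) -> list[ConceptMatch]:
        if lang not in self._phrase_tables:
            raise TerminologyError(f"language {lang!r} not declared in terminology")
        return list(self._phrase_tables[lang].get(normalized_phrase, ()))

    def match_label(self, text: str, lang: str) -> list[ConceptMatch]:
        """Match a query fragment against labels, synonyms and acronyms.

        The lookup is exact after normalization, so it is invariant under
        case, diacritics, ligatures and elision.  Ambiguous acronyms return
        every candidate sense flagged ``ambiguous``.
        """
        phrase = " ".join(normalize_text(text, lang))
        return self.lookup_phrase(phrase, lang)

    def explode(self, descriptor_ui: str) -> set[str]:
        """Expand a descriptor to itself plus all tree-number descendants.

        A descriptor D' is a descendant of D iff some tree number of D' is
        prefixed (at a dot boundary) by some tree number of D.
        """
        try:
            desc = self.descriptors[descriptor_ui]
        except KeyError:
            raise TerminologyError(f"unknown descriptor ui {descriptor_ui!r}") from None
        out = {descriptor_ui}
        prefixes = [tn + "." for tn in desc.tree_numbers]
        exact = set(desc.tree_numbers)
        for other in self.descriptors.values():
            for tn in other.tree_numbers:
                if tn in exact or any(tn.startswith(p) for p in prefixes):
                    out.add(other.ui)
                    break
        return out

    def expand_metaterm(self, name: str, lang: str) -> set[str]:
        """Return the descriptor/qualifier uis semantically linked to a
        metaterm, identified by ui or by its (normalized) name in ``lang``.
        No hierarchy explosion happens at this step."""
        if name in self.metaterms:
            return set(self.metaterms[name].linked)
        table = self._metaterm_tables.get(lang, {})
        key = " ".join(normalize_text(name, lang))
        if key in table:
            return set(self.metaterms[table[key]].linked)
        raise TerminologyError(f"unknown metaterm {name!r} in language {lang!r}")

    def expand_predefined(self, ui: str) -> list[tuple[str, str | None]]:
        return list(self.predefined[ui].expression)

    def resolve_predefined_query(self, label: str, lang: str) -> StructuredQuery | None:
        """Whole-string match of ``label`` against predefined-query labels;
        returns the stored expression as a structured query, or None."""
        tokens = normalize_text(label, lang)
        key = " ".join(tokens)
        ui = self._predef_tables.get(lang, {}).get(key)
        if ui is None:
            return None
        terms = [
            ConceptTerm(
                ui=d,
                kind="descriptor",
                qualifier_ui=q,
                source="predefined",
                matched_tokens=tuple(tokens),
            )
            for d, q in self.predefined[ui].expression
        ]
        return StructuredQuery(concept_terms=terms, tokens=tokens, lang=lang)

    # -- construction -----------------------------------------------------

    def _register(self, lang: str, form: str, match: ConceptMatch) -> None:
        table = self._phrase_tables.setdefault(lang, {})
        key = " ".join(normalize_text(form, lang))
        if not key:
            return
        entries = table.setdefault(key, [])
        if any(e.ui == match.ui and e.kind == match.kind for e in entries):
            return  # one entry per (normalized form, concept) pair
        entries.append(match)
        ntok = key.count(" ") + 1
        if ntok > self._max_phrase_tokens.get(lang, 0):
            self._max_phrase_tokens[lang] = ntok

    def build_lookup_tables(self) -> None:
        self._phrase_tables = {lang: {} for lang in self.languages}
        self._predef_tables = {lang: {} for lang in self.languages}
        self._metaterm_tables = {lang: {} for lang in self.languages}
        self._max_phrase_tokens = {}

        def add_labelled(kind: str, ui: str, labels, synonyms, acronyms=None):
            for lang, label in labels.items():
                self._register(lang, label, ConceptMatch(ui, kind, label, "label"))
            for lang, syns in synonyms.items():
                for syn in syns:
                    self._register(lang, syn, ConceptMatch(ui, kind, syn, "synonym"))
            if acronyms:
                for lang, acs in acronyms.items():
                    for text, ambiguous in acs:
                        self._register(
                            lang, text,
                            ConceptMatch(ui, kind, text, "acronym", ambiguous),
                        )

        for d in self.descriptors.values():
            add_labelled("descriptor", d.ui, d.labels, d.synonyms, d.acronyms)
        for q in self.qualifiers.values():
            add_labelled("qualifier", q.ui, q.labels, q.synonyms)
        for s in self.supplementary.values():
            add_labelled("supplementary", s.ui, s.labels, s.synonyms)
        for m in self.metaterms.values():
            for lang, label in m.labels.items():
                self._register(lang, label, ConceptMatch(m.ui, "metaterm", label, "label"))
                key = " ".join(normalize_text(label, lang))
                self._metaterm_tables.setdefault(lang, {})[key] = m.ui
        for p in self.predefined.values():
            for lang, label in p.labels.items():
                self._register(lang, label, ConceptMatch(p.ui, "predefined", label, "label"))
                key = " ".join(normalize_text(label, lang))
                self._predef_tables.setdefault(lang, {})[key] = p.ui

    def validate(self) -> None:
        """Check referential integrity; raises listing every offender."""
        dangling: list[str] = []
        concept_uis = set(self.descriptors) | set(self.qualifiers)
        for d in self.descriptors.values():
            if not d.tree_numbers:
                dangling.append(f"descriptor {d.ui}: no tree number")
            for ref in d.see_also:
                if ref not in self.descriptors:
                    dangling.append(f"descriptor {d.ui}: see_also -> {ref}")
        for s in self.supplementary.values():
            if "eng" not in s.labels:
                dangling.append(f"supplementary {s.ui}: missing English label")
            for ref in s.mapped_descriptors:
                if ref not in self.descriptors:
                    dangling.append(f"supplementary {s.ui}: mapped -> {ref}")
        for m in self.metaterms.values():
            if not m.linked:
                dangling.append(f"metaterm {m.ui}: no linked concepts")
            for ref in m.linked:
                if ref not in concept_uis:
                    dangling.append(f"metaterm {m.ui}: linked -> {ref}")
        for p in self.predefined.values():
            for d_ui, q_ui in p.expression:
                if d_ui not in self.descriptors:
                    dangling.append(f"predefined {p.ui}: descriptor -> {d_ui}")
                if q_ui is not None and q_ui not in self.qualifiers:
                    dangling.append(f"predefined {p.ui}: qualifier -> {q_ui}")
        if dangling:
            raise TerminologyError(
                "terminology integrity errors:\n  " + "\n  ".join(dangling)
            )


def _read_tsv(path: Path) -> list[dict[str, str]]:
    if not path.exists():
        return []
    with path.open(encoding="utf-8", newline="") as fh:
        rows = [r for r in csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )]
    return rows


def _split(value: str | None, sep: str) -> list[str]:
    if not value:
        return []
    return [p.strip() for p in value.split(sep) if p.strip()]


def load_terminology(path: str | Path) -> TerminologyStore:
    """Load a terminology directory into a :class:`TerminologyStore`.

    Validates referential integrity (a dangling ui reference is a load
    error listing every offender) and builds the normalized lookup tables.
    """
    path = Path(path)
    store = TerminologyStore()

    for row in _read_tsv(path / "descriptors.tsv"):
        ui = row["ui"].strip()
        store.descriptors[ui] = Descriptor(
            ui=ui,
            tree_numbers=_split(row.get("tree_numbers"), ";"),
            see_also=_split(row.get("see_also"), ";"),
        )
    for row in _read_tsv(path / "qualifiers.tsv"):
        ui = row["ui"].strip()
        store.qualifiers[ui] = Qualifier(ui=ui)
    for row in _read_tsv(path / "supplementary.tsv"):
        ui = row["ui"].strip()
        store.supplementary[ui] = SupplementaryConcept(
            ui=ui, mapped_descriptors=_split(row.get("mapped_descriptors"), ";")
        )
    for row in _read_tsv(path / "metaterms.tsv"):
        ui = row["ui"].strip()
        store.metaterms[ui] = Metaterm(ui=ui, linked=_split(row.get("linked"), ";"))
    for row in _read_tsv(path / "predefined.tsv"):
        ui = row["ui"].strip()
        store.predefined[ui] = PredefinedQuery(
            ui=ui, expression=_parse_expression(row.get("expression", ""))
        )

    by_kind = {
        "descriptor": store.descriptors,
        "qualifier": store.qualifiers,
        "supplementary": store.supplementary,
        "metaterm": store.metaterms,
        "predefined": store.predefined,
    }
    for row in _read_tsv(path / "labels.tsv"):
        kind = row["kind"].strip()
        ui = row["ui"].strip()
        lang = row["lang"].strip()
        table = by_kind.get(kind)
        if table is None or ui not in table:
            raise TerminologyError(f"labels.tsv: unknown concept {kind} {ui}")
        obj = table[ui]
        store.languages.add(lang)
        obj.labels[lang] = row["label"].strip()
        syns = _split(row.get("synonyms"), "|")
        if syns and hasattr(obj, "synonyms"):
            obj.synonyms[lang] = syns
        acs = _split(row.get("acronyms"), "|")
        if acs and hasattr(obj, "acronyms"):
            obj.acronyms[lang] = [
                (a[:-1], True) if a.endswith("*") else (a, False) for a in acs
            ]
        note = (row.get("scope_note") or "").strip()
        if note and hasattr(obj, "scope_notes"):
            obj.scope_notes[lang] = note

    store.validate()
    store.build_lookup_tables()
    return store
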