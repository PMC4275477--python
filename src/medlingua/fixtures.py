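"""Deterministic synthetic fixtures and packaged study tables.

Two generators make the whole engine testable without any download:

* :func:`generate_mini_mesh` writes a small multilingual MeSH-style
  terminology (descriptor forest with tree numbers, qualifiers,
  supplementary concepts, metaterms, predefined queries, per-language
  synonyms with diacritic-bearing French forms and an ambiguous acronym);
* :func:`generate_corpus` writes a PubmedArticleSet XML corpus with a
  controlled language mix and, per planted query, a known relevant set split
  between *title-evidence* records (the concept's label appears in the
  original-language title) and *synonym-only* records (the record is MeSH-
  annotated with the concept but its title never mentions it) — the
  construction behind the semantic-vs-title-only coverage-gap checks.

Titles and abstracts are built from a closed pseudo-word vocabulary kept
disjoint from every terminology label, so token-count oracles are trivial
and no text resembles a real citation.

:func:`load_paper_tables` exposes the packaged response-time, coverage and
precision tables of the evaluation study (checksum-verified), with the
footnoted retrieved counts attached and per-query relevant counts recovered
as round(precision × retrieved); the reconstruction is asserted to reproduce
the printed precision at load time.
"""

from __future__ import annotations

import csv
import hashlib
import random
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from lxml import etree

from .evaluation import PrecisionCell, QueryRun
from .query_engine import normalize_text

__all__ = [
    "STRATEGIES_PAPER",
    "CorpusSpec",
    "PaperTables",
    "generate_mini_mesh",
    "generate_corpus",
    "load_relevance_key",
    "judgments_from_key",
    "load_paper_tables",
]

#: The five strategies compared in the study, in table column order.
STRATEGIES_PAPER = (
    "babelmesh",
    "multilingual_pubmed_french",
    "pubmed_lifo",
    "pubmed_relevance",
    "pubmed_tt",
)

#: Table-4 coverage columns: the two PubMed rankings share one column.
_COVERAGE_COLUMNS = ("babelmesh", "multilingual_pubmed_french", "pubmed", "pubmed_tt")

_TABLE_SHA256 = {
    "table3_response_times.tsv":
        "13eb35852591f21c75fcb6a00567b998fb1b50482b8bf12b89f5edfafe631eea",
    "table4_coverage.tsv":
        "37de6f48ac13021e223f6bb389a509115133ec0cddfd32877447786728558f51",
    "table5_precision.tsv":
        "c674846dffe50e61af1af8c47bbd9b3ad18597e495c40bb88b1c444c6cc1cd41",
}

#: Printed per-strategy coverage totals, used as a load-time cross-check.
TABLE4_TOTALS = {
    "babelmesh": 50894,
    "multilingual_pubmed_french": 42384,
    "pubmed": 34047,
    "pubmed_tt": 10716,
}

#: Footnoted retrieved counts (fewer than 20 citations retrieved) for the
#: precision table; every other cell retrieved the full 20.
FOOTNOTE_RETRIEVED = {
    ("breast feeding", "pubmed_lifo"): 3,
    ("breast feeding", "pubmed_relevance"): 3,
    ("electronic cigarette", "pubmed_lifo"): 0,
    ("electronic cigarette", "pubmed_relevance"): 0,
    ("electronic cigarette", "pubmed_tt"): 0,
    ("whooping cough", "pubmed_lifo"): 2,
    ("whooping cough", "pubmed_relevance"): 2,
    ("scabies", "pubmed_lifo"): 4,
    ("scabies", "pubmed_relevance"): 4,
    ("celiac disease", "pubmed_lifo"): 2,
    ("celiac disease", "pubmed_relevance"): 2,
    ("Crohn disease", "pubmed_lifo"): 2,
    ("Crohn disease", "pubmed_relevance"): 2,
    ("sarcoidosis", "pubmed_lifo"): 13,
    ("sarcoidosis", "pubmed_relevance"): 13,
    ("scoliosis", "pubmed_lifo"): 3,
    ("scoliosis", "pubmed_relevance"): 3,
    ("tobacco", "pubmed_lifo"): 18,
    ("tobacco", "pubmed_relevance"): 18,
    ("toxoplasmosis", "pubmed_lifo"): 10,
    ("toxoplasmosis", "pubmed_relevance"): 10,
}


# ---------------------------------------------------------------------------
# pseudo-word machinery
# ---------------------------------------------------------------------------

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"
_ACCENTED = {"a": "à", "e": "é", "i": "ï", "o": "ô", "u": "û"}


def _pseudo_word(rng: random.Random, n_syllables: tuple[int, int] = (2, 4)) -> str:
    n = rng.randint(*n_syllables)
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n)
    )


def _accentify(rng: random.Random, word: str) -> str:
    """Inject a diacritic or the oe ligature into a pseudo-French word."""
    vowels = [i for i, ch in enumerate(word) if ch in _ACCENTED]
    if not vowels:
        return word
    i = rng.choice(vowels)
    if word[i] == "o" and rng.random() < 0.3:
        return word[:i] + "œ" + word[i + 1:]
    return word[:i] + _ACCENTED[word[i]] + word[i + 1:]


class _FormFactory:
    """Generates normalization-unique label forms."""

    def __init__(self, rng: random.Random, lang: str):
        self.rng = rng
        self.lang = lang
        self.used: set[str] = set()

    def fresh(self, n_words: int = 1, accent: bool = False) -> str:
        for _ in range(1000):
            words = [_pseudo_word(self.rng) for _ in range(n_words)]
            if accent:
                words = [
                    _accentify(self.rng, w) if self.rng.random() < 0.7 else w
                    for w in words
                ]
            form = " ".join(words)
            tokens = normalize_text(form, self.lang)
            # token-level uniqueness so no two label forms share a word
            if tokens and all(t not in self.used for t in tokens):
                self.used.update(tokens)
                return form
        raise RuntimeError("pseudo-word space exhausted")


# ---------------------------------------------------------------------------
# mini terminology
# ---------------------------------------------------------------------------


def generate_mini_mesh(
    seed: int,
    out_dir: str | Path,
    n_descriptors: int = 10,
    n_qualifiers: int = 2,
    n_metaterms: int = 2,
    synonyms_per_descriptor: int = 2,
    n_supplementary: int = 2,
    n_predefined: int = 2,
) -> Path:
    """Write a deterministic mini terminology into ``out_dir``.

    Tree numbers form a forest (three roots, random attachment); every
    descriptor gets an English and a French label plus the requested number
    of synonyms per language, French forms carrying diacritics; one acronym
    is deliberately shared by two descriptors and flagged ambiguous.
    Byte-identical output for a given seed.
    """
    if min(n_descriptors, n_qualifiers, n_metaterms, synonyms_per_descriptor) < 1:
        raise ValueError("all sizes must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    forms = {"eng": _FormFactory(rng, "eng"), "fre": _FormFactory(rng, "fre")}

    # descriptor forest
    trees: list[str] = []
    children: dict[int, int] = {}
    for i in range(n_descriptors):
        if i < 3:
            trees.append(f"C{i + 1:02d}")
        else:
            parent = rng.randrange(i)
            children[parent] = children.get(parent, 0) + 1
            trees.append(f"{trees[parent]}.{children[parent]}")

    d_uis = [f"D{i + 1:06d}" for i in range(n_descriptors)]
    q_uis = [f"Q{i + 1:06d}" for i in range(n_qualifiers)]
    s_uis = [f"C{i + 1:06d}" for i in range(n_supplementary)]

    see_also = {}
    if n_descriptors >= 2:
        see_also[d_uis[0]] = d_uis[1]

    label_rows: list[list[str]] = []
    acronym_pool: dict[str, list[str]] = {}
    for i, ui in enumerate(d_uis):
        for lang in ("eng", "fre"):
            accent = lang == "fre"
            label = forms[lang].fresh(rng.randint(1, 2), accent=accent)
            syns = [
                forms[lang].fresh(rng.randint(1, 2), accent=accent)
                for _ in range(synonyms_per_descriptor)
            ]
            acronyms: list[str] = []
            if lang == "fre" and i % 3 == 0:
                acronym = "".join(
                    rng.choice("BCDFGLMNPRST") for _ in range(3)
                )
                acronym_pool.setdefault(acronym, []).append(ui)
                acronyms.append(acronym)
            label_rows.append(
                ["descriptor", ui, lang, label, "|".join(syns), "|".join(acronyms), ""]
            )
    # force one shared (ambiguous) acronym between the first two descriptors
    if n_descriptors >= 2:
        shared = "ZAB"
        for row in label_rows:
            if row[0] == "descriptor" and row[1] in d_uis[:2] and row[2] == "fre":
                row[5] = "|".join(
                    filter(None, [row[5], shared + "*"])
                )

    for ui in q_uis:
        for lang in ("eng", "fre"):
            label = forms[lang].fresh(1, accent=lang == "fre")
            syn = forms[lang].fresh(1, accent=lang == "fre")
            label_rows.append(["qualifier", ui, lang, label, syn, "", ""])

    supp_maps = {}
    for i, ui in enumerate(s_uis):
        supp_maps[ui] = rng.choice(d_uis)
        label_rows.append(
            ["supplementary", ui, "eng", forms["eng"].fresh(2), "", "", ""]
        )
        if i % 2 == 0:  # translation incomplete by design
            label_rows.append(
                ["supplementary", ui, "fre", forms["fre"].fresh(2, accent=True), "", "", ""]
            )

    meta_links = {}
    m_uis = [f"M{i + 1:06d}" for i in range(n_metaterms)]
    for ui in m_uis:
        n_links = rng.randint(1, min(3, n_descriptors))
        meta_links[ui] = sorted(rng.sample(d_uis, n_links))
        for lang in ("eng", "fre"):
            label_rows.append(
                [
                    "metaterm", ui, lang,
                    forms[lang].fresh(1, accent=lang == "fre"), "", "", "",
                ]
            )

    predef_exprs = {}
    p_uis = [f"P{i + 1:06d}" for i in range(n_predefined)]
    for ui in p_uis:
        d = rng.choice(d_uis)
        q = rng.choice(q_uis)
        predef_exprs[ui] = f"{d}/{q}"
        for lang in ("eng", "fre"):
            label_rows.append(
                [
                    "predefined", ui, lang,
                    forms[lang].fresh(1, accent=lang == "fre"), "", "", "",
                ]
            )

    def write_tsv(name: str, header: list[str], rows: list[list[str]]) -> None:
        with (out_dir / name).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)

    write_tsv(
        "descriptors.tsv",
        ["ui", "tree_numbers", "see_also"],
        [[ui, trees[i], see_also.get(ui, "")] for i, ui in enumerate(d_uis)],
    )
    write_tsv("qualifiers.tsv", ["ui"], [[ui] for ui in q_uis])
    write_tsv(
        "supplementary.tsv",
        ["ui", "mapped_descriptors"],
        [[ui, supp_maps[ui]] for ui in s_uis],
    )
    write_tsv(
        "metaterms.tsv",
        ["ui", "linked"],
        [[ui, ";".join(meta_links[ui])] for ui in m_uis],
    )
    write_tsv(
        "predefined.tsv",
        ["ui", "expression"],
        [[ui, predef_exprs[ui]] for ui in p_uis],
    )
    write_tsv(
        "labels.tsv",
        ["kind", "ui", "lang", "label", "synonyms", "acronyms", "scope_note"],
        label_rows,
    )
    return out_dir


# ---------------------------------------------------------------------------
# citation corpus
# ---------------------------------------------------------------------------


@dataclass
class CorpusSpec:
    """Conditions for one synthetic citation corpus.

    ``planted`` maps a descriptor ui to the number of records relevant to a
    query for that concept; each relevant record is either *title-evidence*
    (French label in the original-language title, plus the annotation) or
    *synonym-only* (annotation only), in proportion
    ``1 - synonym_only_fraction`` / ``synonym_only_fraction``.
    """

    seed: int = 0
    n_citations: int = 665
    language_mix: dict[str, float] = dc_field(
        default_factory=lambda: {"fre": 0.85, "eng": 0.15}
    )
    vocab_size: int = 250
    planted: dict[str, int] = dc_field(default_factory=dict)
    synonym_only_fraction: float = 0.4
    partial_fraction: float = 0.2
    automatic_fraction: float = 0.2
    year_range: tuple[int, int] = (1995, 2014)

    def __post_init__(self) -> None:
        if not 0.999 < sum(self.language_mix.values()) < 1.001:
            raise ValueError("language mix proportions must sum to 1")
        for frac in (
            self.synonym_only_fraction,
            self.partial_fraction,
            self.automatic_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def _background_vocab(rng: random.Random, spec: CorpusSpec, store) -> list[str]:
    forbidden: set[str] = set()
    for lang in store.languages:
        for key in store._phrase_tables.get(lang, {}):
            forbidden.update(key.split(" "))
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < spec.vocab_size:
        w = _pseudo_word(rng, (2, 3))
        if w in forbidden or w in seen:
            continue
        seen.add(w)
        vocab.append(w)
    return vocab


def generate_corpus(
    spec: CorpusSpec, store, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write ``citations.xml`` (PubmedArticleSet) and ``relevance_key.tsv``.

    For every planted concept the keyed records — and only those — are
    relevant to the query of its French label, with the spec'd split between
    title-evidence and synonym-only records and the spec'd fraction judged
    only partially relevant.  Background records are never annotated inside
    a planted concept's hierarchy-exploded set.  Deterministic per seed.

    Raises ``ValueError`` for an infeasible spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    total_planted = sum(spec.planted.values())
    if total_planted > spec.n_citations:
        raise ValueError(
            f"infeasible spec: {total_planted} planted records > "
            f"{spec.n_citations} citations"
        )
    for ui in spec.planted:
        if ui not in store.descriptors:
            raise ValueError(f"planted concept {ui!r} not in terminology")
    # planted concepts must be hierarchy-disjoint, otherwise one query's
    # exploded match set would swallow another's planted records and the
    # key's "exactly these are relevant" guarantee would not hold
    planted_uis = sorted(spec.planted)
    for i, ui in enumerate(planted_uis):
        for other in planted_uis[i + 1:]:
            if store.explode(ui) & store.explode(other):
                raise ValueError(
                    f"infeasible spec: planted concepts {ui} and {other} "
                    "overlap in the hierarchy"
                )

    vocab = _background_vocab(rng, spec, store)
    excluded: set[str] = set()
    for ui in spec.planted:
        excluded |= store.explode(ui)
    background_pool = sorted(set(store.descriptors) - excluded)

    journals = [f"Journal de {_pseudo_word(rng).capitalize()}" for _ in range(5)]
    countries = ["France", "Belgium", "Switzerland", "Canada"]
    pub_types = ["Journal Article", "Review", "Case Reports"]
    langs = sorted(spec.language_mix)
    weights = [spec.language_mix[l] for l in langs]

    def words(lo: int, hi: int) -> str:
        return " ".join(rng.choice(vocab) for _ in range(rng.randint(lo, hi)))

    # plan records
    plans: list[dict] = []
    key_rows: list[tuple[str, str, str, str]] = []  # filled after pmids known
    for ui in sorted(spec.planted):
        n_rel = spec.planted[ui]
        n_syn = int(round(spec.synonym_only_fraction * n_rel))
        n_partial = int(round(spec.partial_fraction * n_rel))
        kinds = ["synonym"] * n_syn + ["title"] * (n_rel - n_syn)
        rng.shuffle(kinds)
        levels = ["partially_relevant"] * n_partial + ["relevant"] * (
            n_rel - n_partial
        )
        rng.shuffle(levels)
        for kind, level in zip(kinds, levels):
            plans.append(
                {"type": "planted", "concept": ui, "evidence": kind, "level": level}
            )
    for _ in range(spec.n_citations - total_planted):
        plans.append({"type": "background"})
    rng.shuffle(plans)

    root = etree.Element("PubmedArticleSet")
    for i, plan in enumerate(plans):
        pmid = str(1000001 + i)
        art = etree.SubElement(root, "PubmedArticle")
        mc = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(mc, "PMID").text = pmid
        article = etree.SubElement(mc, "Article")
        journal = etree.SubElement(article, "Journal")
        etree.SubElement(journal, "Title").text = rng.choice(journals)
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        etree.SubElement(pubdate, "Year").text = str(
            rng.randint(*spec.year_range)
        )

        annotations: list[tuple[str, bool]] = []
        if plan["type"] == "planted":
            ui = plan["concept"]
            desc = store.descriptors[ui]
            lang = "fre"
            fr_label = desc.labels["fre"]
            if plan["evidence"] == "title":
                vtitle = f"{fr_label.capitalize()} {words(2, 5)}"
            else:
                vtitle = words(4, 7).capitalize()
            title = f"[{words(3, 6).capitalize()}]"
            syns = desc.synonyms.get("fre", [fr_label])
            abstract = f"{words(8, 15)} {rng.choice(syns)} {words(8, 15)}"
            annotations.append((ui, rng.random() < 0.8))
            key_rows.append((fr_label, pmid, plan["level"], plan["evidence"]))
        else:
            lang = rng.choices(langs, weights=weights)[0]
            vtitle = words(4, 7).capitalize() if lang != "eng" else None
            title = words(4, 7).capitalize()
            abstract = words(20, 40) if rng.random() < 0.8 else None

        if background_pool:
            for ui in rng.sample(
                background_pool, min(len(background_pool), rng.randint(1, 3))
            ):
                annotations.append((ui, rng.random() < 0.3))

        etree.SubElement(article, "ArticleTitle").text = title
        if abstract:
            ab = etree.SubElement(article, "Abstract")
            etree.SubElement(ab, "AbstractText").text = abstract
        etree.SubElement(article, "Language").text = lang
        if vtitle:
            etree.SubElement(article, "VernacularTitle").text = vtitle
        ptl = etree.SubElement(article, "PublicationTypeList")
        etree.SubElement(ptl, "PublicationType").text = rng.choice(pub_types)

        mji = etree.SubElement(mc, "MedlineJournalInfo")
        etree.SubElement(mji, "Country").text = rng.choice(countries)

        mhl = etree.SubElement(mc, "MeshHeadingList")
        for ui, major in annotations:
            heading = etree.SubElement(mhl, "MeshHeading")
            if rng.random() < spec.automatic_fraction:
                heading.set("Origin", "automatic")
            dn = etree.SubElement(heading, "DescriptorName")
            dn.set("UI", ui)
            dn.set("MajorTopicYN", "Y" if major else "N")
            dn.text = store.descriptors[ui].labels.get("eng", ui)
            if store.qualifiers and rng.random() < 0.3:
                q_ui = rng.choice(sorted(store.qualifiers))
                qn = etree.SubElement(heading, "QualifierName")
                qn.set("UI", q_ui)
                qn.set("MajorTopicYN", "N")
                qn.text = store.qualifiers[q_ui].labels.get("eng", q_ui)
        if rng.random() < 0.5:
            pd = etree.SubElement(art, "PubmedData")
            ail = etree.SubElement(pd, "ArticleIdList")
            aid = etree.SubElement(ail, "ArticleId")
            aid.set("IdType", "doi")
            aid.text = f"10.1000/synthetic.{pmid}"

    xml_path = out_dir / "citations.xml"
    xml_path.write_bytes(
        etree.tostring(
            root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
        )
    )

    key_path = out_dir / "relevance_key.tsv"
    with key_path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["query", "pmid", "level", "evidence"])
        writer.writerows(sorted(key_rows))
    return xml_path, key_path


def load_relevance_key(path: str | Path) -> dict[str, dict[str, dict[str, str]]]:
    """Read a relevance key: query → pmid → {level, evidence}."""
    out: dict[str, dict[str, dict[str, str]]] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["query"], {})[row["pmid"]] = {
                "level": row["level"],
                "evidence": row["evidence"],
            }
    return out


def judgments_from_key(
    key: Mapping[str, Mapping[str, Mapping[str, str]]],
    runs: Sequence[QueryRun] = (),
) -> dict[str, dict[str, str]]:
    """Turn a relevance key into per-query judgments; any PMID ranked by a
    run but absent from the key is judged not relevant (the key is complete
    by construction)."""
    judgments: dict[str, dict[str, str]] = {
        query: {pmid: info["level"] for pmid, info in pmids.items()}
        for query, pmids in key.items()
    }
    for run in runs:
        table = judgments.setdefault(run.query, {})
        for pmid in run.pmids:
            table.setdefault(pmid, "not_relevant")
    return judgments


# ---------------------------------------------------------------------------
# packaged study tables
# ---------------------------------------------------------------------------


@dataclass
class PaperTables:
    """The three printed evaluation tables in machine-readable form."""

    #: rows (query_fr, query_en, response_time_s, n_citations)
    response_times: list[tuple[str, str, float, int]]
    #: query_en → coverage column → total hits
    coverage: dict[str, dict[str, int]]
    #: strategy → per-query precision cells (retrieved + relevant counts)
    cells: dict[str, list[PrecisionCell]]
    #: (query_en, strategy) → (strict, relaxed) printed precision, or None
    printed_precision: dict[tuple[str, str], tuple[float, float] | None]

    def coverage_column(self, strategy: str) -> list[int]:
        column = "pubmed" if strategy in ("pubmed_lifo", "pubmed_relevance") else strategy
        return [self.coverage[q][column] for q in self.coverage]

    def retrieved(self, query: str, strategy: str) -> int:
        column = "pubmed" if strategy in ("pubmed_lifo", "pubmed_relevance") else strategy
        return min(20, self.coverage[query][column])


def _read_packaged(name: str) -> list[dict[str, str]]:
    data = resources.files("medlingua.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _TABLE_SHA256[name]:
        raise ValueError(f"packaged table {name} is corrupted (checksum mismatch)")
    return list(csv.DictReader(data.decode("utf-8").splitlines(), delimiter="\t"))


def load_paper_tables() -> PaperTables:
    """Load the packaged study tables, verifying checksums, attaching the
    footnoted retrieved counts and recovering per-query relevant counts."""
    t3 = [
        (r["query_fr"], r["query_en"], float(r["response_time_s"]), int(r["n_citations"]))
        for r in _read_packaged("table3_response_times.tsv")
    ]

    coverage: dict[str, dict[str, int]] = {}
    for r in _read_packaged("table4_coverage.tsv"):
        coverage[r["query_en"]] = {c: int(r[c]) for c in _COVERAGE_COLUMNS}
    for column, expected in TABLE4_TOTALS.items():
        total = sum(row[column] for row in coverage.values())
        if total != expected:
            raise ValueError(
                f"coverage column {column}: sum {total} != printed total {expected}"
            )

    printed: dict[tuple[str, str], tuple[float, float] | None] = {}
    cells: dict[str, list[PrecisionCell]] = {s: [] for s in STRATEGIES_PAPER}
    for r in _read_packaged("table5_precision.tsv"):
        query = r["query_en"]
        for strategy in STRATEGIES_PAPER:
            column = "pubmed" if strategy in ("pubmed_lifo", "pubmed_relevance") else strategy
            retrieved = min(20, coverage[query][column])
            foot = FOOTNOTE_RETRIEVED.get((query, strategy))
            if foot is not None and foot != retrieved:
                raise ValueError(
                    f"footnoted retrieved count mismatch for ({query}, {strategy})"
                )
            strict_raw = r[f"{strategy}_strict"]
            relaxed_raw = r[f"{strategy}_relaxed"]
            if strict_raw == "NA":
                if retrieved != 0:
                    raise ValueError(f"({query}, {strategy}): NA but retrieved > 0")
                printed[(query, strategy)] = None
                cells[strategy].append(PrecisionCell(query, strategy, 0, 0, 0))
                continue
            strict_p, relaxed_p = float(strict_raw), float(relaxed_raw)
            printed[(query, strategy)] = (strict_p, relaxed_p)
            strict_n = int(strict_p * retrieved + 0.5)
            relaxed_n = int(relaxed_p * retrieved + 0.5)
            # the reconstruction must reproduce the printed 2-dp precision
            for n, p in ((strict_n, strict_p), (relaxed_n, relaxed_p)):
                if abs(n / retrieved - p) >= 0.005 + 1e-9:
                    raise ValueError(
                        f"({query}, {strategy}): relevant-count reconstruction "
                        f"{n}/{retrieved} does not reproduce printed {p}"
                    )
            cells[strategy].append(
                PrecisionCell(query, strategy, retrieved, strict_n, relaxed_n)
            )
    return PaperTables(
        response_times=t3, coverage=coverage, cells=cells, printed_precision=printed
    )
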