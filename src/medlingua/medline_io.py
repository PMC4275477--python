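"""MEDLINE/PubMed citation XML ingestion and subset persistence.

Reads the PubmedArticleSet XML dialect, extracts a monolingual subset (e.g.
every citation whose Language list contains ``fre``) and persists it in a
compact line-delimited form: one JSON object per citation under a one-line
schema header, so subsets are streamable and diffable.

MeSH annotations keep the major-topic flag per descriptor and per qualifier.
Standard MEDLINE XML does not say whether a heading was assigned by a human
indexer or programmatically; corpora that carry this distinction mark it with
an ``Origin="automatic"`` attribute on ``MeshHeading`` (absent ⇒ human), and
the parser honors it because descriptor origin is one of the ranking
criteria downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from lxml import etree

__all__ = [
    "MeshAnnotation",
    "CitationRecord",
    "MISSING_YEAR",
    "CitationParseError",
    "parse_citations",
    "filter_language",
    "store_subset",
    "load_subset",
]

logger = logging.getLogger(__name__)

#: Sentinel for a citation without a parseable publication year.  Negative so
#: that it sorts last under the recency (descending-year) orderings used by
#: both ranking modes; such citations are kept, never silently dropped.
MISSING_YEAR = -1

_SUBSET_FORMAT = "medlingua-subset"
_SUBSET_VERSION = 1


class CitationParseError(ValueError):
    """Malformed citation XML; message carries the reported position."""


@dataclass(frozen=True)
class MeshAnnotation:
    descriptor_ui: str
    major: bool = False
    qualifiers: tuple[tuple[str, bool], ...] = ()
    origin: str = "human"  # human | automatic


@dataclass
class CitationRecord:
    """One PubMed citation with the metadata the search engine uses."""

    pmid: str
    title: str = ""
    transliterated_title: str | None = None
    abstract: str | None = None
    languages: list[str] = field(default_factory=list)
    journal_title: str = ""
    journal_country: str | None = None
    pub_year: int = MISSING_YEAR
    pub_types: list[str] = field(default_factory=list)
    doi: str | None = None
    annotations: list[MeshAnnotation] = field(default_factory=list)


def _text(elem, path: str) -> str | None:
    node = elem.find(path)
    if node is None or node.text is None:
        return None
    return node.text.strip() or None


def _parse_year(citation) -> int:
    year = _text(citation, ".//Article/Journal/JournalIssue/PubDate/Year")
    if year is None:
        medline_date = _text(
            citation, ".//Article/Journal/JournalIssue/PubDate/MedlineDate"
        )
        if medline_date:
            digits = "".join(ch for ch in medline_date[:4] if ch.isdigit())
            if len(digits) == 4:
                year = digits
    if year is None:
        return MISSING_YEAR
    try:
        return int(year)
    except ValueError:
        return MISSING_YEAR


def _parse_mesh(citation) -> list[MeshAnnotation]:
    annotations = []
    for heading in citation.findall(".//MeshHeadingList/MeshHeading"):
        dname = heading.find("DescriptorName")
        if dname is None:
            continue
        ui = dname.get("UI") or (dname.text or "").strip()
        if not ui:
            continue
        qualifiers = []
        for qname in heading.findall("QualifierName"):
            q_ui = qname.get("UI") or (qname.text or "").strip()
            if q_ui:
                qualifiers.append((q_ui, qname.get("MajorTopicYN") == "Y"))
        annotations.append(
            MeshAnnotation(
                descriptor_ui=ui,
                major=dname.get("MajorTopicYN") == "Y",
                qualifiers=tuple(qualifiers),
                origin="automatic" if heading.get("Origin") == "automatic" else "human",
            )
        )
    return annotations


def _parse_one(citation) -> CitationRecord | None:
    pmid = _text(citation, ".//MedlineCitation/PMID") or _text(citation, ".//PMID")
    if pmid is None:
        logger.warning("citation without PMID skipped")
        return None
    article = citation.find(".//Article")
    abstract_parts = [
        (n.text or "").strip()
        for n in citation.findall(".//Article/Abstract/AbstractText")
    ]
    abstract = " ".join(p for p in abstract_parts if p) or None
    doi = None
    for aid in citation.findall(".//ArticleIdList/ArticleId"):
        if aid.get("IdType") == "doi" and aid.text:
            doi = aid.text.strip()
    return CitationRecord(
        pmid=pmid,
        title=_text(citation, ".//Article/ArticleTitle") or "",
        transliterated_title=_text(citation, ".//Article/VernacularTitle"),
        abstract=abstract,
        languages=[
            (n.text or "").strip()
            for n in citation.findall(".//Article/Language")
            if (n.text or "").strip()
        ],
        journal_title=_text(citation, ".//Article/Journal/Title") or "",
        journal_country=_text(citation, ".//MedlineJournalInfo/Country"),
        pub_year=_parse_year(citation),
        pub_types=[
            (n.text or "").strip()
            for n in citation.findall(".//PublicationTypeList/PublicationType")
            if (n.text or "").strip()
        ],
        doi=doi,
        annotations=_parse_mesh(citation),
    )


def parse_citations(xml_source: str | Path | IO) -> list[CitationRecord]:
    """Parse a PubmedArticleSet document into citation records, in document
    order.  Citations missing a PMID are skipped with a logged warning;
    malformed XML raises :class:`CitationParseError` naming the position."""
    try:
        tree = etree.parse(xml_source)
    except etree.XMLSyntaxError as exc:
        raise CitationParseError(
            f"malformed citation XML at line {exc.lineno}, column "
            f"{getattr(exc, 'offset', 0)}: {exc.msg}"
        ) from exc
    root = tree.getroot()
    records = []
    for citation in root.iter("PubmedArticle"):
        record = _parse_one(citation)
        if record is not None:
            records.append(record)
    return records


def filter_language(
    records: Iterable[CitationRecord], lang: str, plausibility: bool = False
) -> list[CitationRecord]:
    """Keep citations whose language list contains ``lang``, preserving order.

    PubMed's language tags are occasionally wrong; with ``plausibility`` on,
    a citation must additionally carry an original-language (vernacular)
    title — a proxy for genuinely non-English text.  The filtered set under
    the plausibility rule is always a subset of the plain tag filter.
    """
    out = []
    for record in records:
        if lang not in record.languages:
            continue
        if plausibility and not record.transliterated_title:
            continue
        out.append(record)
    return out


def _record_to_json(record: CitationRecord) -> str:
    payload = asdict(record)
    payload["annotations"] = [
        {
            "descriptor_ui": a.descriptor_ui,
            "major": a.major,
            "qualifiers": [list(q) for q in a.qualifiers],
            "origin": a.origin,
        }
        for a in record.annotations
    ]
    return json.dumps(payload, ensure_ascii=False, sort_keys=True)


def _record_from_json(line: str) -> CitationRecord:
    payload = json.loads(line)
    payload["annotations"] = [
        MeshAnnotation(
            descriptor_ui=a["descriptor_ui"],
            major=a["major"],
            qualifiers=tuple((q[0], q[1]) for q in a["qualifiers"]),
            origin=a["origin"],
        )
        for a in payload["annotations"]
    ]
    return CitationRecord(**payload)


def store_subset(records: Iterable[CitationRecord], path: str | Path) -> int:
    """Write records to a line-delimited subset file; returns the count."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps({"format": _SUBSET_FORMAT, "version": _SUBSET_VERSION}))
        fh.write("\n")
        for record in records:
            fh.write(_record_to_json(record))
            fh.write("\n")
            n += 1
    return n


def load_subset(path: str | Path) -> list[CitationRecord]:
    """Read a subset file written by :func:`store_subset`.

    ``load_subset(store_subset(x))`` is the identity, field for field.
    Raises ``ValueError`` on a missing/mismatched schema header.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError:
            header = {}
        if header.get("format") != _SUBSET_FORMAT:
            raise ValueError(f"{path}: not a {_SUBSET_FORMAT} file")
        if header.get("version") != _SUBSET_VERSION:
            raise ValueError(
                f"{path}: schema version {header.get('version')} "
                f"(expected {_SUBSET_VERSION})"
            )
        return [_record_from_json(line) for line in fh if line.strip()]


def iter_subset(path: str | Path) -> Iterator[CitationRecord]:
    """Streaming variant of :func:`load_subset`."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        if header.get("format") != _SUBSET_FORMAT:
            raise ValueError(f"{path}: not a {_SUBSET_FORMAT} file")
        for line in fh:
            if line.strip():
                yield _record_from_json(line)
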