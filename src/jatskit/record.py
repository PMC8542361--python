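"""The unified decoded article: one record bundling every extractor.

``decode_article`` runs all extractors over one JATS/NXML file (or an
already-read document) and returns an :class:`ArticleRecord` with
metadata, publication history, contributors, affiliations, countries,
abstract, sectioned text and the reference list.  Records serialize to
plain dictionaries (JSON for a single article, NDJSON for a corpus).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

from . import contributors, metadata, textparts
from .jats_io import RawDocument, read_jats
from .metadata import DateStampSet, PartialDate

__all__ = ["ArticleRecord", "decode_article", "record_to_dict", "write_ndjson"]


@dataclass
class ArticleRecord:
    """Everything decoded from one article."""

    source_path: str = ""
    title: str | None = None
    journal: str | None = None
    doi: str | None = None
    type: str | None = None
    volume: str | None = None
    subjects: tuple[str, ...] = ()
    keywords: tuple[str, ...] = ()
    authors: list[contributors.PersonName] = field(default_factory=list)
    editors: list[contributors.PersonName] = field(default_factory=list)
    affiliations: list[contributors.AffiliationEntry] = field(default_factory=list)
    countries: tuple[str, ...] = ()
    history: DateStampSet = field(default_factory=DateStampSet)
    pub_date: PartialDate | None = None
    pub_year: int | None = None
    time_to_accept: int | None = None
    time_to_publish: int | None = None
    abstract: str = ""
    abstract_present: bool = False
    sections: list[textparts.Section] = field(default_factory=list)
    text_present: bool = False
    references: list[textparts.Reference] = field(default_factory=list)

    @property
    def international(self) -> bool:
        """More than one extractable country of origin."""
        return len(self.countries) > 1


def decode_article(
    source: str | Path | RawDocument,
    sectionsplit: list[str] | None = None,
    shorten_given: bool = False,
) -> ArticleRecord:
    """Decode one JATS/NXML article into an :class:`ArticleRecord`.

    ``sectionsplit`` optionally merges the flattened section list into
    main sections; ``shorten_given`` abbreviates given names to initials.
    """
    doc = source if isinstance(source, RawDocument) else read_jats(source)

    stamps = metadata.get_history(doc)
    pub_date, pub_year = metadata.compute_pub_date(stamps)
    t_accept, t_publish = metadata.publication_lags(stamps, pub_date)

    affs = contributors.get_affiliations(doc)
    countries = tuple(sorted({c for a in affs for c in a.countries}))

    abstract, abstract_present = textparts.get_abstract(doc)
    sections = textparts.get_sections(doc)
    if sectionsplit:
        sections = textparts.split_into_main_sections(sections, sectionsplit)
    body_text = " ".join(s.text for s in sections).strip()
    text_present = len(body_text) >= textparts.MIN_TEXT_CHARS

    return ArticleRecord(
        source_path=doc.source_path,
        title=metadata.get_simple_tag(doc, "title"),
        journal=metadata.get_simple_tag(doc, "journal"),
        doi=metadata.get_simple_tag(doc, "doi"),
        type=metadata.get_simple_tag(doc, "type"),
        volume=metadata.get_simple_tag(doc, "volume"),
        subjects=metadata.get_subjects(doc),
        keywords=metadata.get_keywords(doc),
        authors=contributors.get_contributors(doc, "author", shorten_given),
        editors=contributors.get_contributors(doc, "editor", shorten_given),
        affiliations=affs,
        countries=countries,
        history=stamps,
        pub_date=pub_date,
        pub_year=pub_year,
        time_to_accept=t_accept,
        time_to_publish=t_publish,
        abstract=abstract,
        abstract_present=abstract_present,
        sections=sections,
        text_present=text_present,
        references=textparts.get_references(doc),
    )


def _date_to_list(d: PartialDate | None) -> list[int | None] | None:
    return None if d is None else [d.year, d.month, d.day]


def record_to_dict(record: ArticleRecord) -> dict[str, Any]:
    """A JSON-serializable view of a record (stable key order)."""
    return {
        "source_path": record.source_path,
        "title": record.title,
        "journal": record.journal,
        "doi": record.doi,
        "type": record.type,
        "volume": record.volume,
        "subjects": list(record.subjects),
        "keywords": list(record.keywords),
        "authors": [
            {"surname": p.surname, "given": p.given, "ids": [list(i) for i in p.ids]}
            for p in record.authors
        ],
        "editors": [
            {"surname": p.surname, "given": p.given, "ids": [list(i) for i in p.ids]}
            for p in record.editors
        ],
        "affiliations": [
            {"text": a.text, "countries": list(a.countries)} for a in record.affiliations
        ],
        "countries": list(record.countries),
        "history": {lbl: _date_to_list(d) for lbl, d in record.history.stamps.items()},
        "pub_date": _date_to_list(record.pub_date),
        "pub_year": record.pub_year,
        "time_to_accept": record.time_to_accept,
        "time_to_publish": record.time_to_publish,
        "abstract": record.abstract,
        "abstract_present": record.abstract_present,
        "sections": [{"title": s.title, "text": s.text} for s in record.sections],
        "text_present": record.text_present,
        "references": [r.raw for r in record.references],
    }


def write_ndjson(records: Iterable[ArticleRecord], path: str | Path) -> int:
    """Write records as NDJSON (one JSON object per line, UTF-8)."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps(record_to_dict(record), ensure_ascii=False) + "\n")
            n += 1
    return n
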