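"""Simple metadata tags and the publication history.

The publication history of a JATS article lives in ``<date>`` elements
inside ``<history>`` and in ``<pub-date>`` elements, each labelled with a
date type.  Fourteen distinct labels occur in the wild; six of them mark
actual publication events and feed the unified earliest publication date
(``pub_date``/``pub_year``).  Stamps may omit month and day; for
comparisons the missing parts are completed to 1 while the raw partial
values are preserved.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field

from . import charconv
from .jats_io import RawDocument, TagFragment, extract_fragments, fragment_text

logger = logging.getLogger(__name__)

__all__ = [
    "PartialDate",
    "DateStampSet",
    "SimpleMeta",
    "HISTORY_LABELS",
    "PUBLICATION_EVENT_LABELS",
    "OTHER_LABEL",
    "get_simple_tag",
    "get_subjects",
    "get_keywords",
    "get_history",
    "compute_pub_date",
    "publication_lags",
]

#: The recognized history date-stamp label vocabulary (14 labels).
HISTORY_LABELS = frozenset({
    "accepted", "collection", "ecorrected", "epreprint", "epub",
    "nihms_submitted", "pmc-release", "ppub", "print", "pub",
    "received", "retracted", "rev-recd", "submitted",
})

#: The six labels that mark a publication event and are candidates for
#: the unified earliest publication date.  The remaining eight labels
#: denote editorial or administrative events (received, accepted, ...).
PUBLICATION_EVENT_LABELS = frozenset({
    "epub", "ppub", "print", "pub", "collection", "pmc-release",
})

#: Catch-all bucket for unrecognized labels.
OTHER_LABEL = "other"


@dataclass(frozen=True, order=True)
class PartialDate:
    """A date stamp whose month and/or day may be missing."""

    year: int
    month: int | None = None
    day: int | None = None

    def completed(self) -> dt.date:
        """The comparable form: missing month and day substitute 1."""
        return dt.date(self.year, self.month or 1, self.day or 1)

    def __str__(self) -> str:
        parts = [str(self.year)]
        parts.append(str(self.month) if self.month else "NA")
        parts.append(str(self.day) if self.day else "NA")
        return "-".join(parts)


@dataclass
class DateStampSet:
    """Labelled history date stamps of one article."""

    stamps: dict[str, PartialDate] = field(default_factory=dict)

    def add(self, label: str, date: PartialDate) -> None:
        """Store a stamp; unknown labels go to the catch-all bucket, a
        duplicate label keeps the first stamp seen."""
        if label not in HISTORY_LABELS:
            logger.info("unknown history label %r stored under %r", label, OTHER_LABEL)
            label = OTHER_LABEL
        if label in self.stamps:
            logger.info("duplicate history label %r; keeping first stamp", label)
            return
        self.stamps[label] = date

    def __len__(self) -> int:
        return len(self.stamps)

    def get(self, label: str) -> PartialDate | None:
        return self.stamps.get(label)


@dataclass(frozen=True)
class SimpleMeta:
    """The uniformly used one-value metadata tags plus subject/keyword lists."""

    title: str | None = None
    journal: str | None = None
    doi: str | None = None
    type: str | None = None
    volume: str | None = None
    subjects: tuple[str, ...] = ()
    keywords: tuple[str, ...] = ()


_SIMPLE_TAGS = {
    "title": "article-title",
    "journal": "journal-title",
    "volume": "volume",
}


def get_simple_tag(doc: RawDocument | str, which: str) -> str | None:
    """Extract one of the simple metadata fields.

    ``which`` is one of ``title``, ``journal``, ``doi``, ``type``,
    ``volume``.  The value comes back entity-converted, tag-stripped and
    trimmed; absence is ``None``, never an empty string.
    """
    if which == "type":
        for frag in extract_fragments(doc, "article"):
            value = frag.attributes.get("article-type")
            if value:
                return value.strip()
        return None
    if which == "doi":
        for frag in extract_fragments(doc, "article-id"):
            if frag.attributes.get("pub-id-type", "").lower() == "doi":
                value = charconv.convert_letters(fragment_text(frag))
                if value:
                    return value
        return None
    try:
        tag = _SIMPLE_TAGS[which]
    except KeyError:
        raise ValueError(f"unsupported simple field: {which!r}") from None
    fragments = extract_fragments(doc, tag)
    if which == "journal":
        # tolerate <journal-title-group> absence and bare <journal-title>
        fragments = fragments or extract_fragments(doc, "journal-id")
    if which == "volume":
        # <volume> also occurs inside references; take the front-matter one,
        # i.e. the first occurrence outside any <ref> element
        content = doc.content if isinstance(doc, RawDocument) else doc
        back = content.find("<back")
        fragments = [f for f in fragments if back < 0 or content.find(f.raw_xml) < back]
    for frag in fragments:
        value = charconv.convert_letters(fragment_text(frag))
        if value:
            return value
    return None


def _dedupe(values: list[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for v in values:
        if v and v not in seen:
            seen[v] = None
    return tuple(seen)


_SEPARATOR_ONLY = re.compile(r"^[\s,;/|·•]*$")


def get_subjects(doc: RawDocument | str) -> tuple[str, ...]:
    """All ``<subject>`` entries flattened across ``<subj-group>`` nesting."""
    values = [charconv.convert_letters(fragment_text(f))
              for f in extract_fragments(doc, "subject")]
    return _dedupe(values)


def get_keywords(doc: RawDocument | str) -> tuple[str, ...]:
    """All ``<kwd>`` entries; separator-only entries are dropped."""
    values = []
    for frag in extract_fragments(doc, "kwd"):
        value = charconv.convert_letters(fragment_text(frag))
        if not _SEPARATOR_ONLY.match(value):
            values.append(value)
    return _dedupe(values)


def _int_or_none(text: str | None) -> int | None:
    if text is None:
        return None
    m = re.search(r"\d+", text)
    return int(m.group(0)) if m else None


def _parse_stamp(frag: TagFragment) -> tuple[str | None, PartialDate | None]:
    label = (
        frag.attributes.get("date-type")
        or frag.attributes.get("pub-type")
        or frag.attributes.get("publication-format")
    )
    label = label.strip().lower().replace("-", "_") if label else None
    # two vocabulary labels genuinely contain a hyphen
    if label in {"pmc_release", "rev_recd"}:
        label = label.replace("_", "-")
    parts = {}
    for name in ("year", "month", "day"):
        sub = extract_fragments(frag.raw_xml, name)
        parts[name] = _int_or_none(fragment_text(sub[0])) if sub else None
    year, month, day = parts["year"], parts["month"], parts["day"]
    if year is None:
        logger.info("history stamp %r dropped: no usable year", label)
        return label, None
    if month is not None and not 1 <= month <= 12:
        logger.info("history stamp %r dropped: month %s out of range", label, month)
        return label, None
    if day is not None and not 1 <= day <= 31:
        logger.info("history stamp %r dropped: day %s out of range", label, day)
        return label, None
    try:
        dt.date(year, month or 1, day or 1)
    except ValueError:
        logger.info("history stamp %r dropped: invalid date %s-%s-%s", label, year, month, day)
        return label, None
    return label, PartialDate(year, month, day)


def get_history(doc: RawDocument | str) -> DateStampSet:
    """Extract all labelled date stamps from ``<history>`` and ``<pub-date>``.

    Stamps without a usable year or with out-of-range month/day are
    dropped and logged.  Raw partial values are preserved; completion to
    the first of the month/year happens only when dates are compared.
    """
    stamps = DateStampSet()
    fragments: list[TagFragment] = []
    for hist in extract_fragments(doc, "history"):
        fragments.extend(extract_fragments(hist.raw_xml, "date"))
    fragments.extend(extract_fragments(doc, "pub-date"))
    for frag in fragments:
        label, date = _parse_stamp(frag)
        if label is None:
            logger.info("unlabelled date stamp skipped")
            continue
        if date is not None:
            stamps.add(label, date)
    return stamps


def compute_pub_date(stamps: DateStampSet) -> tuple[PartialDate | None, int | None]:
    """The unified earliest publication date and year.

    ``pub_date`` is the minimum completed date over the six
    publication-event labels present; ``pub_year`` its year.  When none
    of the six is present, ``pub_year`` falls back to the earliest year
    over all stamps.  Both are ``None`` only when no stamp has a year.
    """
    candidates = [d for lbl, d in stamps.stamps.items() if lbl in PUBLICATION_EVENT_LABELS]
    if candidates:
        pub = min(candidates, key=PartialDate.completed)
        return pub, pub.year
    years = [d.year for d in stamps.stamps.values()]
    return None, (min(years) if years else None)


def publication_lags(
    stamps: DateStampSet, pub_date: PartialDate | None
) -> tuple[int | None, int | None]:
    """Day lags of the editorial process, on completed dates.

    ``time_to_accept`` = accept date − receive date;
    ``time_to_publish`` = publication date − accept date.  Either is
    ``None`` when an operand is missing; negative values are preserved —
    they are the date-error anomaly signal.
    """
    received = stamps.get("received")
    accepted = stamps.get("accepted")
    time_to_accept = None
    if received is not None and accepted is not None:
        time_to_accept = (accepted.completed() - received.completed()).days
    time_to_publish = None
    if accepted is not None and pub_date is not None:
        time_to_publish = (pub_date.completed() - accepted.completed()).days
    return time_to_accept, time_to_publish
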