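"""Abstract, sectioned body text, sentence segmentation and references.

Text sectioning is implemented inconsistently across journals, so
sections and subsections are not differentiated: the body flattens to
one sequential list of (title, text) pairs in reading order.  A list of
``sectionsplit`` substring patterns can then merge that list into main
sections (intro/method/result/discussion style): each section whose
title contains a pattern starts a group that absorbs all following
non-matching sections.

The 30-character presence rule applies to the abstract and the body
text: shorter extracted text counts as not present.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from . import charconv
from .jats_io import RawDocument, extract_fragments, fragment_text

logger = logging.getLogger(__name__)

__all__ = [
    "Section",
    "Reference",
    "MIN_TEXT_CHARS",
    "get_abstract",
    "get_sections",
    "split_into_main_sections",
    "text2sentences",
    "get_references",
]

#: Extracted abstract or body text shorter than this counts as not present.
MIN_TEXT_CHARS = 30


@dataclass(frozen=True)
class Section:
    """A section title plus its floating text (markup-free)."""

    title: str
    text: str
    merged_titles: tuple[str, ...] = ()

    def titles(self) -> tuple[str, ...]:
        return self.merged_titles or (self.title,)


@dataclass(frozen=True)
class Reference:
    """One cleaned reference string and its position in the list."""

    raw: str
    index: int


_STRIP_ELEMENTS = re.compile(
    r"<(fig|table-wrap|table|graphic|inline-graphic|supplementary-material|media)"
    r"(?=[\s/>])[^>]*(?:/>|>.*?</\1\s*>)",
    re.S,
)
_FORMULA = re.compile(
    r"<(inline-formula|disp-formula|mml:math|math|tex-math)(?=[\s/>])[^>]*"
    r"(?:/>|>.*?</\1\s*>)",
    re.S,
)


def _clean_body_xml(raw: str) -> str:
    """Drop figures/tables, flatten formulas, leave the rest for text extraction."""
    raw = _STRIP_ELEMENTS.sub(" ", raw)
    raw = _FORMULA.sub(lambda m: " " + charconv.flatten_math(m.group(0)) + " ", raw)
    return raw


def get_abstract(
    doc: RawDocument | str, as_sentences: bool = False
) -> tuple[str | list[str], bool]:
    """The abstract text (or its sentence list) plus a presence flag.

    Presence is false when the tag is absent or the extracted text has
    fewer than 30 characters.
    """
    fragments = extract_fragments(doc, "abstract")
    if not fragments:
        return ([] if as_sentences else ""), False
    raw = _clean_body_xml(fragments[0].raw_xml)
    # structured abstracts carry their own inner titles; keep them inline
    text = charconv.convert_letters(fragment_text(raw))
    present = len(text) >= MIN_TEXT_CHARS
    if as_sentences:
        return text2sentences(text), present
    return text, present


def get_sections(doc: RawDocument | str) -> list[Section]:
    """Flatten the article body into a sequential list of sections.

    Sections and subsections are not differentiated: every titled
    ``<sec>`` yields one entry in reading order, its text being the
    floating text directly under it (nested subsection content belongs
    to the nested entry).  Untitled leading body text becomes a section
    with an empty title.  No body -> empty list.
    """
    bodies = extract_fragments(doc, "body")
    if not bodies:
        return []
    raw = _clean_body_xml(bodies[0].raw_xml)
    sections: list[Section] = []

    def walk(fragment_xml: str, inner: str) -> None:
        # split the element's inner XML into own text vs nested <sec> blocks
        sec_frags = extract_fragments(inner, "sec")
        own = inner
        for sf in sec_frags:
            own = own.replace(sf.raw_xml, "\x01", 1)
        titles = extract_fragments(own, "title")
        title = charconv.convert_letters(fragment_text(titles[0])) if titles else ""
        if titles:
            own = own.replace(titles[0].raw_xml, " ", 1)
        text = charconv.convert_letters(fragment_text(own.replace("\x01", " ")))
        if title or text:
            sections.append(Section(title=title, text=text))
        for sf in sec_frags:
            body_inner = sf.raw_xml[sf.raw_xml.index(">") + 1 :]
            body_inner = re.sub(r"</sec\s*>\s*$", "", body_inner)
            walk(sf.raw_xml, body_inner)

    body_inner = raw[raw.index(">") + 1 :]
    body_inner = re.sub(r"</body\s*>\s*$", "", body_inner)
    walk(raw, body_inner)
    return sections


def split_into_main_sections(
    sections: list[Section], sectionsplit: list[str]
) -> list[Section]:
    """Merge a flat section list into main sections.

    A section whose title contains any pattern (case-insensitive
    substring) starts a group; following non-matching sections append
    their text (blank-line separated) and their title to the group's
    merged-titles list.  Sections before the first match form one
    leading group.  An empty pattern list returns the input unchanged.
    """
    if not sectionsplit:
        return list(sections)
    patterns = [p.lower() for p in sectionsplit]

    def matches(title: str) -> bool:
        lowered = title.lower()
        return any(p in lowered for p in patterns)

    groups: list[list[Section]] = []
    for sec in sections:
        if matches(sec.title) or not groups:
            groups.append([sec])
        else:
            groups[-1].append(sec)
    merged = []
    for group in groups:
        titles = tuple(s.title for s in group)
        text = "\n\n".join(s.text for s in group)
        merged.append(Section(title=group[0].title, text=text, merged_titles=titles))
    return merged


@lru_cache(maxsize=1)
def _abbreviations() -> tuple[str, ...]:
    text = resources.files("jatskit.data").joinpath("abbreviations.txt").read_text("utf-8")
    abbrs = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
    return tuple(sorted(abbrs, key=len, reverse=True))


_DECIMAL_DOT = re.compile(r"(?<=\d)\.(?=\d)|(?<=[=<>(\s])\.(?=\d)")
_INITIAL_DOT = re.compile(r"\b([A-Z])\.(?=\s+[A-Z])")
_ENUM_DOT = re.compile(r"(?<=[\s(])(\d{1,3}|[ivxIVX]{1,4}|[a-zA-Z])\.(?=\s)")
_BOUNDARY = re.compile(r"([.!?]+[\"'”’)\]]?)\s+(?=[\"'“‘(\[]?[A-Z0-9])")
_DOT = "\x00"


def text2sentences(text: str) -> list[str]:
    """Split floating text into sentences.

    Boundaries are sentence-final ``.``/``!``/``?`` followed by
    whitespace and an uppercase letter or digit.  Dots inside decimal
    numbers (``p = .05``, ``3.14``), known abbreviations (``e.g.``,
    ``et al.``, ``Fig.``), single initials (``J. R.``) and short
    enumerators are protected.  Joining the result with single spaces
    reproduces the input up to whitespace normalization.
    """
    # C0 control characters carry no text content and would collide with
    # the masking sentinel; drop them before normalizing whitespace
    text = re.sub(r"[\x00-\x08\x0e-\x1f]", "", text)
    text = re.sub(r"\s+", " ", text).strip()
    if not text:
        return []
    masked = text
    for abbr in _abbreviations():
        # word boundary so "universal." is not mistaken for "al."
        masked = re.sub(
            rf"\b{re.escape(abbr)}", abbr.replace(".", _DOT), masked
        )
    masked = _DECIMAL_DOT.sub(_DOT, masked)
    masked = _INITIAL_DOT.sub(rf"\1{_DOT}", masked)
    masked = _ENUM_DOT.sub(rf"\1{_DOT}", masked)
    pieces = _BOUNDARY.split(masked)
    # re-join the captured terminators with their sentences
    sentences = []
    for i in range(0, len(pieces), 2):
        sentence = pieces[i] + (pieces[i + 1] if i + 1 < len(pieces) else "")
        sentence = sentence.replace(_DOT, ".").strip()
        if sentence:
            sentences.append(sentence)
    return sentences


def get_references(doc: RawDocument | str) -> list[Reference]:
    """The back-matter reference list as cleaned strings, in listed order.

    Free-text (``mixed-citation``) and structured (``element-citation``)
    entries both render to one string; structured parts are joined in
    document order with comma separators.
    """
    refs = []
    ref_frags = []
    for back in extract_fragments(doc, "ref-list") or extract_fragments(doc, "back"):
        ref_frags.extend(extract_fragments(back.raw_xml, "ref"))
    part_tags = (
        "name|string-name|collab|article-title|source|year|volume|issue|"
        "fpage|lpage|page-range|elocation-id|publisher-name|publisher-loc|"
        "pub-id|edition|comment"
    )
    for frag in ref_frags:
        raw = re.sub(r"<label>.*?</label>", "", frag.raw_xml, flags=re.S)
        if re.search(r"<element-citation(?=[\s/>])", raw):
            raw = re.sub(r"</(?:surname|prefix)\s*>", " ", raw)
            raw = re.sub(rf"</(?:{part_tags})\s*>", "\x01", raw)
            text = charconv.convert_letters(fragment_text(raw))
            parts = [p.strip(" ,;") for p in text.split("\x01") if p.strip(" ,;")]
            cleaned = ", ".join(parts)
        else:
            cleaned = charconv.convert_letters(fragment_text(raw))
        cleaned = cleaned.strip()
        if cleaned:
            refs.append(Reference(raw=cleaned, index=len(refs)))
    return refs
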