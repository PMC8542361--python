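"""Contributor names, contributor IDs, affiliations and countries.

Name representation varies widely across journals: some supply fully
capitalized names, some abbreviate given names, and affiliation detail
ranges from fully tagged institution/address/country structures to one
untagged line.  This module normalizes names to initial-capital form,
optionally shortens given names to initials, flattens affiliations to a
comma-separated string, and unifies country spellings against a shipped
dictionary of canonical names and aliases, matched at the end of each
affiliation address.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from . import charconv
from .jats_io import RawDocument, TagFragment, extract_fragments, fragment_text

logger = logging.getLogger(__name__)

__all__ = [
    "PersonName",
    "AffiliationEntry",
    "get_contributors",
    "get_affiliations",
    "get_countries",
    "recase_allcaps",
    "country_dictionary",
]


@dataclass(frozen=True)
class PersonName:
    """A contributor: surname/given-name pair plus optional IDs."""

    surname: str
    given: str
    role: str = "author"
    ids: tuple[tuple[str, str], ...] = ()

    def display(self) -> str:
        if self.surname and self.given:
            return f"{self.surname}, {self.given}"
        return self.surname or self.given


@dataclass(frozen=True)
class AffiliationEntry:
    """One ``<aff>`` element: cleaned comma-separated text + countries."""

    text: str
    countries: tuple[str, ...] = ()


def _recase_token(token: str) -> str:
    if len(token) >= 2 and token.isalpha() and token.isupper():
        return token[0] + token[1:].lower()
    return token


def recase_allcaps(name: str) -> str:
    """Convert fully capitalized name tokens to initial-capital form.

    Only strictly all-caps alphabetic tokens of length >= 2 are touched
    (per space- or hyphen-separated token), so mixed-case names like
    ``McDonald`` and lowercase particles like ``van`` survive untouched.
    """
    return re.sub(r"[^\s\-]+", lambda m: _recase_token(m.group(0)), name)


def _shorten_given(given: str) -> str:
    def initial(tok: str) -> str:
        return tok[0] + "." if tok and tok[0].isalpha() else tok

    parts = [
        "-".join(initial(t) for t in word.split("-"))
        for word in given.split()
    ]
    return " ".join(p for p in parts if p)


_ORCID = re.compile(r"\d{4}-\d{4}-\d{4}-\d{3}[\dX]")


def _harvest_ids(frag: TagFragment) -> tuple[tuple[str, str], ...]:
    ids = []
    for id_frag in extract_fragments(frag.raw_xml, "contrib-id"):
        value = fragment_text(id_frag).strip()
        if not value:
            continue
        scheme = id_frag.attributes.get("contrib-id-type", "").strip().lower()
        if not scheme:
            scheme = "orcid" if _ORCID.search(value) else "unknown"
        ids.append((scheme, value))
    return tuple(ids)


def get_contributors(
    doc: RawDocument | str, role: str = "author", shorten_given: bool = False
) -> list[PersonName]:
    """Extract contributor names of one role, in document order.

    All-caps surnames/given names are recased to initial capitals; with
    ``shorten_given`` each given-name token reduces to its first letter
    plus period.  Contributor IDs (ORCID and friends) are harvested with
    their scheme.  A contributor with neither surname nor given name is
    skipped and logged.
    """
    if role not in {"author", "editor"}:
        raise ValueError(f"unsupported contributor role: {role!r}")
    people = []
    for frag in extract_fragments(doc, "contrib"):
        ctype = frag.attributes.get("contrib-type", "author").strip().lower()
        if ctype != role:
            continue
        surname_frags = extract_fragments(frag.raw_xml, "surname")
        given_frags = extract_fragments(frag.raw_xml, "given-names")
        surname = charconv.convert_letters(fragment_text(surname_frags[0])) if surname_frags else ""
        given = charconv.convert_letters(fragment_text(given_frags[0])) if given_frags else ""
        if not surname and not given:
            logger.info("contributor without surname or given name skipped")
            continue
        surname = recase_allcaps(surname)
        given = recase_allcaps(given)
        if shorten_given and given:
            given = _shorten_given(given)
        people.append(PersonName(surname, given, role=role, ids=_harvest_ids(frag)))
    return people


_LABEL_MARKER = re.compile(r"^\s*[\dA-Za-z]\s*$|^\s*[*†‡§¶#]+\s*$")


def get_affiliations(doc: RawDocument | str) -> list[AffiliationEntry]:
    """One entry per ``<aff>`` element, tags removed.

    Tagged parts (institution, address line, country, ...) are joined
    with ``", "`` in document order; label markers (superscript letters
    or numbers used to link authors to affiliations) are stripped;
    untagged one-line affiliations pass through with cleanup only.
    """
    part_tags = (
        "institution|institution-wrap|addr-line|country|city|state|"
        "postal-code|named-content|email|phone|fax"
    )
    sep = "\x01"  # not whitespace, survives cleanup
    entries = []
    for frag in extract_fragments(doc, "aff"):
        raw = frag.raw_xml
        # drop linking labels and superscript markers
        raw = re.sub(r"<label>.*?</label>|<sup>.*?</sup>", "", raw, flags=re.S)
        # structural part boundaries become soft separators, then cleanup
        raw = re.sub(rf"</(?:{part_tags})>", sep, raw)
        text = charconv.convert_letters(fragment_text(raw))
        pieces = [p.strip(" ,;") for p in text.split(sep)]
        pieces = [p for p in pieces if p and not _LABEL_MARKER.match(p)]
        text = ", ".join(pieces)
        text = re.sub(r"\s*,\s*,+\s*", ", ", text).strip(" ,")
        if not text:
            continue
        explicit = [
            charconv.convert_letters(fragment_text(c))
            for c in extract_fragments(frag.raw_xml, "country")
        ]
        entries.append(
            AffiliationEntry(text=text, countries=get_countries([text], explicit))
        )
    return entries


@lru_cache(maxsize=1)
def country_dictionary() -> tuple[frozenset[str], dict[str, str]]:
    """(canonical names, lowercase alias -> canonical name)."""
    data = resources.files("jatskit.data")
    canonical = frozenset(
        line.strip()
        for line in data.joinpath("countries.txt").read_text("utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    )
    aliases = {name.lower(): name for name in canonical}
    for line in data.joinpath("country_aliases.tsv").read_text("utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        alias, name = line.split("\t")
        aliases[alias.strip().lower()] = name.strip()
    return canonical, aliases


_TRAILING_JUNK = re.compile(
    r"(?:[\s,;.:()\[\]\d/-]|e-?mail\s*:?\s*\S*|@\S+)+$", re.I
)


def _match_end(text: str, aliases: dict[str, str]) -> str | None:
    trimmed = _TRAILING_JUNK.sub("", text).rstrip()
    # a trailing period may belong to the alias itself (e.g. "Rep. of China")
    for candidate in (trimmed, trimmed + "."):
        lowered = candidate.lower()
        for alias, name in aliases.items():
            if lowered.endswith(alias):
                before = lowered[: -len(alias)]
                if not before or not (before[-1].isalpha() or before[-1] == "."):
                    return name
    return None


def get_countries(
    aff_texts: list[str] | list[AffiliationEntry],
    country_tags: list[str] | None = None,
) -> tuple[str, ...]:
    """Unified country names for a set of affiliations.

    Explicit ``<country>`` tag content is preferred; otherwise the
    dictionary search is anchored at the *end* of each affiliation string
    (after stripping trailing punctuation, postal codes and e-mail
    addresses), so an institution name like "Georgia Institute of
    Technology" mid-string never counts as a country.  Output is unique,
    sorted, possibly empty.
    """
    _, aliases = country_dictionary()
    found = set()
    for tag in country_tags or []:
        tag = tag.strip()
        if not tag:
            continue
        name = aliases.get(tag.lower()) or _match_end(tag, aliases)
        if name:
            found.add(name)
        else:
            logger.info("unrecognized country tag %r", tag)
    if not found:
        for entry in aff_texts:
            text = entry.text if isinstance(entry, AffiliationEntry) else entry
            name = _match_end(text, aliases)
            if name:
                found.add(name)
    return tuple(sorted(found))
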