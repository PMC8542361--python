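"""Unify character representations in article text.

Scholarly XML mixes hexadecimal (``&#x3b1;``) and decimal (``&#945;``)
numeric entities, named HTML entities, more than twenty distinct space
codings, half a dozen dashes, and styled (bold/italic/script/
double-struck) variants of the same letter.  This module folds all of
them onto one plain representation so downstream search and text
processing can rely on a single spelling:

* numeric and named entities -> Unicode characters,
* every space coding -> a plain space, every dash -> ``-``,
* styled math-alphanumeric letters -> their plain equivalent,
* markup tags and hyperlinks removed, spacing errors corrected,
* MathML / LaTeX-style formulas flattened to plain text.

All public functions are idempotent: converting already-converted text
changes nothing.
"""

from __future__ import annotations

import html
import html.entities
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .jats_io import TagFragment

logger = logging.getLogger(__name__)

__all__ = [
    "EntityTable",
    "entity_table",
    "convert_letters",
    "flatten_math",
    "fix_spacing",
    "strip_tags",
]

_SOFT_HYPHEN = "­"


@dataclass(frozen=True)
class EntityTable:
    """Character-unification tables shipped with the package."""

    entity_to_char: dict[str, str]
    space_codings: frozenset[str]
    hyphen_codings: frozenset[str]
    synonym_map: dict[str, str] = field(repr=False)


def _load_codepoints(filename: str) -> frozenset[str]:
    text = resources.files("jatskit.data").joinpath(filename).read_text("utf-8")
    points = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        points.add(chr(int(line.split("\t")[0], 16)))
    return frozenset(points)


def _load_synonyms() -> dict[str, str]:
    text = resources.files("jatskit.data").joinpath("char_synonyms.tsv").read_text("utf-8")
    table = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        cp, plain = line.split("\t")
        table[chr(int(cp, 16))] = plain
    return table


@lru_cache(maxsize=1)
def entity_table() -> EntityTable:
    """The loaded character-unification tables (singleton)."""
    named = {
        name: char
        for name, char in html.entities.html5.items()
        if len(unicodedata.normalize("NFC", char)) == 1
    }
    return EntityTable(
        entity_to_char=named,
        space_codings=_load_codepoints("space_codings.txt"),
        hyphen_codings=_load_codepoints("hyphen_codings.txt"),
        synonym_map=_load_synonyms(),
    )


@lru_cache(maxsize=1)
def _translation() -> dict[int, str | None]:
    table = entity_table()
    trans: dict[int, str | None] = {ord(c): " " for c in table.space_codings}
    trans.update({ord(c): "-" for c in table.hyphen_codings})
    trans.update({ord(c): plain for c, plain in table.synonym_map.items()})
    trans[ord(_SOFT_HYPHEN)] = None  # discretionary hyphen: drop
    return trans


_URL = re.compile(r"(?:https?|ftp)://\S+|www\.[\w.-]+\S*", re.I)
_MALFORMED_ENTITY = re.compile(r"&#x?;|&#x[^0-9a-fA-F]")
_WS_RUN = re.compile(r"\s+")


def strip_tags(text: str) -> str:
    """Drop XML/HTML markup (tags, comments, CDATA wrappers), keep inner text."""
    text = re.sub(r"<!\[CDATA\[(.*?)\]\]>", r"\1", text, flags=re.S)
    text = re.sub(r"<!--.*?-->", "", text, flags=re.S)
    text = re.sub(r"<\?.*?\?>", "", text, flags=re.S)
    text = re.sub(r"<!DOCTYPE[^>]*>", "", text, flags=re.I)
    return re.sub(r"</?[A-Za-z_][^>]*>", "", text)


def _convert_once(text: str) -> str:
    text = strip_tags(text)
    text = _URL.sub("", text)
    if _MALFORMED_ENTITY.search(text):
        logger.warning("malformed character entity left verbatim: %r",
                       _MALFORMED_ENTITY.search(text).group(0))
    text = html.unescape(text)
    text = text.translate(_translation())
    text = unicodedata.normalize("NFC", text)
    return _WS_RUN.sub(" ", text).strip()


def convert_letters(text: str) -> str:
    """Unify entities, spaces, hyphens and styled characters to plain text.

    Hexadecimal/decimal numeric entities and named HTML entities become
    Unicode characters, all space codings a plain space, all dashes
    ``-``; hyperlinks and markup tags are removed, whitespace runs
    collapsed, and the result is NFC-normalized.  Applied repeatedly
    until stable, so the function is idempotent even for doubly encoded
    input (``&amp;#x3b1;``).  Malformed entities are left verbatim and
    logged; content never raises.
    """
    for _ in range(5):
        converted = _convert_once(text)
        if converted == text:
            break
        text = converted
    return text


# ---------------------------------------------------------------------------
# formula flattening


_MATH_TOKEN_TAGS = {"mi", "mn", "mo", "mtext", "ms"}
_SKIP_TAGS = {"annotation", "annotation-xml"}

_GREEK = {
    "alpha": "α", "beta": "β", "gamma": "γ", "delta": "δ", "epsilon": "ε",
    "zeta": "ζ", "eta": "η", "theta": "θ", "iota": "ι", "kappa": "κ",
    "lambda": "λ", "mu": "μ", "nu": "ν", "xi": "ξ", "omicron": "ο",
    "pi": "π", "rho": "ρ", "sigma": "σ", "tau": "τ", "upsilon": "υ",
    "phi": "φ", "chi": "χ", "psi": "ψ", "omega": "ω",
    "Gamma": "Γ", "Delta": "Δ", "Theta": "Θ", "Lambda": "Λ", "Xi": "Ξ",
    "Pi": "Π", "Sigma": "Σ", "Phi": "Φ", "Psi": "Ψ", "Omega": "Ω",
}

_LATEX_MACROS = {
    "times": "×", "pm": "±", "mp": "∓", "cdot": "·", "div": "/",
    "le": "≤", "leq": "≤", "ge": "≥", "geq": "≥", "ne": "≠", "neq": "≠",
    "approx": "≈", "sim": "~", "propto": "∝", "infty": "∞",
    "sum": "Σ", "prod": "Π", "int": "∫", "sqrt": "√", "partial": "∂",
    "rightarrow": "→", "leftarrow": "←", "circledR": "®", "circledast": "⊛",
    "circ": "∘", "degree": "°", "prime": "'", "percent": "%",
}
_LATEX_MACROS.update(_GREEK)


def _localname(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _render_mathml(el) -> str:
    name = _localname(el.tag)
    if name in _SKIP_TAGS:
        return ""
    children = [c for c in el if _localname(c.tag) not in _SKIP_TAGS]
    if name == "mfrac" and len(children) == 2:
        return f"{_render_mathml(children[0])}/{_render_mathml(children[1])}"
    if name in {"msup", "mover"} and len(children) == 2:
        return f"{_render_mathml(children[0])}^{_render_mathml(children[1])}"
    if name in {"msub", "munder"} and len(children) == 2:
        return f"{_render_mathml(children[0])}_{_render_mathml(children[1])}"
    if name == "msqrt":
        return "√(" + "".join(_render_mathml(c) for c in children) + ")"
    parts = [el.text or ""]
    for child in el:
        parts.append(_render_mathml(child))
        parts.append(child.tail or "")
    text = "".join(parts)
    if name in _MATH_TOKEN_TAGS:
        text = text.strip()
    return text


def _flatten_latex(text: str) -> str:
    text = re.sub(r"\${1,2}|\\[()\[\]]", "", text)
    for _ in range(4):  # nested \frac
        new = re.sub(r"\\[dt]?frac\s*\{([^{}]*)\}\s*\{([^{}]*)\}", r"\1/\2", text)
        if new == text:
            break
        text = new
    text = re.sub(
        r"\\([A-Za-z]+)",
        lambda m: _LATEX_MACROS.get(m.group(1), m.group(1)), text,
    )
    text = text.replace("{", "").replace("}", "")
    return text


_HAS_LETTERISH = re.compile(r"[^\s<>/=\"']")


def flatten_math(fragment: TagFragment | str) -> str:
    """Flatten a MathML element or LaTeX-style notation to plain text.

    Operators and identifiers come out in reading order; fractions render
    as ``a/b``, super-/subscripts as ``^``/``_``, styled letter variants
    are folded to their plain equivalent.  A formula represented only by
    a hyper-referenced image cannot be recovered as text: it yields an
    empty string and an ``image_formula`` log entry.  Unrecognized
    constructs degrade to concatenated text content.
    """
    raw = fragment.raw_xml if isinstance(fragment, TagFragment) else fragment
    if "<" in raw:
        from lxml import etree

        try:
            root = etree.fromstring(
                raw.encode("utf-8"), etree.XMLParser(recover=True, resolve_entities=False)
            )
        except (etree.XMLSyntaxError, ValueError):
            root = None
        if root is not None:
            inner = _render_mathml(root)
            if not inner.strip() and re.search(r"<(?:inline-)?graphic\b", raw):
                logger.warning("image_formula: formula stored as referenced image only")
                return ""
            raw = inner
    text = _flatten_latex(raw)
    text = convert_letters(text)
    return text.replace(" ", "")


# ---------------------------------------------------------------------------
# spacing


_BEFORE_CLOSERS = re.compile(r"\s+([,.;:%?!)\]])")
_AFTER_OPENERS = re.compile(r"([(\[])\s+")
_OPERATOR = re.compile(r"(?<=[\w)\]])\s*([=<>≤≥±])\s*(?=[.\d(−-])")
_SENTENCE_GAP = re.compile(r"(?<=[a-z])([.?!])(?=[A-Z])")


def fix_spacing(text: str) -> str:
    """Correct common spacing errors; idempotent.

    Rules: whitespace runs collapse to one space; no space before
    ``, . ; : % ? ! ) ]`` or after ``( [``; comparison/equality operators
    in numeric context are set tight (``p = .05`` -> ``p=.05``); a missing
    space after sentence-final punctuation between a lowercase and an
    uppercase letter is inserted; no leading/trailing space.
    """
    text = _WS_RUN.sub(" ", text)
    text = _BEFORE_CLOSERS.sub(r"\1", text)
    text = _AFTER_OPENERS.sub(r"\1", text)
    text = _OPERATOR.sub(r"\1", text)
    text = _SENTENCE_GAP.sub(r"\1 ", text)
    return text.strip()
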