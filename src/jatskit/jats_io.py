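"""Robust reading of NISO-JATS XML files and location of tag fragments.

PMC-style NXML spans decades of vintages with mixed encodings and the
occasional malformed document, so reading is deliberately forgiving:
the XML encoding declaration is trusted first, then UTF-8, then Latin-1
with replacement.  Element fragments are located by a balanced-tag scan
that matches local element names (namespace prefixes ignored) and keeps
working even when an unrelated part of the document is not well formed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "RawDocument",
    "TagFragment",
    "JatsReadError",
    "EmptyFileError",
    "read_jats",
    "extract_fragments",
    "fragment_text",
]


class JatsReadError(Exception):
    """A file could not be read or decoded."""


class EmptyFileError(JatsReadError):
    """A file exists but contains no content."""


@dataclass(frozen=True)
class RawDocument:
    """A decoded JATS document: full text content plus provenance."""

    source_path: str
    content: str
    declared_encoding: str | None = None


@dataclass(frozen=True)
class TagFragment:
    """One element occurrence: raw XML (including its own tags) + attributes."""

    tag_name: str
    raw_xml: str
    attributes: dict[str, str] = field(default_factory=dict)


_ENC_DECL = re.compile(rb'<\?xml[^>]*?encoding\s*=\s*["\']([A-Za-z0-9._-]+)["\']')


def read_jats(path: str | Path) -> RawDocument:
    """Read one JATS/NXML file into a :class:`RawDocument`.

    The encoding declared in the XML prolog is honored; when absent or
    wrong the file is decoded as UTF-8, falling back to Latin-1 with
    replacement (and a logged warning).  DOCTYPE declarations are kept
    verbatim; nothing is ever fetched from the network.

    Raises :class:`EmptyFileError` for an empty file and
    :class:`JatsReadError` for an unreadable one.
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise JatsReadError(f"cannot read JATS file: {path}") from exc
    if not raw.strip():
        raise EmptyFileError(f"empty JATS file: {path}")

    declared = None
    m = _ENC_DECL.search(raw[:200])
    if m:
        declared = m.group(1).decode("ascii", "replace")

    content = None
    for encoding in filter(None, (declared, "utf-8")):
        try:
            content = raw.decode(encoding)
            break
        except (UnicodeDecodeError, LookupError):
            logger.warning("decoding %s as %s failed, trying fallback", path, encoding)
    if content is None:
        content = raw.decode("latin-1", errors="replace")
        logger.warning("decoded %s as latin-1 with replacement", path)
    return RawDocument(source_path=str(path), content=content, declared_encoding=declared)


_ATTR = re.compile(r"""([A-Za-z_][\w:.-]*)\s*=\s*(?:"([^"]*)"|'([^']*)')""")


def _parse_attributes(open_tag: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for name, dq, sq in _ATTR.findall(open_tag):
        local = name.rsplit(":", 1)[-1]
        attrs.setdefault(local, dq if dq != "" or sq == "" else sq)
    return attrs


def extract_fragments(doc: RawDocument | str, tag_name: str) -> list[TagFragment]:
    """Return all top-level occurrences of ``tag_name`` in document order.

    "Top-level" means occurrences not nested inside another element of the
    same name (a ``<sec>`` inside a ``<sec>`` belongs to the outer
    fragment).  Absence yields an empty list.  The scan is purely textual
    and balanced per tag, so a malformed element elsewhere in the document
    does not prevent extraction.
    """
    content = doc.content if isinstance(doc, RawDocument) else doc
    open_or_close = re.compile(
        rf"<(/?)(?:[A-Za-z_][\w.-]*:)?{re.escape(tag_name)}(?=[\s/>])([^>]*)>"
    )
    fragments: list[TagFragment] = []
    depth = 0
    start = -1
    for m in open_or_close.finditer(content):
        closing = m.group(1) == "/"
        self_closing = m.group(2).rstrip().endswith("/")
        if not closing:
            if self_closing:
                if depth == 0:
                    fragments.append(
                        TagFragment(tag_name, m.group(0), _parse_attributes(m.group(0)))
                    )
                continue
            if depth == 0:
                start = m.start()
            depth += 1
        else:
            if depth == 0:
                continue  # stray close tag
            depth -= 1
            if depth == 0:
                raw = content[start : m.end()]
                open_tag = raw[: raw.index(">") + 1]
                fragments.append(TagFragment(tag_name, raw, _parse_attributes(open_tag)))
    if depth > 0 and start >= 0:
        # unclosed element: runs to end of document
        raw = content[start:]
        open_tag = raw[: raw.index(">") + 1]
        fragments.append(TagFragment(tag_name, raw, _parse_attributes(open_tag)))
        logger.warning("unclosed <%s> element; fragment truncated at document end", tag_name)
    return fragments


_TAG = re.compile(r"<[^>]*>")
# closing a block-level element must leave a space so adjacent paragraphs,
# titles and cells do not glue together when tags are stripped
_BLOCK_BOUNDARY = re.compile(
    r"</(?:p|sec|title|label|caption|abstract|body|list-item|list|def-item|"
    r"td|th|tr|table|boxed-text)\s*>|<break\s*/?>|<hr\s*/?>"
)


def fragment_text(fragment: TagFragment | str) -> str:
    """Inner text of a fragment with all markup tags dropped (no cleanup).

    Block-level element boundaries become spaces; inline tags (italic,
    sup, xref, ...) are removed without inserting anything.
    """
    raw = fragment.raw_xml if isinstance(fragment, TagFragment) else fragment
    raw = re.sub(r"<!\[CDATA\[(.*?)\]\]>", r"\1", raw, flags=re.S)
    raw = re.sub(r"<!--.*?-->", "", raw, flags=re.S)
    raw = _BLOCK_BOUNDARY.sub(" ", raw)
    return _TAG.sub("", raw)
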