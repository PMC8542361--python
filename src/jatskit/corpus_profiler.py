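"""Aggregate decoded article records into bibliometric tables.

Given a directory of JATS/NXML files (or already-decoded records) the
profiler computes: relative tag-use frequencies overall and per
publication period, frequency tables for types, journals (with
journal-size bins), date-stamp labels, names, subjects, keywords and
countries, date-stamp anomaly counts (accept before receive, publish
before accept, future dates), and the country co-occurrence table with
the share of internationally co-authored records.

All outputs are plain :class:`pandas.DataFrame` objects with a stable
column order; ``profile_corpus`` writes them as CSV.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .jats_io import JatsReadError
from .record import ArticleRecord, decode_article

logger = logging.getLogger(__name__)

__all__ = [
    "CONTENT_ELEMENTS",
    "JOURNAL_BIN_EDGES",
    "TagUseTable",
    "decode_collection",
    "tag_use_table",
    "frequency_table",
    "date_anomalies",
    "country_cooccurrence",
    "profile_corpus",
]

#: The content elements whose presence the tag-use table reports.
CONTENT_ELEMENTS = (
    "abstract", "affiliation", "author", "country", "doi", "editor",
    "history", "journal", "keywords", "references", "sections", "subject",
    "text", "title", "type", "volume",
)

#: Upper edges of the journal-size bins (number of articles per journal).
JOURNAL_BIN_EDGES = (1, 10, 100, 1000, 10_000, 100_000)


def _present(record: ArticleRecord, element: str) -> bool:
    return {
        "abstract": lambda r: r.abstract_present,
        "affiliation": lambda r: bool(r.affiliations),
        "author": lambda r: bool(r.authors),
        "country": lambda r: bool(r.countries),
        "doi": lambda r: r.doi is not None,
        "editor": lambda r: bool(r.editors),
        "history": lambda r: len(r.history) > 0,
        "journal": lambda r: r.journal is not None,
        "keywords": lambda r: bool(r.keywords),
        "references": lambda r: bool(r.references),
        "sections": lambda r: any(s.title for s in r.sections),
        "subject": lambda r: bool(r.subjects),
        "text": lambda r: r.text_present,
        "title": lambda r: r.title is not None,
        "type": lambda r: r.type is not None,
        "volume": lambda r: r.volume is not None,
    }[element](record)


def decode_collection(
    paths: str | Path | Iterable[str | Path],
    sectionsplit: list[str] | None = None,
    shorten_given: bool = False,
) -> list[ArticleRecord]:
    """Decode a directory or list of JATS files into records.

    Undecodable files are logged and skipped; the result is sorted by
    source path, so it is independent of input ordering.  Raises when no
    file at all could be decoded.
    """
    if isinstance(paths, (str, Path)):
        directory = Path(paths)
        files = sorted(
            p for p in directory.glob("*") if p.suffix.lower() in {".xml", ".nxml"}
        )
        if not files:
            raise JatsReadError(f"no JATS files found in {directory}")
    else:
        files = sorted(Path(p) for p in paths)
    records = []
    failures = 0
    for path in files:
        try:
            records.append(decode_article(path, sectionsplit, shorten_given))
        except Exception:
            failures += 1
            logger.warning("skipping undecodable file %s", path, exc_info=True)
    if not records:
        raise JatsReadError(f"all {failures} files failed to decode")
    return records


@dataclass
class TagUseTable:
    """Relative tag-use frequencies, overall and per publication period."""

    frequencies: pd.DataFrame  # index: CONTENT_ELEMENTS; columns: total + bins
    totals: pd.Series  # records per column
    n_without_pub_year: int

    def to_frame(self) -> pd.DataFrame:
        out = self.frequencies.copy()
        out.loc["total_n"] = self.totals
        return out


def _period_bins(edges: Sequence[int], min_year: int) -> list[tuple[float, int, str]]:
    bins = []
    lo = -math.inf
    for i, edge in enumerate(edges):
        label = f"[{min_year}; {edge}]" if i == 0 else f"({bins[-1][1]}; {edge}]"
        bins.append((lo, edge, label))
        lo = edge
    return bins


def tag_use_table(
    records: Sequence[ArticleRecord], period_edges: Sequence[int] = ()
) -> TagUseTable:
    """Relative frequency of extracted tag use, overall and per period.

    Period bins are right-closed; the first bin is closed on both sides
    and starts at the earliest publication year present.  Records
    without a publication year count in the ``total`` column only and
    are reported separately.
    """
    if list(period_edges) != sorted(set(period_edges)):
        raise ValueError("period edges must be strictly increasing")
    years = [r.pub_year for r in records if r.pub_year is not None]
    min_year = min(years) if years else 0
    bins = _period_bins(period_edges, min_year) if period_edges else []

    columns = ["total"] + [label for _, _, label in bins]
    presence = {col: Counter() for col in columns}
    totals = {col: 0 for col in columns}
    n_no_year = 0
    for record in records:
        cols = ["total"]
        if record.pub_year is None:
            n_no_year += 1
        else:
            for lo, hi, label in bins:
                if lo < record.pub_year <= hi or (lo == -math.inf and record.pub_year <= hi):
                    cols.append(label)
                    break
        for col in cols:
            totals[col] += 1
            for element in CONTENT_ELEMENTS:
                if _present(record, element):
                    presence[col][element] += 1
    freq = pd.DataFrame(
        {
            col: [presence[col][el] / totals[col] if totals[col] else float("nan")
                  for el in CONTENT_ELEMENTS]
            for col in columns
        },
        index=list(CONTENT_ELEMENTS),
    )
    return TagUseTable(
        frequencies=freq,
        totals=pd.Series(totals)[columns],
        n_without_pub_year=n_no_year,
    )


_FIELD_VALUES = {
    "type": lambda r: [r.type] if r.type else [],
    "journal": lambda r: [r.journal] if r.journal else [],
    "date_label": lambda r: list(r.history.stamps),
    "author_name": lambda r: [p.display() for p in r.authors],
    "editor_name": lambda r: [p.display() for p in r.editors],
    "subject": lambda r: list(r.subjects),
    "keyword": lambda r: list(r.keywords),
    "country": lambda r: list(r.countries),
}


def _journal_bin_label(count: int) -> str:
    prev = 0
    for edge in JOURNAL_BIN_EDGES:
        if count <= edge:
            return str(edge) if edge == prev + 1 else f"{prev + 1}-{edge}"
        prev = edge
    return f">{JOURNAL_BIN_EDGES[-1]}"


def frequency_table(
    records: Sequence[ArticleRecord],
    field: str,
    bins: bool = False,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Counts per label for one field.

    ``field`` is one of type, journal, date_label, author_name,
    editor_name, subject, keyword, country.  With ``bins`` (journals
    only) the table reports how many journals supply n articles, per
    journal-size bin, as absolute (h) and relative (f) frequency.
    ``top_k`` truncates to the most frequent labels.
    """
    try:
        values = _FIELD_VALUES[field]
    except KeyError:
        raise ValueError(f"unknown field: {field!r}") from None
    counts = Counter()
    for record in records:
        counts.update(values(record))
    if bins:
        if field != "journal":
            raise ValueError("bins are defined for the journal field only")
        bin_counts = Counter(_journal_bin_label(c) for c in counts.values())
        labels = [_journal_bin_label(e) for e in
                  [1] + [lo + 1 for lo in JOURNAL_BIN_EDGES[:-1]]] \
            + [f">{JOURNAL_BIN_EDGES[-1]}"]
        total = sum(bin_counts.values())
        return pd.DataFrame({
            "n": labels,
            "h": [bin_counts.get(l, 0) for l in labels],
            "f": [bin_counts.get(l, 0) / total if total else float("nan")
                  for l in labels],
        })
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        items = items[:top_k]
    return pd.DataFrame(items, columns=["label", "count"])


def date_anomalies(
    records: Sequence[ArticleRecord], reference_date: dt.date
) -> dict[str, int]:
    """Date-stamp sanity counts.

    ``n_accept_before_receive`` and ``n_publish_before_accept`` count
    records whose editorial lags are negative (both operands present);
    ``n_future_dates`` counts records with any completed stamp after the
    supplied reference date (no wall-clock dependence).
    """
    n_reversed = sum(
        1 for r in records if r.time_to_accept is not None and r.time_to_accept < 0
    )
    n_publish = sum(
        1 for r in records if r.time_to_publish is not None and r.time_to_publish < 0
    )
    n_future = sum(
        1 for r in records
        if any(d.completed() > reference_date for d in r.history.stamps.values())
    )
    return {
        "n_accept_before_receive": n_reversed,
        "n_publish_before_accept": n_publish,
        "n_future_dates": n_future,
    }


def country_cooccurrence(
    records: Sequence[ArticleRecord],
) -> tuple[pd.DataFrame, float]:
    """Unordered country-pair counts and the international share.

    The share is the fraction of country-bearing records that list more
    than one country (international author groups); 0 when no record
    bears a country.
    """
    pairs = Counter()
    n_with_country = 0
    n_multi = 0
    for record in records:
        if record.countries:
            n_with_country += 1
        if len(record.countries) > 1:
            n_multi += 1
            pairs.update(combinations(sorted(record.countries), 2))
    share = n_multi / n_with_country if n_with_country else 0.0
    table = pd.DataFrame(
        [(a, b, c) for (a, b), c in
         sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0]))],
        columns=["country_a", "country_b", "count"],
    )
    return table, share


def profile_corpus(
    source: str | Path | Sequence[ArticleRecord],
    out_dir: str | Path,
    period_edges: Sequence[int] = (2000, 2005, 2010, 2015, 2020),
    reference_date: dt.date | None = None,
    top_k: int = 250,
) -> dict[str, Path]:
    """Run the full profile over a corpus and write the CSV tables.

    Outputs: tag_use.csv, journal_bins.csv, date_types.csv,
    type_counts.csv, anomalies.csv, country_pairs.csv, plus top-k
    author/editor/subject/keyword frequency lists.
    """
    records = (
        decode_collection(source) if isinstance(source, (str, Path)) else list(source)
    )
    reference_date = reference_date or dt.date.today()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def write(name: str, frame: pd.DataFrame, **kwargs) -> None:
        path = out_dir / name
        frame.to_csv(path, **kwargs)
        written[name] = path

    write("tag_use.csv", tag_use_table(records, period_edges).to_frame(),
          index_label="content")
    write("journal_bins.csv", frequency_table(records, "journal", bins=True),
          index=False)
    n = len(records)
    date_types = frequency_table(records, "date_label")
    date_types["relative_use"] = date_types["count"] / n
    write("date_types.csv", date_types, index=False)
    write("type_counts.csv", frequency_table(records, "type"), index=False)
    anomalies = date_anomalies(records, reference_date)
    pair_table, share = country_cooccurrence(records)
    anomalies["n_records"] = n
    summary = pd.DataFrame([anomalies])
    summary["international_share"] = share
    write("anomalies.csv", summary, index=False)
    write("country_pairs.csv", pair_table, index=False)
    for field, name in (("author_name", "author_names.csv"),
                        ("editor_name", "editor_names.csv"),
                        ("subject", "subject_counts.csv"),
                        ("keyword", "keyword_counts.csv")):
        write(name, frequency_table(records, field, top_k=top_k), index=False)
    return written
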