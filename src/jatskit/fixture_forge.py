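"""Synthetic NISO-JATS documents with known ground truth.

Real PMC archives mix encodings, date-stamp labels, all-caps names,
tagged and untagged affiliations, nested subject groups and image-only
formulas.  The forge generates well-formed JATS articles that reproduce
those dialect quirks while knowing exactly which record a canonical
decode must produce, so every extractor is testable without any
download.  Generation is fully deterministic: the same spec always
yields byte-identical XML.

Quirks apply only to surface encoding; semantic fields (which stamps
exist, whether dates are reversed) are part of the spec itself.
"""

from __future__ import annotations

import datetime as dt
import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from . import metadata as md
from .contributors import AffiliationEntry, PersonName, get_countries, recase_allcaps
from .metadata import DateStampSet, PartialDate
from .record import ArticleRecord, record_to_dict
from .textparts import MIN_TEXT_CHARS, Reference, Section

__all__ = [
    "SURFACE_QUIRKS",
    "SEMANTIC_QUIRKS",
    "ALL_QUIRKS",
    "REFERENCE_DATE",
    "FixtureSpec",
    "GroundTruth",
    "PrevalenceConfig",
    "generate_article",
    "generate_corpus",
    "write_manifest",
]

#: Quirks that change only the XML surface; decoding with or without them
#: yields the identical record.
SURFACE_QUIRKS = frozenset({
    "hex_entities", "decimal_entities", "named_entities", "allcaps_names",
    "untagged_affiliation", "alt_space_codings", "nested_subjects",
    "inline_formula_image", "duplicate_date_label", "subsectioned_body",
})

#: Quirks that change the planted content (and hence the ground truth).
SEMANTIC_QUIRKS = frozenset({
    "missing_month_day", "mathml_formula", "reversed_accept_receive",
    "future_date",
})

ALL_QUIRKS = SURFACE_QUIRKS | SEMANTIC_QUIRKS

#: The corpus snapshot date used as "today" for future-date flags.
REFERENCE_DATE = dt.date(2021, 1, 1)


@dataclass(frozen=True)
class FixtureSpec:
    """Configuration for one generated article (all fields optional)."""

    seed: int = 0
    title: str | None = None
    journal: str | None = None
    doi: str | None = None
    article_type: str | None = "research-article"
    volume: str | None = None
    subjects: tuple[str, ...] = ()
    keywords: tuple[str, ...] = ()
    authors: tuple[tuple[str, str, tuple[tuple[str, str], ...]], ...] = ()
    editors: tuple[tuple[str, str, tuple[tuple[str, str], ...]], ...] = ()
    #: each affiliation: (parts without country, country name or None)
    affiliations: tuple[tuple[tuple[str, ...], str | None], ...] = ()
    #: label -> (year, month, day); month/day may be None
    history: tuple[tuple[str, tuple[int, int | None, int | None]], ...] = ()
    abstract: str | None = None
    sections: tuple[tuple[str, str], ...] = ()
    references: tuple[str, ...] = ()
    quirks: frozenset[str] = frozenset()
    #: demand an explicit <country> element (conflicts with untagged_affiliation)
    require_country_tag: bool = False


@dataclass
class GroundTruth:
    """The exact record a canonical decode must produce, plus anomaly flags."""

    record: ArticleRecord
    accept_before_receive: bool = False
    publish_before_accept: bool = False
    future_date: bool = False
    quirks: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# surface encoding

_NAMED_ENTITIES = {
    "α": "&alpha;", "β": "&beta;", "γ": "&gamma;", "δ": "&delta;",
    "é": "&eacute;", "ü": "&uuml;", "ö": "&ouml;", "ä": "&auml;",
    "ñ": "&ntilde;", "ç": "&ccedil;",
}
_ALT_SPACES = ["\u00a0", "\u2009", "\u2002", "\u205f", "\u2008"]


def _encode(text: str, quirks: frozenset[str], alt_spaces: bool = False) -> str:
    out = text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    if "named_entities" in quirks:
        for char, entity in _NAMED_ENTITIES.items():
            out = out.replace(char, entity)
    if "hex_entities" in quirks:
        out = "".join(f"&#x{ord(c):x};" if ord(c) > 127 else c for c in out)
    elif "decimal_entities" in quirks:
        out = "".join(f"&#{ord(c)};" if ord(c) > 127 else c for c in out)
    if alt_spaces and "alt_space_codings" in quirks:
        pieces = out.split(" ")
        out = "".join(
            piece + (_ALT_SPACES[i % len(_ALT_SPACES)] if i < len(pieces) - 1 else "")
            for i, piece in enumerate(pieces)
        )
    return out


def _date_xml(tag: str, label_attr: str, label: str,
              ymd: tuple[int, int | None, int | None]) -> str:
    year, month, day = ymd
    parts = []
    if day is not None:
        parts.append(f"<day>{day:02d}</day>")
    if month is not None:
        parts.append(f"<month>{month:02d}</month>")
    parts.append(f"<year>{year}</year>")
    return f'<{tag} {label_attr}="{label}">{"".join(parts)}</{tag}>'


def _history_xml(spec: FixtureSpec) -> str:
    history_dates = []
    pub_dates = []
    for label, ymd in spec.history:
        if label in md.PUBLICATION_EVENT_LABELS:
            pub_dates.append(_date_xml("pub-date", "pub-type", label, ymd))
        else:
            history_dates.append(_date_xml("date", "date-type", label, ymd))
            if "duplicate_date_label" in spec.quirks and label == "received":
                year, month, day = ymd
                dup = (year, month, min((day or 1) + 5, 28))
                history_dates.append(_date_xml("date", "date-type", label, dup))
    xml = "".join(pub_dates)
    if history_dates:
        xml += "<history>" + "".join(history_dates) + "</history>"
    return xml


def _contrib_xml(person: tuple[str, str, tuple[tuple[str, str], ...]],
                 role: str, quirks: frozenset[str]) -> str:
    surname, given, ids = person
    if "allcaps_names" in quirks:
        surname, given = surname.upper(), given.upper()
    id_xml = "".join(
        f'<contrib-id contrib-id-type="{scheme}">{value}</contrib-id>'
        for scheme, value in ids
    )
    return (
        f'<contrib contrib-type="{role}">{id_xml}'
        f"<name><surname>{_encode(surname, quirks)}</surname>"
        f"<given-names>{_encode(given, quirks)}</given-names></name></contrib>"
    )


def _aff_xml(aff: tuple[tuple[str, ...], str | None], spec: FixtureSpec) -> str:
    parts, country = aff
    if "untagged_affiliation" in spec.quirks:
        line = ", ".join([*parts, country] if country else list(parts))
        return f"<aff>{_encode(line, spec.quirks)}</aff>"
    tagged = [f"<institution>{_encode(parts[0], spec.quirks)}</institution>"]
    tagged += [f"<addr-line>{_encode(p, spec.quirks)}</addr-line>" for p in parts[1:]]
    if country is not None:
        tagged.append(f"<country>{_encode(country, spec.quirks)}</country>")
    return "<aff>" + ", ".join(tagged) + "</aff>"


def _subjects_xml(spec: FixtureSpec) -> str:
    if not spec.subjects:
        return ""
    if "nested_subjects" in spec.quirks and len(spec.subjects) > 1:
        inner = f"<subject>{_encode(spec.subjects[-1], spec.quirks)}</subject>"
        nested = f"<subj-group>{inner}</subj-group>"
        outer = "".join(
            f"<subject>{_encode(s, spec.quirks)}</subject>" for s in spec.subjects[:-1]
        )
        groups = f"<subj-group>{outer}{nested}</subj-group>"
    else:
        groups = "<subj-group>" + "".join(
            f"<subject>{_encode(s, spec.quirks)}</subject>" for s in spec.subjects
        ) + "</subj-group>"
    return f"<article-categories>{groups}</article-categories>"


_MATHML_SNIPPET = (
    '<inline-formula><mml:math><mml:mi>p</mml:mi><mml:mo>&#x3C;</mml:mo>'
    "<mml:mn>0.05</mml:mn></mml:math></inline-formula>"
)
_IMAGE_FORMULA_SNIPPET = (
    '<inline-formula><inline-graphic xlink:href="formula1.gif"/></inline-formula>'
)


def _body_xml(spec: FixtureSpec) -> str:
    if not spec.sections:
        return ""
    secs = []
    for i, (title, text) in enumerate(spec.sections):
        inner = f"<title>{_encode(title, spec.quirks)}</title>"
        paragraph = _encode(text, spec.quirks)
        if i == 0 and "inline_formula_image" in spec.quirks:
            paragraph += " " + _IMAGE_FORMULA_SNIPPET
        if i == 0 and "mathml_formula" in spec.quirks:
            paragraph += " " + _MATHML_SNIPPET
        secs.append(f"<sec>{inner}<p>{paragraph}</p></sec>")
    if "subsectioned_body" in spec.quirks and len(secs) >= 3:
        # nest the third section inside the second; flattening restores order
        nested = secs[1][: -len("</sec>")] + secs[2] + "</sec>"
        secs = [secs[0], nested] + secs[3:]
    return "<body>" + "".join(secs) + "</body>"


def generate_article(spec: FixtureSpec) -> tuple[str, GroundTruth]:
    """Render one spec to JATS XML plus its ground-truth record.

    Raises ``ValueError`` for contradictory quirk combinations
    (an untagged affiliation cannot carry an explicit country element)
    or unknown quirk names.
    """
    unknown = spec.quirks - ALL_QUIRKS
    if unknown:
        raise ValueError(f"unknown quirks: {sorted(unknown)}")
    if spec.require_country_tag and "untagged_affiliation" in spec.quirks:
        raise ValueError(
            "contradictory quirks: untagged_affiliation with an explicit country tag"
        )
    spec = _apply_semantic_quirks(spec)

    front_meta = []
    if spec.doi:
        front_meta.append(f'<article-id pub-id-type="doi">{spec.doi}</article-id>')
    front_meta.append(_subjects_xml(spec))
    if spec.title is not None:
        front_meta.append(
            "<title-group><article-title>"
            + _encode(spec.title, spec.quirks, alt_spaces=True)
            + "</article-title></title-group>"
        )
    contribs = [_contrib_xml(p, "author", spec.quirks) for p in spec.authors]
    contribs += [_contrib_xml(p, "editor", spec.quirks) for p in spec.editors]
    if contribs:
        front_meta.append("<contrib-group>" + "".join(contribs) + "</contrib-group>")
    front_meta += [_aff_xml(a, spec) for a in spec.affiliations]
    front_meta.append(_history_xml(spec))
    if spec.volume is not None:
        front_meta.append(f"<volume>{_encode(spec.volume, spec.quirks)}</volume>")
    if spec.abstract is not None:
        front_meta.append(
            "<abstract><p>"
            + _encode(spec.abstract, spec.quirks, alt_spaces=True)
            + "</p></abstract>"
        )
    if spec.keywords:
        front_meta.append(
            "<kwd-group>"
            + "".join(f"<kwd>{_encode(k, spec.quirks)}</kwd>" for k in spec.keywords)
            + "</kwd-group>"
        )

    journal_meta = ""
    if spec.journal is not None:
        journal_meta = (
            "<journal-meta><journal-title-group><journal-title>"
            + _encode(spec.journal, spec.quirks)
            + "</journal-title></journal-title-group></journal-meta>"
        )

    back = ""
    if spec.references:
        refs = "".join(
            f'<ref id="r{i + 1}"><mixed-citation>{_encode(r, spec.quirks)}'
            "</mixed-citation></ref>"
            for i, r in enumerate(spec.references)
        )
        back = f"<back><ref-list>{refs}</ref-list></back>"

    type_attr = f' article-type="{spec.article_type}"' if spec.article_type else ""
    xml = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f"<article{type_attr} "
        'xmlns:mml="http://www.w3.org/1998/Math/MathML" '
        'xmlns:xlink="http://www.w3.org/1999/xlink">'
        f"<front>{journal_meta}<article-meta>{''.join(front_meta)}</article-meta></front>"
        f"{_body_xml(spec)}{back}</article>"
    )
    return xml, _ground_truth(spec)


def _apply_semantic_quirks(spec: FixtureSpec) -> FixtureSpec:
    history = dict(spec.history)
    if "reversed_accept_receive" in spec.quirks:
        rec, acc = history.get("received"), history.get("accepted")
        if rec and acc and _completed(acc) >= _completed(rec):
            history["received"], history["accepted"] = acc, rec
    if "future_date" in spec.quirks and "accepted" in history:
        year, month, day = history["accepted"]
        if month == 2 and day is not None:
            day = min(day, 28)  # 2100 is not a leap year
        history["accepted"] = (2100, month, day)
    if "missing_month_day" in spec.quirks:
        for label in ("collection", "ppub"):
            if label in history:
                year, _, _ = history[label]
                history[label] = (year, None, None)
    return replace(spec, history=tuple(history.items()))


def _completed(ymd: tuple[int, int | None, int | None]) -> dt.date:
    year, month, day = ymd
    return dt.date(year, month or 1, day or 1)


def _truth_person(person, quirks: frozenset[str], role: str) -> PersonName:
    surname, given, ids = person
    if "allcaps_names" in quirks:
        surname = recase_allcaps(surname.upper())
        given = recase_allcaps(given.upper())
    return PersonName(surname, given, role=role,
                      ids=tuple((s.lower(), v) for s, v in ids))


def _ground_truth(spec: FixtureSpec) -> GroundTruth:
    stamps = DateStampSet()
    for label, (year, month, day) in spec.history:
        stamps.add(label, PartialDate(year, month, day))
    pub_date, pub_year = md.compute_pub_date(stamps)
    t_accept, t_publish = md.publication_lags(stamps, pub_date)

    affs = []
    for parts, country in spec.affiliations:
        text = ", ".join([*parts, country] if country else list(parts))
        countries = get_countries([text], [country] if country else [])
        affs.append(AffiliationEntry(text=text, countries=countries))
    countries = tuple(sorted({c for a in affs for c in a.countries}))

    sections = []
    for i, (title, text) in enumerate(spec.sections):
        if i == 0 and "mathml_formula" in spec.quirks:
            text = (text + " p<0.05").strip()
        sections.append(Section(title=title, text=text))
    body_text = " ".join(s.text for s in sections).strip()

    record = ArticleRecord(
        source_path="",
        title=spec.title,
        journal=spec.journal,
        doi=spec.doi,
        type=spec.article_type,
        volume=spec.volume,
        subjects=tuple(dict.fromkeys(spec.subjects)),
        keywords=tuple(dict.fromkeys(spec.keywords)),
        authors=[_truth_person(p, spec.quirks, "author") for p in spec.authors],
        editors=[_truth_person(p, spec.quirks, "editor") for p in spec.editors],
        affiliations=affs,
        countries=countries,
        history=stamps,
        pub_date=pub_date,
        pub_year=pub_year,
        time_to_accept=t_accept,
        time_to_publish=t_publish,
        abstract=spec.abstract or "",
        abstract_present=len(spec.abstract or "") >= MIN_TEXT_CHARS,
        sections=sections,
        text_present=len(body_text) >= MIN_TEXT_CHARS,
        references=[Reference(raw=r, index=i) for i, r in enumerate(spec.references)],
    )
    received, accepted = stamps.get("received"), stamps.get("accepted")
    return GroundTruth(
        record=record,
        accept_before_receive=(
            received is not None and accepted is not None
            and accepted.completed() < received.completed()
        ),
        publish_before_accept=(
            accepted is not None and pub_date is not None
            and pub_date.completed() < accepted.completed()
        ),
        future_date=any(
            d.completed() > REFERENCE_DATE for d in stamps.stamps.values()
        ),
        quirks=spec.quirks,
    )


# ---------------------------------------------------------------------------
# corpus generation


@dataclass(frozen=True)
class PrevalenceConfig:
    """Planted presence rates for a generated corpus.

    Defaults follow the overall tag-use frequencies observed across the
    PMC open-access collection, so a default corpus emulates the mix of
    complete and sparse records found in the wild.  Rates are realized
    by deterministic allocation — exactly ``round(n * p)`` records get a
    feature — never by sampling, so profiler tests are exact.
    """

    abstract: float = 0.879
    affiliation: float = 0.948
    author: float = 0.969
    country: float = 0.829
    editor: float = 0.126
    keywords: float = 0.599
    references: float = 0.903
    body: float = 0.885
    subject: float = 0.998
    volume: float = 0.487
    author_id: float = 0.098
    #: share of country-bearing records with more than one country
    international: float = 0.308
    #: date-stamp anomaly rates (orders of magnitude as seen in the wild)
    reversed_accept_receive: float = 0.0007
    publish_before_accept: float = 0.0038
    future_date: float = 0.0002
    #: surface-dialect quirk rates
    quirk_rates: tuple[tuple[str, float], ...] = (
        ("hex_entities", 0.30),
        ("decimal_entities", 0.10),
        ("named_entities", 0.10),
        ("allcaps_names", 0.15),
        ("untagged_affiliation", 0.30),
        ("missing_month_day", 0.20),
        ("alt_space_codings", 0.15),
        ("nested_subjects", 0.20),
        ("inline_formula_image", 0.05),
        ("mathml_formula", 0.10),
        ("duplicate_date_label", 0.05),
        ("subsectioned_body", 0.30),
    )


QUIRK_PROFILES = {
    "default": PrevalenceConfig(),
    "clean": PrevalenceConfig(quirk_rates=(), reversed_accept_receive=0.0,
                              publish_before_accept=0.0, future_date=0.0),
    "messy": PrevalenceConfig(quirk_rates=tuple(
        (q, 0.5) for q in sorted(ALL_QUIRKS - {"decimal_entities"})
    )),
}


_JOURNAL_POOL = [
    ("PLoS ONE", 30), ("Scientific Reports", 15), ("The Hospital", 8),
    ("BMC Genomics", 4), ("Frontiers in Psychology", 3),
    ("Nature Communications", 3), ("PeerJ", 2),
] + [(f"Journal of Synthetic Studies {k}", 1) for k in range(1, 21)]

_AUTHOR_POOL = [
    (("Wang", "Wei"), 8), (("Zhang", "Li"), 4), (("Kim", "Min"), 3),
    (("Chen", "Jing"), 3), (("Smith", "John"), 2), (("Lee", "Sun"), 2),
    (("Müller", "Anna"), 1), (("Garcia", "Maria"), 1), (("Brown", "Emily"), 1),
    (("Davis", "Michael"), 1), (("Rossi", "Marco"), 1), (("Kumar", "Raj"), 1),
]

_EDITOR_POOL = [
    ("Johnson", "Robert"), ("Williams", "Sarah"), ("Taylor", "James"),
    ("Moore", "Patricia"), ("Clark", "David"),
]

_AFF_POOL = [
    (("Institute of Psychology, University Hamburg", "Von-Melle-Park 5",
      "20146 Hamburg"), "Germany"),
    (("Department of Biology", "Harvard University", "Cambridge"), "United States"),
    (("School of Medicine", "Peking University", "Beijing"), "China"),
    (("Institute of Genetics", "University of Oxford"), "United Kingdom"),
    (("Department of Chemistry", "University of Tokyo"), "Japan"),
    (("INSERM U1234", "Université de Paris"), "France"),
    (("Department of Ecology", "University of São Paulo"), "Brazil"),
    (("School of Public Health", "Seoul National University"), "South Korea"),
]

_SUBJECT_POOL = ["Research Article", "Biology", "Genetics", "Neuroscience",
                 "Medicine", "Ecology", "Psychology"]
_KEYWORD_POOL = ["Covid-19", "SARS-Cov-2", "text mining", "meta-research",
                 "gene expression", "machine learning", "public health",
                 "phylogenetics"]

_TITLE_POOL = [
    "A large α study of gene expression in model organisms",
    "Robust estimation of effect sizes across heterogeneous samples",
    "Sentence segmentation for scientific text corpora",
    "Longitudinal évaluation of publication practices",
    "Network structure of international research collaborations",
    "Säuregrad and metabolic cost in yeast biosynthesis",
]

_TYPE_POOL = [("research-article", 72), ("review", 8), ("case-report", 5),
              ("correction", 2), ("brief-report", 5), ("editorial", 4),
              ("letter", 4)]

_SECTION_TEMPLATES = [
    ("Introduction", "Prior work has examined this question in depth. "
     "We extend those findings with a larger and more diverse sample."),
    ("Method", "Participants completed a standardized protocol under "
     "controlled conditions. All measures were validated beforehand."),
    ("Participants", "The sample comprised adult volunteers recruited "
     "from the local community over twelve months."),
    ("Results", "The primary outcome improved substantially relative to "
     "baseline. Secondary outcomes followed the same pattern."),
    ("Discussion", "These findings align with earlier reports and extend "
     "them to a broader population. Limitations are discussed."),
]

_REFERENCE_POOL = [
    "Smith J, Doe A (2015). A study of measurable things. Journal of "
    "Examples, 12(3), 45-67.",
    "Chen J, Wang W (2018). Large-scale text analysis in biomedicine. "
    "Computational Reviews, 4(1), 1-20.",
    "Müller A (2012). Methodological notes on corpus construction. "
    "Methods Quarterly, 8(2), 100-115.",
    "Garcia M, Rossi M (2019). Replication in the life sciences. Open "
    "Science Letters, 2(4), 200-210.",
]

_ABSTRACT_TEMPLATE = (
    "This synthetic article examines {topic} in a controlled setting. "
    "The results indicate a consistent pattern across all conditions. "
    "Implications for future work are outlined."
)


def _weighted_choice(rng: random.Random, pool):
    items = [item for item, _ in pool]
    weights = [w for _, w in pool]
    return rng.choices(items, weights=weights, k=1)[0]


def _allocate(feature: str, seed: int, universe: list[int], k: int) -> set[int]:
    """Deterministically pick k members of universe for a feature."""
    k = max(0, min(k, len(universe)))
    rng = random.Random(f"{seed}:{feature}")
    return set(rng.sample(sorted(universe), k))


def _orcid(i: int) -> str:
    return f"0000-000{2 + i % 7}-{1000 + i % 9000:04d}-{1234 + 7 * i % 8766:04d}"


def build_corpus_specs(
    n: int, config: PrevalenceConfig | None = None, seed: int = 0
) -> list[FixtureSpec]:
    """Build the n fixture specs for a corpus (deterministic in seed)."""
    if n < 1:
        raise ValueError("corpus size must be at least 1")
    config = config or PrevalenceConfig()
    everyone = list(range(n))
    has = {
        feat: _allocate(feat, seed, everyone, round(n * getattr(config, feat)))
        for feat in ("abstract", "affiliation", "author", "editor", "keywords",
                     "references", "body", "subject", "volume")
    }
    aff_members = sorted(has["affiliation"])
    has["country"] = _allocate("country", seed, aff_members, round(n * config.country))
    country_members = sorted(has["country"])
    has["international"] = _allocate(
        "international", seed, country_members,
        round(len(country_members) * config.international),
    )
    author_members = sorted(has["author"])
    has["author_id"] = _allocate("author_id", seed, author_members,
                                 round(n * config.author_id))
    for anomaly in ("reversed_accept_receive", "publish_before_accept", "future_date"):
        has[anomaly] = _allocate(anomaly, seed, everyone,
                                 round(n * getattr(config, anomaly)))
    quirk_sets = {
        q: _allocate(f"quirk:{q}", seed, everyone, round(n * rate))
        for q, rate in config.quirk_rates
    }

    specs = []
    for i in range(n):
        rng = random.Random((seed * 1_000_003 + i) % 2**31)
        quirks = {q for q, members in quirk_sets.items() if i in members}
        if i in has["reversed_accept_receive"]:
            quirks.add("reversed_accept_receive")
        if i in has["future_date"]:
            quirks.add("future_date")

        year = rng.randint(1998, 2020)
        received = dt.date(year, rng.randint(1, 12), rng.randint(1, 28))
        accepted = received + dt.timedelta(days=rng.randint(30, 200))
        if i in has["publish_before_accept"]:
            epub = accepted - dt.timedelta(days=rng.randint(20, 60))
        else:
            epub = accepted + dt.timedelta(days=rng.randint(10, 150))
        history = [
            ("received", (received.year, received.month, received.day)),
            ("accepted", (accepted.year, accepted.month, accepted.day)),
            ("epub", (epub.year, epub.month, epub.day)),
        ]
        if rng.random() < 0.4:
            ppub = epub + dt.timedelta(days=rng.randint(5, 90))
            history.append(("ppub", (ppub.year, ppub.month, ppub.day)))
        if rng.random() < 0.3:
            history.append(("collection", (epub.year, epub.month, epub.day)))

        authors = ()
        if i in has["author"]:
            k = rng.randint(1, 5)
            chosen = [_weighted_choice(rng, _AUTHOR_POOL) for _ in range(k)]
            authors = tuple(
                (s, g, ((("orcid", _orcid(i)),) if j == 0 and i in has["author_id"]
                        else ()))
                for j, (s, g) in enumerate(chosen)
            )
        editors = ()
        if i in has["editor"]:
            editors = ((*rng.choice(_EDITOR_POOL), ()),)

        affiliations = ()
        if i in has["affiliation"]:
            n_aff = 2 if i in has["international"] else 1
            picks = rng.sample(_AFF_POOL, n_aff)
            if i in has["international"] and picks[0][1] == picks[1][1]:
                picks[1] = _AFF_POOL[(_AFF_POOL.index(picks[1]) + 1) % len(_AFF_POOL)]
            affiliations = tuple(
                (parts, country if i in has["country"] else None)
                for parts, country in picks
            )

        sections = ()
        if i in has["body"]:
            n_sec = rng.randint(3, len(_SECTION_TEMPLATES))
            sections = tuple(_SECTION_TEMPLATES[:n_sec])

        n_ref = rng.randint(2, len(_REFERENCE_POOL)) if i in has["references"] else 0
        subjects = tuple(rng.sample(_SUBJECT_POOL, rng.randint(1, 3))) \
            if i in has["subject"] else ()
        keywords = tuple(rng.sample(_KEYWORD_POOL, rng.randint(2, 4))) \
            if i in has["keywords"] else ()

        specs.append(FixtureSpec(
            seed=i,
            title=rng.choice(_TITLE_POOL),
            journal=_weighted_choice(rng, _JOURNAL_POOL),
            doi=f"10.5555/synth.{seed}.{i:05d}",
            article_type=_weighted_choice(rng, _TYPE_POOL),
            volume=str(rng.randint(1, 40)) if i in has["volume"] else None,
            subjects=subjects,
            keywords=keywords,
            authors=authors,
            editors=editors,
            affiliations=affiliations,
            history=tuple(history),
            abstract=_ABSTRACT_TEMPLATE.format(topic=rng.choice(_KEYWORD_POOL))
            if i in has["abstract"] else None,
            sections=sections,
            references=tuple(rng.sample(_REFERENCE_POOL, n_ref)),
            quirks=frozenset(quirks),
        ))
    return specs


def generate_corpus(
    n: int,
    out_dir: str | Path,
    config: PrevalenceConfig | None = None,
    seed: int = 0,
) -> list[tuple[Path, GroundTruth]]:
    """Write an n-article corpus plus its ground-truth manifest.

    Files are named ``article_<i>.xml``; the manifest
    (``manifest.ndjson``) lists one ground truth per line.  The same
    (n, config, seed) always produces identical directories.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(n - 1)))
    results = []
    for i, spec in enumerate(build_corpus_specs(n, config, seed)):
        xml, truth = generate_article(spec)
        path = out_dir / f"article_{i:0{width}d}.xml"
        path.write_text(xml, encoding="utf-8")
        results.append((path, truth))
    write_manifest(results, out_dir / "manifest.ndjson")
    return results


def write_manifest(
    results: Iterable[tuple[Path, GroundTruth]], path: str | Path
) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for file_path, truth in results:
            fh.write(json.dumps({
                "file": Path(file_path).name,
                "quirks": sorted(truth.quirks),
                "accept_before_receive": truth.accept_before_receive,
                "publish_before_accept": truth.publish_before_accept,
                "future_date": truth.future_date,
                "record": record_to_dict(truth.record),
            }, ensure_ascii=False) + "\n")
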