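# Methods

## What the package does

`jatskit` decodes journal articles stored in NISO-JATS XML (the archival
format used by PubMed Central for its NXML files) into a unified
`ArticleRecord`: title, journal, DOI, article type, volume, subjects,
keywords, author and editor names with contributor IDs, affiliations,
unified country names, the labelled publication-history date stamps with
a derived earliest publication date, the abstract, the sectioned body
text, and the reference list.  On top of the decoder sit a corpus
profiler (bibliometric frequency tables and date-stamp sanity counts)
and a synthetic fixture generator that produces JATS files with known
ground truth, so that every extraction step is testable without any
archive download.

## Reading and fragment location

JATS corpora span decades of publisher tooling, so the reader never
assumes well-formedness.  Files are decoded using the encoding declared
in the XML prolog, falling back to UTF-8 and then Latin-1 with
replacement (each fallback logged).  Element occurrences are located by
a balanced-tag textual scan that matches local element names and
ignores namespace prefixes; a malformed element elsewhere in a document
therefore cannot prevent extraction of an unrelated tag.  An unclosed
target element is truncated at the document end and logged.  DTDs are
never fetched and no schema validation is attempted.

## Character unification

All text leaves the package in one plain representation:

* hexadecimal (`&#x3b1;`) and decimal (`&#945;`) numeric entities and
  the HTML5 named entities become Unicode characters (the named set is
  the standard library's HTML5 table; unknown or malformed entities are
  left verbatim and logged);
* 24 space codings (NBSP, thin/hair/em/en spaces, ideographic space,
  zero-width spaces, line/paragraph separators, ...) map to U+0020, and
  12 dash variants (en/em dash, minus sign, figure dash, ...) map to
  `-`; both tables ship as `data/space_codings.txt` and
  `data/hyphen_codings.txt`;
* 1 079 styled letter variants (mathematical bold/italic/script/
  fraktur/double-struck/monospace letters and digits, letterlike
  symbols, circled digits) fold to their plain equivalent via
  `data/char_synonyms.tsv`, generated from the Unicode compatibility
  decompositions;
* markup tags and hyperlink URLs are removed, whitespace runs collapse
  to single spaces, and output is NFC-normalized.

Conversion is applied to a fixed point (bounded at five passes), which
makes it idempotent even for doubly encoded input such as
`&amp;#x3b1;`.  In practice two passes suffice; the bound exists only to
guarantee termination.

### Spacing correction

"Spacing errors" is inherently a judgement call; the implemented rule
set is deliberately explicit and idempotent:

| rule | example |
| --- | --- |
| collapse whitespace runs | `a  b` → `a b` |
| no space before `, . ; : % ? ! ) ]` | `value ,` → `value,` |
| no space after `( [` | `( p` → `(p` |
| tighten `= < > ≤ ≥ ±` in numeric context | `p = .05` → `p=.05` |
| space after sentence punctuation between lowercase and uppercase | `end.Next` → `end. Next` |
| strip leading/trailing space | |

The numeric-context restriction on operator tightening avoids mangling
prose such as "a < b" appearing in running text; it fires only when a
digit, period or parenthesis follows.

### Formula flattening

MathML renders to reading order: token elements concatenate, `mfrac`
becomes `a/b`, `msup`/`msub` become `^`/`_`, `msqrt` becomes `√(...)`;
`annotation` alternatives are skipped.  LaTeX-style (MathJax) notation
strips `$$`, `\(`, `\)` markers and applies a fixed macro table (Greek
letters, comparison operators, `\frac` → `a/b`, `\times`, `\pm`, ...);
anything unrecognized degrades to concatenated argument text.  Spaces
are removed from flattened formulas, so `p < 0.05` in MathML tokens
comes out as `p<0.05`.  A formula represented only by a referenced
image has no recoverable text: it flattens to an empty string and emits
an `image_formula` log entry.  Full LaTeX semantics and OCR of formula
images are out of scope.

## Publication history

Date stamps live in `<date>` elements inside `<history>` and in
`<pub-date>` elements.  The recognized label vocabulary has exactly 14
entries: accepted, collection, ecorrected, epreprint, epub,
nihms_submitted, pmc-release, ppub, print, pub, received, retracted,
rev-recd, submitted.  Unknown labels land in a logged catch-all bucket;
a duplicated label keeps the first stamp.  A stamp without a usable
year, or with month/day out of range, is dropped and logged.

Missing month and day are completed to 1 **only when dates are
compared**; the raw partial values are preserved in the record.  The
unified earliest publication date (`pub_date`) is the minimum completed
date over the six publication-event labels {epub, ppub, print, pub,
collection, pmc-release} — the remaining eight labels describe
editorial or administrative events, not publication.  When none of the
six is present, `pub_year` falls back to the earliest year over all
stamps.  Two consequences of the completion rule are documented rather
than patched: a year-only `collection` stamp can dominate a later fully
dated `epub` stamp, and year-only stamps are generally favored as
"earliest".

Editorial lags are day differences on completed dates: time to accept =
accepted − received, time to publish = publication date − accepted.
Negative values are preserved deliberately — they are the anomaly
signal the profiler counts.  Future-dated stamps (relative to an
explicitly supplied reference date, never the wall clock) are likewise
retained and surfaced by the profiler, not silenced.

## Contributors and countries

All-caps name tokens of length ≥ 2 are recased to initial capitals
per space- or hyphen-separated token; mixed-case tokens (`McDonald`)
and lowercase particles (`van`) are never touched.  Optional given-name
shortening reduces each token to its initial plus period (`Wei` →
`W.`, `Min-Jun` → `M.-J.`).  Contributor IDs are harvested from
`<contrib-id>` elements, with the ORCID 16-digit pattern as a fallback
when the scheme attribute is missing.

Affiliations flatten to one comma-separated string per `<aff>` element;
linking labels and superscript markers are dropped.  Country
recognition prefers explicit `<country>` elements; otherwise a
dictionary search is anchored at the **end** of the affiliation string
(after stripping trailing punctuation, postal codes and e-mail
addresses), so an institution name like "Georgia Institute of
Technology" mid-string is never mistaken for the country Georgia.  The
dictionary is a canonical name list (`data/countries.txt`, 200 entries)
plus an alias table (`data/country_aliases.tsv`: UK, USA, Peoples Rep.
of China, Republic of Korea, historical and native spellings, ...);
matching is case-insensitive, so all-caps forms need no separate
entries.  Genuinely ambiguous tokens at string end (a line actually
ending "..., Georgia, USA" resolves via the later USA match only if it
is last) are a known limitation of end-anchored matching.  Author
disambiguation across documents is explicitly out of scope.

## Text parts

Sections and subsections are not differentiated: the body flattens to
one sequential (title, text) list in reading order, with untitled
leading content as an empty-titled section.  Figures, tables and their
captions are excluded from section text; formulas pass through the
flattener.  The `sectionsplit` merge treats each pattern-matching title
as the start of a main-section group that absorbs following
non-matching sections (blank-line separated, merged titles retained);
content before the first match forms its own leading group so that text
is conserved.

Presence of the abstract and of the body text follows a 30-character
rule: extracted text shorter than that counts as not present.

The sentence splitter breaks on `.`/`!`/`?` followed by whitespace and
an uppercase letter or digit, protecting decimal numbers, a shipped
abbreviation list (`data/abbreviations.txt`), single initials and short
enumerators.  Joining the output with single spaces reproduces the
input modulo whitespace.  Abbreviations absent from the list cause
over-splitting ("..., etc. The next..."), and an abbreviation that
genuinely ends a sentence causes under-splitting; both are accepted
costs of a dictionary approach.

References render to one cleaned string each: free-text
`mixed-citation` entries pass through; structured `element-citation`
parts are joined with commas in document order.  Parsing references
into author/year/journal fields is out of scope.

## Corpus profiler

The tag-use table reports presence frequencies for 16 content elements,
overall and per publication-year period.  Period bins are right-closed;
the first bin is closed on both sides and starts at the earliest
observed publication year.  Records without a publication year count in
the totals column only and are reported separately, so period columns
need not sum to the corpus total.  Journal-size bins are 1, 2–10,
11–100, 101–1000, 1001–10⁴, 10⁴+1–10⁵, >10⁵ articles per journal.
Decoding a collection is order-normalized (records sorted by path) and
skips undecodable files with a logged warning, failing only when
nothing decodes.  All tables are plain pandas DataFrames written as CSV
with stable column order.

## The fixture generator

The generator is first-class, tested code, not a test helper.  Each
`FixtureSpec` describes the planted record plus a set of quirk toggles
drawn from the dialect variation seen in real archives:

* surface quirks (hex/decimal/named entities, all-caps names, untagged
  affiliations, alternative space codings, nested subject groups,
  image-only inline formulas, duplicated date labels, subsectioned
  bodies) change only the XML encoding — decoding with and without them
  yields identical records, and the test suite asserts exactly that;
* semantic quirks (missing month/day, an embedded MathML formula,
  reversed accept/receive dates, future-dated stamps) change the
  planted content, and the ground truth changes with them.

Corpus generation realizes presence rates by deterministic allocation:
exactly `round(n·p)` records receive a feature, selected by a seeded
per-feature shuffle, so profiler expectations are exact counts with no
sampling error.  Default rates mirror the overall tag-use frequencies
of a large open-access archive (abstract 0.879, affiliation 0.948,
author 0.969, country 0.829, editor 0.126, keywords 0.599, references
0.903, body 0.885, subject 0.998, volume 0.487, at least one
ID-tagged author 0.098, international share 0.308 of country-bearing
records, and small date-anomaly rates).  Sections and body text are
tied to a single body feature because their observed rates are
indistinguishable at these corpus sizes.  Name, journal, subject and
keyword pools are skewed so that frequency-table tests have a known
dominant label ("Wang, Wei"; "PLoS ONE"; "Covid-19").  The future-date
reference is fixed at 2021-01-01.

What the generator does **not** emulate: deeply broken markup beyond
one unclosed element, publisher-specific tag dialects outside JATS,
non-Latin scripts in names, multi-paragraph structured abstracts, and
real-world affiliation noise.  Passing the round-trip suite therefore
shows the extractors are exact on the dialect space the generator
covers, not on every file in the wild.

## Problem sizes and determinism

The test suite and the acceptance script use corpora of 10–1 000
articles and string samples of 1 000; these sizes give exact,
deterministic expectations (by construction of the allocator) while
keeping a full run in seconds.  All randomness flows from explicit
seeds; property-based tests run derandomized.  Every check the
documentation mentions is computed by the tests or the acceptance
script at run time.
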