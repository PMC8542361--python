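import datetime as dt
import random

import pytest

from jatskit.metadata import (
    HISTORY_LABELS,
    OTHER_LABEL,
    PUBLICATION_EVENT_LABELS,
    DateStampSet,
    PartialDate,
    compute_pub_date,
    get_history,
    get_keywords,
    get_simple_tag,
    get_subjects,
    publication_lags,
)


def history_xml(*dates: str) -> str:
    return f"<article><front><history>{''.join(dates)}</history></front></article>"


def date_el(label: str, y=None, m=None, d=None) -> str:
    parts = "".join(
        f"<{t}>{v}</{t}>" for t, v in (("day", d), ("month", m), ("year", y))
        if v is not None
    )
    return f'<date date-type="{label}">{parts}</date>'


class TestSimpleTags:
    def test_entity_coded_title(self):
        doc = (
            "<article><title-group><article-title>Big &#x3b1; study"
            "</article-title></title-group></article>"
        )
        assert get_simple_tag(doc, "title") == "Big α study"

    def test_type_from_article_attribute(self):
        doc = '<article article-type="research-article"><front/></article>'
        assert get_simple_tag(doc, "type") == "research-article"

    def test_missing_volume_is_none_not_empty(self):
        assert get_simple_tag("<article><front/></article>", "volume") is None

    def test_volume_in_reference_not_mistaken_for_front_matter(self):
        doc = (
            "<article><front/><back><ref-list><ref><element-citation>"
            "<volume>99</volume></element-citation></ref></ref-list></back></article>"
        )
        assert get_simple_tag(doc, "volume") is None

    def test_doi_requires_type_attribute(self):
        doc = (
            '<article><article-id pub-id-type="pmid">123</article-id>'
            '<article-id pub-id-type="doi">10.1/x</article-id></article>'
        )
        assert get_simple_tag(doc, "doi") == "10.1/x"

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError):
            get_simple_tag("<article/>", "publisher")


class TestSubjectsKeywords:
    def test_nested_subjects_flattened(self):
        doc = (
            "<article><subj-group><subject>Biology</subject>"
            "<subj-group><subject>Genetics</subject></subj-group>"
            "</subj-group></article>"
        )
        assert get_subjects(doc) == ("Biology", "Genetics")

    def test_two_keywords(self):
        doc = "<article><kwd-group><kwd>Covid-19</kwd><kwd>SARS-Cov-2</kwd></kwd-group></article>"
        assert get_keywords(doc) == ("Covid-19", "SARS-Cov-2")

    def test_separator_only_keywords_dropped(self):
        doc = "<article><kwd-group><kwd>alpha</kwd><kwd>;</kwd><kwd>beta</kwd></kwd-group></article>"
        assert get_keywords(doc) == ("alpha", "beta")

    def test_no_keyword_group(self):
        assert get_keywords("<article/>") == ()


class TestGetHistory:
    def test_three_stamps(self):
        doc = history_xml(
            date_el("received", 2010, 3, 1),
            date_el("accepted", 2010, 6, 15),
            date_el("epub", 2010, 7, 1),
        )
        stamps = get_history(doc)
        assert len(stamps) == 3
        assert stamps.get("received") == PartialDate(2010, 3, 1)

    def test_year_only_stamp_keeps_partial_form(self):
        stamps = get_history(history_xml(date_el("ppub", 1999)))
        assert stamps.get("ppub") == PartialDate(1999, None, None)
        assert stamps.get("ppub").completed() == dt.date(1999, 1, 1)

    def test_invalid_day_drops_stamp(self, caplog):
        with caplog.at_level("INFO", logger="jatskit.metadata"):
            stamps = get_history(history_xml(date_el("received", 2010, 5, 42)))
        assert len(stamps) == 0
        assert any("dropped" in r.message for r in caplog.records)

    def test_duplicate_label_keeps_first(self):
        stamps = get_history(
            history_xml(date_el("received", 2010, 1, 1), date_el("received", 2011, 1, 1))
        )
        assert stamps.get("received") == PartialDate(2010, 1, 1)

    def test_unknown_label_bucketed(self):
        stamps = get_history(history_xml(date_el("weird-event", 2010, 1, 1)))
        assert stamps.get(OTHER_LABEL) == PartialDate(2010, 1, 1)

    def test_pub_date_elements_recognized(self):
        doc = (
            "<article><pub-date pub-type='epub'><day>03</day><month>09</month>"
            "<year>2005</year></pub-date></article>"
        )
        assert get_history(doc).get("epub") == PartialDate(2005, 9, 3)

    def test_vocabulary_has_fourteen_labels_all_recognized(self):
        assert len(HISTORY_LABELS) == 14
        for label in sorted(HISTORY_LABELS):
            stamps = get_history(history_xml(date_el(label, 2015, 2, 3)))
            assert stamps.get(label) == PartialDate(2015, 2, 3), label


class TestComputePubDate:
    def test_minimum_of_event_stamps(self):
        stamps = DateStampSet()
        stamps.add("epub", PartialDate(2005, 9, 3))
        stamps.add("ppub", PartialDate(2005, 8, 1))
        pub, year = compute_pub_date(stamps)
        assert pub == PartialDate(2005, 8, 1)
        assert year == 2005

    def test_fallback_year_from_editorial_stamp(self):
        stamps = DateStampSet()
        stamps.add("accepted", PartialDate(2011, 5, 2))
        pub, year = compute_pub_date(stamps)
        assert pub is None
        assert year == 2011

    def test_empty_set(self):
        assert compute_pub_date(DateStampSet()) == (None, None)

    def test_six_candidate_labels(self):
        assert len(PUBLICATION_EVENT_LABELS) == 6

    def test_order_invariant(self):
        dates = [
            ("epub", PartialDate(2012, 6, 1)),
            ("collection", PartialDate(2012, None, None)),
            ("ppub", PartialDate(2013, 1, 1)),
            ("received", PartialDate(2011, 12, 1)),
        ]
        rng = random.Random(0)
        results = set()
        for _ in range(10):
            rng.shuffle(dates)
            stamps = DateStampSet()
            for label, date in dates:
                stamps.add(label, date)
            results.add(compute_pub_date(stamps))
        assert results == {(PartialDate(2012, None, None), 2012)}

    def test_pub_year_matches_pub_date(self):
        stamps = DateStampSet()
        stamps.add("pub", PartialDate(2018, 4, 2))
        stamps.add("pmc-release", PartialDate(2019, 1, 1))
        pub, year = compute_pub_date(stamps)
        assert year == pub.year


class TestPublicationLags:
    def test_negative_time_to_accept(self):
        stamps = DateStampSet()
        stamps.add("received", PartialDate(2020, 5, 1))
        stamps.add("accepted", PartialDate(2020, 4, 1))
        t_accept, _ = publication_lags(stamps, None)
        assert t_accept == -30

    def test_negative_time_to_publish(self):
        stamps = DateStampSet()
        stamps.add("accepted", PartialDate(2020, 4, 1))
        stamps.add("epub", PartialDate(2020, 3, 1))
        pub, _ = compute_pub_date(stamps)
        _, t_publish = publication_lags(stamps, pub)
        assert t_publish == -31

    def test_missing_operands(self):
        stamps = DateStampSet()
        stamps.add("received", PartialDate(2020, 5, 1))
        assert publication_lags(stamps, None) == (None, None)
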