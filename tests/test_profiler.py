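import dataclasses
import datetime as dt
import random

import pytest

from jatskit.corpus_profiler import (
    country_cooccurrence,
    date_anomalies,
    decode_collection,
    frequency_table,
    profile_corpus,
    tag_use_table,
)
from jatskit.fixture_forge import (
    REFERENCE_DATE,
    FixtureSpec,
    PrevalenceConfig,
    generate_corpus,
)
from jatskit.jats_io import JatsReadError
from jatskit.record import ArticleRecord, record_to_dict
from jatskit.metadata import DateStampSet, PartialDate


def minimal_record(**kwargs) -> ArticleRecord:
    return ArticleRecord(**kwargs)


def record_with_year(year, **kwargs) -> ArticleRecord:
    stamps = DateStampSet()
    stamps.add("epub", PartialDate(year, 1, 1))
    return ArticleRecord(history=stamps, pub_year=year, **kwargs)


class TestDecodeCollection:
    def test_directory_of_fixtures(self, tmp_path):
        generate_corpus(10, tmp_path / "c", seed=1)
        records = decode_collection(tmp_path / "c")
        assert len(records) == 10

    def test_corrupt_file_skipped(self, tmp_path, caplog):
        generate_corpus(9, tmp_path / "c", seed=1)
        (tmp_path / "c" / "article_9999.xml").write_text("")
        with caplog.at_level("WARNING", logger="jatskit.corpus_profiler"):
            records = decode_collection(tmp_path / "c")
        assert len(records) == 9
        assert any("skipping" in r.message for r in caplog.records)

    def test_empty_directory_error(self, tmp_path):
        with pytest.raises(JatsReadError):
            decode_collection(tmp_path)

    def test_order_independent(self, tmp_path):
        generate_corpus(8, tmp_path / "c", seed=2)
        paths = [p for p in (tmp_path / "c").glob("*.xml")]
        shuffled = paths[:]
        random.Random(0).shuffle(shuffled)
        a = [record_to_dict(r) for r in decode_collection(paths)]
        b = [record_to_dict(r) for r in decode_collection(shuffled)]
        assert a == b


class TestTagUseTable:
    def test_abstract_ratio(self):
        records = [
            record_with_year(2010, abstract="y" * 30, abstract_present=True)
            for _ in range(7)
        ] + [record_with_year(2010) for _ in range(3)]
        table = tag_use_table(records)
        assert table.frequencies.loc["abstract", "total"] == pytest.approx(0.70)

    def test_right_closed_binning_with_leading_bin(self):
        records = [record_with_year(y) for y in (1999, 2003, 2005)]
        table = tag_use_table(records, (2000, 2005))
        assert list(table.totals.index) == ["total", "[1999; 2000]", "(2000; 2005]"]
        assert table.totals["[1999; 2000]"] == 1  # 1999 in the leading bin
        assert table.totals["(2000; 2005]"] == 2  # 2003 and 2005 (right-closed)

    def test_record_without_pub_year_counts_in_total_only(self):
        records = [record_with_year(2010), minimal_record()]
        table = tag_use_table(records, (2005, 2015))
        assert table.totals["total"] == 2
        assert table.n_without_pub_year == 1
        assert table.totals.drop("total").sum() == 1

    def test_empty_keyword_content_is_absent(self, tmp_path):
        path = tmp_path / "a.xml"
        path.write_text(
            "<article><front><kwd-group></kwd-group></front></article>"
        )
        records = decode_collection([path])
        table = tag_use_table(records)
        assert table.frequencies.loc["keywords", "total"] == 0.0

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            tag_use_table([], (2005, 2000))


class TestFrequencyTable:
    def test_journal_bins(self):
        records = (
            [minimal_record(journal="A")]
            + [minimal_record(journal="B")]
            + [minimal_record(journal="C")] * 5
            + [minimal_record(journal="D")] * 150
        )
        table = frequency_table(records, "journal", bins=True).set_index("n")
        assert table.loc["1", "h"] == 2
        assert table.loc["2-10", "h"] == 1
        assert table.loc["101-1000", "h"] == 1
        assert table["h"].sum() == 4
        assert table["f"].sum() == pytest.approx(1.0)

    def test_type_counts(self):
        records = [minimal_record(type="research-article")] * 3 + [
            minimal_record(type="review")
        ]
        table = frequency_table(records, "type").set_index("label")
        assert table.loc["research-article", "count"] == 3
        assert table.loc["review", "count"] == 1

    def test_top_k(self):
        records = [minimal_record(type=t) for t in "aabbbc"]
        table = frequency_table(records, "type", top_k=1)
        assert list(table["label"]) == ["b"]

    def test_unknown_field(self):
        with pytest.raises(ValueError):
            frequency_table([], "publisher")


class TestDateAnomalies:
    def test_planted_reversals_counted(self, tmp_path):
        config = PrevalenceConfig(
            reversed_accept_receive=0.2, publish_before_accept=0.0, future_date=0.0
        )
        results = generate_corpus(10, tmp_path / "c", config=config, seed=4)
        records = decode_collection(tmp_path / "c")
        counts = date_anomalies(records, REFERENCE_DATE)
        planted = sum(t.accept_before_receive for _, t in results)
        assert planted == 2
        assert counts["n_accept_before_receive"] == planted

    def test_future_stamp_counted(self):
        stamps = DateStampSet()
        stamps.add("accepted", PartialDate(2100, 1, 14))
        records = [ArticleRecord(history=stamps)]
        counts = date_anomalies(records, dt.date(2021, 1, 1))
        assert counts["n_future_dates"] == 1

    def test_clean_corpus_zero(self, tmp_path):
        from jatskit.fixture_forge import QUIRK_PROFILES

        generate_corpus(10, tmp_path / "c", config=QUIRK_PROFILES["clean"], seed=1)
        records = decode_collection(tmp_path / "c")
        counts = date_anomalies(records, dt.date(2022, 1, 1))
        assert counts["n_accept_before_receive"] == 0
        assert counts["n_publish_before_accept"] == 0


class TestCountryCooccurrence:
    def test_enumeration(self):
        records = [
            minimal_record(countries=("United Kingdom", "United States")),
            minimal_record(countries=("United States",)),
            minimal_record(
                countries=("Germany", "United Kingdom", "United States")
            ),
        ]
        table, share = country_cooccurrence(records)
        table = table.set_index(["country_a", "country_b"])
        assert table.loc[("United Kingdom", "United States"), "count"] == 2
        assert table.loc[("Germany", "United States"), "count"] == 1
        assert table.loc[("Germany", "United Kingdom"), "count"] == 1
        assert share == pytest.approx(2 / 3)

    def test_no_multi_country_records(self):
        table, share = country_cooccurrence([minimal_record(countries=("France",))])
        assert table.empty
        assert share == 0.0


class TestProfileCorpus:
    def test_writes_all_tables(self, tmp_path):
        generate_corpus(20, tmp_path / "c", seed=6)
        written = profile_corpus(
            tmp_path / "c", tmp_path / "out", reference_date=REFERENCE_DATE
        )
        for name in (
            "tag_use.csv", "journal_bins.csv", "date_types.csv",
            "type_counts.csv", "anomalies.csv", "country_pairs.csv",
        ):
            assert written[name].exists(), name

    def test_tables_match_manifest_truth(self, tmp_path):
        results = generate_corpus(50, tmp_path / "c", seed=7)
        decoded = decode_collection(tmp_path / "c")
        truth_records = [t.record for _, t in results]
        got = tag_use_table(decoded, (2000, 2010, 2020)).to_frame()
        expected = tag_use_table(truth_records, (2000, 2010, 2020)).to_frame()
        assert got.equals(expected)
        got_pairs, got_share = country_cooccurrence(decoded)
        exp_pairs, exp_share = country_cooccurrence(truth_records)
        assert got_pairs.equals(exp_pairs)
        assert got_share == exp_share
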