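from pathlib import Path

import pytest
from hypothesis import given, settings, strategies as st

from jatskit.textparts import (
    Section,
    get_abstract,
    get_references,
    get_sections,
    split_into_main_sections,
    text2sentences,
)

ORACLE_PATH = Path(__file__).parent / "data" / "sentence_oracle.txt"


def load_oracle() -> list[list[str]]:
    blocks, current = [], []
    for line in ORACLE_PATH.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            continue
        if not line.strip():
            if current:
                blocks.append(current)
                current = []
        else:
            current.append(line.strip())
    if current:
        blocks.append(current)
    return blocks


def abstract_doc(text: str) -> str:
    return f"<article><abstract><p>{text}</p></abstract></article>"


class TestAbstract:
    def test_29_characters_not_present(self):
        text = "x" * 29
        extracted, present = get_abstract(abstract_doc(text))
        assert extracted == text
        assert present is False

    def test_30_characters_present(self):
        _, present = get_abstract(abstract_doc("x" * 30))
        assert present is True

    def test_missing_tag(self):
        assert get_abstract("<article/>") == ("", False)

    def test_as_sentences(self):
        text = "The model fits well in practice. The test was significant."
        sentences, present = get_abstract(abstract_doc(text), as_sentences=True)
        assert sentences == [
            "The model fits well in practice.",
            "The test was significant.",
        ]
        assert present is True


class TestSections:
    def test_nested_subsections_flattened_in_order(self):
        doc = (
            "<article><body>"
            "<sec><title>Intro</title><p>Start here.</p></sec>"
            "<sec><title>Method</title><p>Overview.</p>"
            "<sec><title>Participants</title><p>People.</p></sec>"
            "<sec><title>Measures</title><p>Scales.</p></sec></sec>"
            "</body></article>"
        )
        secs = get_sections(doc)
        assert [s.title for s in secs] == ["Intro", "Method", "Participants", "Measures"]
        assert secs[1].text == "Overview."

    def test_empty_body(self):
        assert get_sections("<article><body></body></article>") == []
        assert get_sections("<article/>") == []

    def test_untitled_leading_text(self):
        doc = "<article><body><p>Preamble text.</p><sec><title>A</title><p>B.</p></sec></body></article>"
        secs = get_sections(doc)
        assert secs[0].title == ""
        assert secs[0].text == "Preamble text."

    def test_figures_and_tables_excluded(self):
        doc = (
            "<article><body><sec><title>Results</title>"
            "<p>Before.</p><fig><caption><p>A figure caption.</p></caption>"
            '<graphic xlink:href="f.jpg"/></fig><p>After.</p></sec></body></article>'
        )
        assert get_sections(doc)[0].text == "Before. After."


class TestSectionSplit:
    TITLES = ["Introduction", "Method", "Participants", "Results", "Discussion"]
    PATTERNS = ["intro", "method", "result", "discussion"]

    def sections(self):
        return [Section(t, f"text of {t.lower()}") for t in self.TITLES]

    def test_listing_scenario_four_groups(self):
        groups = split_into_main_sections(self.sections(), self.PATTERNS)
        assert len(groups) == 4
        assert groups[1].titles() == ("Method", "Participants")
        assert "text of participants" in groups[1].text

    def test_empty_pattern_list_identity(self):
        secs = self.sections()
        assert split_into_main_sections(secs, []) == secs

    def test_no_match_single_group(self):
        groups = split_into_main_sections(self.sections(), ["zzz"])
        assert len(groups) == 1
        assert groups[0].titles() == tuple(self.TITLES)

    def test_text_conserved(self):
        secs = self.sections()
        groups = split_into_main_sections(secs, self.PATTERNS)
        assert "".join(g.text.replace("\n", "") for g in groups) == "".join(
            s.text for s in secs
        )

    @given(
        titles=st.lists(
            st.sampled_from(["Introduction", "Method", "Results", "Extra", "Notes"]),
            max_size=8,
        ),
        patterns=st.lists(st.sampled_from(["intro", "method", "result"]), max_size=3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_group_count_bounds(self, titles, patterns):
        secs = [Section(t, f"body {i}") for i, t in enumerate(titles)]
        groups = split_into_main_sections(secs, patterns)
        assert len(groups) <= len(secs)
        if patterns:
            matching = sum(
                any(p in t.lower() for p in patterns) for t in titles
            )
            assert len(groups) <= matching + 1


class TestText2Sentences:
    @pytest.mark.parametrize(
        ("text", "expected"),
        [
            (
                "The model fits. The test was significant (p < .05).",
                ["The model fits.", "The test was significant (p < .05)."],
            ),
            (
                "Estimates (M = 3.5, SD = 1.2) were stable.",
                ["Estimates (M = 3.5, SD = 1.2) were stable."],
            ),
            (
                "Smith et al. (2020) agree. We concur.",
                ["Smith et al. (2020) agree.", "We concur."],
            ),
            ("", []),
            ("One sentence without terminator", ["One sentence without terminator"]),
        ],
    )
    def test_examples(self, text, expected):
        assert text2sentences(text) == expected

    def test_oracle_agreement(self):
        blocks = load_oracle()
        assert sum(len(b) for b in blocks) >= 50
        for block in blocks:
            assert text2sentences(" ".join(block)) == block

    @given(st.text(max_size=300))
    @settings(max_examples=200, derandomize=True)
    def test_reconstruction(self, text):
        import re

        cleaned = re.sub(r"[\x00-\x08\x0e-\x1f]", "", text)
        normalized = re.sub(r"\s+", " ", cleaned).strip()
        assert " ".join(text2sentences(text)) == normalized


class TestReferences:
    def test_mixed_citations_in_order(self):
        doc = (
            "<article><back><ref-list>"
            "<ref><mixed-citation>First ref.</mixed-citation></ref>"
            "<ref><mixed-citation>Second ref.</mixed-citation></ref>"
            "<ref><mixed-citation>Third ref.</mixed-citation></ref>"
            "</ref-list></back></article>"
        )
        refs = get_references(doc)
        assert [r.raw for r in refs] == ["First ref.", "Second ref.", "Third ref."]
        assert [r.index for r in refs] == [0, 1, 2]

    def test_element_citation_parts_joined(self):
        doc = (
            "<article><back><ref-list><ref><element-citation>"
            "<person-group><name><surname>Smith</surname>"
            "<given-names>J</given-names></name></person-group>"
            "<year>2019</year><article-title>A title</article-title>"
            "<source>A journal</source><volume>7</volume>"
            "</element-citation></ref></ref-list></back></article>"
        )
        (ref,) = get_references(doc)
        for part in ("Smith J", "2019", "A title", "A journal", "7"):
            assert part in ref.raw

    def test_no_back_matter(self):
        assert get_references("<article><front/></article>") == []
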