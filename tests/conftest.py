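import dataclasses

import pytest

from jatskit.fixture_forge import FixtureSpec, generate_article


@pytest.fixture
def canonical_spec() -> FixtureSpec:
    """A fully populated article spec used across extractor tests."""
    return FixtureSpec(
        title="Big α study",
        journal="PLoS ONE",
        doi="10.5555/synth.test",
        volume="12",
        subjects=("Biology", "Genetics"),
        keywords=("Covid-19", "SARS-Cov-2"),
        authors=(
            ("Wang", "Wei", (("orcid", "0000-0002-1825-0097"),)),
            ("Müller", "Anna", ()),
        ),
        editors=(("Johnson", "Robert", ()),),
        affiliations=(
            (
                ("Institute of Psychology, University Hamburg",
                 "Von-Melle-Park 5", "20146 Hamburg"),
                "Germany",
            ),
        ),
        history=(
            ("received", (2010, 3, 1)),
            ("accepted", (2010, 6, 15)),
            ("epub", (2010, 7, 1)),
        ),
        abstract=(
            "This abstract clearly has more than thirty characters. "
            "It even has two sentences."
        ),
        sections=(
            ("Introduction", "We study things carefully and at length."),
            ("Method", "A standard protocol was used throughout the work."),
            ("Results", "Everything improved. The test was significant (p < .05)."),
        ),
        references=(
            "Smith J (2010). A paper about things. Journal of Examples, 1, 1-10.",
            "Chen J, Wang W (2018). Another paper. Reviews, 4, 1-20.",
        ),
    )


@pytest.fixture
def make_article(tmp_path):
    """Write a spec (with optional quirk overrides) to a file; return
    (path, ground truth)."""

    counter = iter(range(10_000))

    def _make(spec: FixtureSpec, **overrides):
        if overrides:
            spec = dataclasses.replace(spec, **overrides)
        xml, truth = generate_article(spec)
        path = tmp_path / f"fixture_{next(counter)}.xml"
        path.write_text(xml, encoding="utf-8")
        return path, truth

    return _make
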