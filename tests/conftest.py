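"""Shared fixtures: small hand corpora and a session-scoped synthetic study."""

from __future__ import annotations

import pytest

from themescape.records import BibRecord
from themescape.network import build_cooc, keyword_frequencies, select_keywords
from themescape.synthcorpus import default_config, generate_corpus


def make_record(rid, keywords, year=2020, abstract="some text", rcr=None,
                title="t", journal="j", affiliations=()):
    return BibRecord(
        record_id=rid,
        title=title,
        abstract=abstract,
        year=year,
        journal=journal,
        author_keywords=list(keywords),
        affiliations=list(affiliations),
        rcr=rcr,
    )


@pytest.fixture
def abc_corpus():
    """Three records with keyword sets {A,B}, {A,B,C}, {A,C}."""
    return [
        make_record("r1", ["A", "B"]),
        make_record("r2", ["A", "B", "C"]),
        make_record("r3", ["A", "C"]),
    ]


@pytest.fixture(scope="session")
def synth_study():
    """Reference synthetic study: 5 disjoint-vocab topics, 300 records."""
    config = default_config(n_records=300, n_topics=5, seed=0)
    corpus, truth = generate_corpus(config)
    return config, corpus, truth


@pytest.fixture(scope="session")
def synth_network(synth_study):
    _, corpus, _ = synth_study
    stats = keyword_frequencies(corpus)
    retained, _ = select_keywords(stats)
    return stats, retained, build_cooc(corpus, retained)
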