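import json

import numpy as np
import pytest

from themescape.records import (
    BibRecord,
    CountsLog,
    NormalizationRules,
    corpus_stats,
    extract_country,
    filter_complete,
    normalize_keywords,
    parse_records,
    write_jsonl,
)

from conftest import make_record

MEDLINE_SAMPLE = """\
PMID- 11111111
TI  - Social media surveillance of influenza.
AB  - We mined tweets for influenza-like illness signals.
DP  - 2019 Mar
JT  - Journal of Medical Internet Research
OT  - social media
OT  - influenza
AD  - Dept of Informatics, Example University, Boston, United States.

PMID- 22222222
TI  - A record with no abstract field.
DP  - 2021
JT  - Test Journal
OT  - data mining
"""


class TestParse:
    def test_empty_file_gives_empty_corpus(self, tmp_path):
        p = tmp_path / "empty.jsonl"
        p.write_text("")
        corpus, report = parse_records(p, "jsonl")
        assert corpus == [] and report.n_parsed == 0

    def test_jsonl_roundtrip_exact(self, tmp_path):
        corpus = [
            make_record("a", ["K1", "K2"], year=2018, rcr=1.5),
            make_record("b", ["K3"], year=2020),
            make_record("c", [], year=2021, abstract=""),
        ]
        p = tmp_path / "c.jsonl"
        write_jsonl(corpus, p)
        back, report = parse_records(p, "jsonl")
        assert [r.to_dict() for r in back] == [r.to_dict() for r in corpus]
        assert not report.skipped

    def test_medline_missing_abstract_flagged(self, tmp_path):
        p = tmp_path / "sample.nbib"
        p.write_text(MEDLINE_SAMPLE)
        corpus, report = parse_records(p, "medline")
        assert len(corpus) == 2
        assert corpus[0].year == 2019
        assert corpus[0].author_keywords == ["social media", "influenza"]
        assert corpus[1].abstract == ""
        assert "22222222" in report.missing_abstract

    def test_malformed_jsonl_line_skipped_not_silent(self, tmp_path):
        p = tmp_path / "bad.jsonl"
        p.write_text('{"record_id": "ok", "year": 2020}\nnot json\n')
        corpus, report = parse_records(p, "jsonl")
        assert len(corpus) == 1 and len(report.skipped) == 1

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_records(tmp_path / "nope.jsonl", "jsonl")

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.jsonl"
        p.write_text('{"record_id": "x"}\n{"record_id": "x"}\n')
        with pytest.raises(ValueError, match="duplicate"):
            parse_records(p, "jsonl")


class TestFilter:
    def test_records_missing_keywords_excluded(self):
        corpus = [
            make_record("a", ["k"]),
            make_record("b", ["k"]),
            make_record("c", ["k"]),
            make_record("d", []),
            make_record("e", [""]),
        ]
        kept, log = filter_complete(corpus, (2015, 2025))
        assert [r.record_id for r in kept] == ["a", "b", "c"]
        assert log.n_missing_abstract_or_keywords == 2
        assert log.n_retained == log.n_retrieved - log.n_missing_abstract_or_keywords

    def test_complete_corpus_identity_and_idempotent(self):
        corpus = [make_record(f"r{i}", ["k"]) for i in range(4)]
        kept, log = filter_complete(corpus, (2015, 2025))
        assert kept == corpus and log.n_missing_abstract_or_keywords == 0
        again, log2 = filter_complete(kept, (2015, 2025))
        assert again == kept and log2.n_retained == log.n_retained

    def test_year_window_and_unknown_year(self):
        corpus = [
            make_record("in", ["k"], year=2020),
            make_record("early", ["k"], year=2010),
            make_record("undated", ["k"], year=None),
        ]
        kept, _ = filter_complete(corpus, (2015, 2025))
        assert [r.record_id for r in kept] == ["in"]

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            filter_complete([], (2025, 2015))

    def test_counts_log_identity_enforced(self):
        with pytest.raises(ValueError):
            CountsLog(n_retrieved=10, n_missing_abstract_or_keywords=2, n_retained=9)


class TestNormalize:
    def test_abbreviation_expansion_deduplicates(self):
        rules = NormalizationRules(
            abbreviation_map={"nlp": "natural language processing"}
        )
        corpus = [make_record("a", ["NLP", "natural language processing"])]
        out = normalize_keywords(corpus, rules)
        assert out[0].author_keywords == ["natural language processing"]

    def test_plural_folds_only_when_singular_attested(self):
        corpus = [make_record("a", ["pandemics", "pandemic"]),
                  make_record("b", ["measles"])]
        out = normalize_keywords(corpus)
        assert out[0].author_keywords == ["pandemic"]
        assert out[1].author_keywords == ["measles"]  # no attested singular

    def test_idempotent_on_random_keywords(self):
        rng = np.random.default_rng(3)
        vocab = [f"term{i}" for i in range(30)] + [f"term{i}s" for i in range(10)]
        corpus = [
            make_record(f"r{j}", list(rng.choice(vocab, size=5, replace=False)))
            for j in range(10)
        ]
        rules = NormalizationRules(synonym_map={"term0": "term1"})
        once = normalize_keywords(corpus, rules)
        twice = normalize_keywords(once, rules)
        assert [r.author_keywords for r in once] == [r.author_keywords for r in twice]

    def test_never_increases_distinct_keywords(self):
        corpus = [make_record("a", ["Alpha", "alpha ", "BETAS", "beta"])]
        out = normalize_keywords(corpus)
        before = {k.lower().strip() for k in corpus[0].author_keywords}
        assert len(set(out[0].author_keywords)) <= len(before)

    def test_cyclic_map_rejected_upfront(self):
        with pytest.raises(ValueError, match="idempotent"):
            NormalizationRules(synonym_map={"a": "b", "b": "a"})


class TestStats:
    def test_singleton_country_is_100_percent(self):
        corpus = [make_record("a", ["k"], affiliations=["Uni, Paris, France"])]
        tables = corpus_stats(corpus)
        row = tables["countries"].iloc[0]
        assert row["value"] == "France" and row["pct"] == 100.0

    def test_reference_percentage_rounding(self):
        # 54 of 189 records from one country -> 28.6%
        corpus = [
            make_record(f"r{i}", ["k"],
                        affiliations=["U, United States" if i < 54 else "U, China"])
            for i in range(189)
        ]
        tables = corpus_stats(corpus)
        us = tables["countries"].set_index("value").loc["United States"]
        assert us["n"] == 54 and us["pct"] == 28.6

    def test_annual_counts_zero_filled(self):
        corpus = [make_record("a", ["k"], year=2016), make_record("b", ["k"], year=2019)]
        annual = corpus_stats(corpus, window=(2015, 2020))["annual_counts"]
        assert list(annual["year"]) == list(range(2015, 2021))
        assert list(annual["n"]) == [0, 1, 0, 0, 1, 0]

    def test_percentages_bounded_per_category(self):
        rng = np.random.default_rng(0)
        corpus = [
            make_record(
                f"r{i}", [f"kw{rng.integers(5)}"],
                journal=f"J{rng.integers(4)}",
                affiliations=[f"U, {['France', 'China', 'Japan'][rng.integers(3)]}"],
            )
            for i in range(200)
        ]
        tables = corpus_stats(corpus, top_n=50)
        for name in ("countries", "journals"):
            assert tables[name]["pct"].sum() <= 100.0 + 0.05 * len(tables[name])

    def test_unknown_country_fallback(self):
        assert extract_country("Somewhere, Atlantis") == "unknown"
        assert extract_country("") == "unknown"
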