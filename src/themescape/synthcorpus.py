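"""Synthetic corpus generator with planted thematic structure.

Emulates the shape of a PubMed-derived bibliometric corpus: each record has a
dominant planted topic, author keywords drawn mostly from that topic's
vocabulary, a title/abstract built as a topic-conditioned token bag, a year
drawn from the topic's temporal profile (optionally amplified inside a burst
window), and an optional lognormal relative citation ratio centered on the
topic mean. All randomness flows from a single integer seed, so identical
configurations produce byte-identical corpora.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import BibRecord

__all__ = ["TopicSpec", "SynthConfig", "generate_corpus", "inject_burst_series",
           "default_config"]


@dataclass(frozen=True)
class TopicSpec:
    topic_id: int
    keyword_vocab: tuple[str, ...]
    token_vocab: tuple[str, ...]
    year_profile: tuple[tuple[int, float], ...]  # (year, weight), weights sum to 1
    burst_window: Optional[tuple[int, int, float]] = None  # start, end, multiplier
    mean_rcr: Optional[float] = None

    def __post_init__(self) -> None:
        weights = [w for _, w in self.year_profile]
        if any(w < 0 for w in weights):
            raise ValueError("year_profile weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-8:
            raise ValueError("year_profile weights must sum to 1")
        if self.burst_window is not None and self.burst_window[2] <= 1:
            raise ValueError("burst multiplier must exceed 1")

    @property
    def years(self) -> list[int]:
        return [y for y, _ in self.year_profile]


@dataclass(frozen=True)
class SynthConfig:
    n_records: int
    topics: tuple[TopicSpec, ...]
    background_vocab: tuple[str, ...] = ()
    keywords_per_record: tuple[int, int] = (3, 6)
    mixture_concentration: float = 9.0
    seed: int = 0
    rcr_sigma: float = 0.5
    tokens_per_abstract: int = 40
    max_vocab_overlap: float = 0.2
    # relative prevalence of each topic (uniform when empty); a skew here
    # plants a frequency/strength gradient across topics
    topic_weights: tuple[float, ...] = ()
    # per-record Bernoulli inclusion keywords with a year-dependent rate;
    # keyword -> (start_year, end_year, multiplier)
    keyword_bursts: tuple[tuple[str, tuple[int, int, float]], ...] = ()

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if len(self.topics) < 2:
            raise ValueError("at least 2 topics are required")
        if self.mixture_concentration <= 0:
            raise ValueError("mixture_concentration must be positive")
        lo, hi = self.keywords_per_record
        if not (1 <= lo <= hi):
            raise ValueError("invalid keywords_per_record range")
        if self.topic_weights and len(self.topic_weights) != len(self.topics):
            raise ValueError("topic_weights length must match topics")
        vocabs = [set(t.keyword_vocab) for t in self.topics]
        union = set().union(*vocabs)
        overlap = sum(len(v) for v in vocabs) - len(union)
        if union and overlap / len(union) > self.max_vocab_overlap:
            warnings.warn(
                "topic keyword vocabularies overlap beyond the configured "
                "fraction; ground truth is ambiguous",
                stacklevel=2,
            )

    @property
    def all_years(self) -> list[int]:
        return sorted({y for t in self.topics for y in t.years})


def _year_weights(topic: TopicSpec) -> tuple[np.ndarray, np.ndarray]:
    years = np.array([y for y, _ in topic.year_profile])
    w = np.array([wt for _, wt in topic.year_profile], dtype=float)
    if topic.burst_window is not None:
        lo, hi, mult = topic.burst_window
        w = np.where((years >= lo) & (years <= hi), w * mult, w)
    return years, w / w.sum()


def generate_corpus(
    config: SynthConfig,
) -> tuple[list[BibRecord], dict]:
    """Draw a corpus from ``config``.

    Returns ``(corpus, ground_truth)`` where ``ground_truth`` has keys
    ``record_topic`` (record_id -> topic_id) and ``keyword_topic``
    (keyword -> topic_id, background keywords absent).
    """
    rng = np.random.default_rng(config.seed)
    topics = config.topics
    n_topics = len(topics)
    p_own = config.mixture_concentration / (config.mixture_concentration + 1.0)
    if math.isinf(config.mixture_concentration):
        p_own = 1.0
    burst_kws = dict(config.keyword_bursts)
    for kw, (lo, hi, _mult) in burst_kws.items():
        if not any(kw in t.keyword_vocab for t in topics):
            raise ValueError(f"burst keyword {kw!r} not in any topic vocabulary")
        years = config.all_years
        if hi < years[0] or lo > years[-1]:
            raise ValueError(f"burst window {(lo, hi)} outside corpus years")

    kw_lo, kw_hi = config.keywords_per_record
    mean_kw = (kw_lo + kw_hi) / 2.0

    if config.topic_weights:
        tw = np.asarray(config.topic_weights, dtype=float)
        tw = tw / tw.sum()
    else:
        tw = np.full(n_topics, 1.0 / n_topics)

    corpus: list[BibRecord] = []
    record_topic: dict[str, int] = {}
    for i in range(config.n_records):
        t_idx = int(rng.choice(n_topics, p=tw))
        topic = topics[t_idx]
        years, weights = _year_weights(topic)
        year = int(rng.choice(years, p=weights))

        own = [k for k in topic.keyword_vocab if k not in burst_kws]
        other = [
            k
            for t in topics
            if t is not topic
            for k in t.keyword_vocab
            if k not in burst_kws
        ] + [k for k in config.background_vocab if k not in burst_kws]
        n_kw = int(rng.integers(kw_lo, kw_hi + 1))
        kws: dict[str, None] = {}
        for _ in range(n_kw):
            pool = own if (rng.random() < p_own or not other) else other
            kws.setdefault(str(pool[int(rng.integers(len(pool)))]))
        # burst keywords: independent Bernoulli inclusion at the keyword's
        # natural corpus-wide draw rate, multiplied inside the burst window.
        # The rate is topic-independent so multiplier * q stays below 1 and
        # the in-window/out-of-window count ratio equals the multiplier.
        for kw, (lo, hi, mult) in burst_kws.items():
            host = next(t for t in topics if kw in t.keyword_vocab)
            q = mean_kw / max(n_topics * len(host.keyword_vocab), 1)
            if lo <= year <= hi:
                q *= mult
            if rng.random() < min(q, 1.0):
                kws.setdefault(kw)

        n_tok = config.tokens_per_abstract
        tokens = [
            topic.token_vocab[int(rng.integers(len(topic.token_vocab)))]
            for _ in range(n_tok)
        ]
        rcr = None
        if topic.mean_rcr is not None:
            sigma = config.rcr_sigma
            mu = math.log(topic.mean_rcr) - sigma**2 / 2.0
            rcr = float(rng.lognormal(mu, sigma))
        rid = f"S{i:06d}"
        corpus.append(
            BibRecord(
                record_id=rid,
                title=" ".join(tokens[:8]),
                abstract=" ".join(tokens),
                year=year,
                journal=f"synthetic journal {t_idx + 1}",
                author_keywords=list(kws),
                mesh_terms=[],
                affiliations=[f"Synthetic Institute, Topic City, Country {t_idx + 1}"],
                rcr=rcr,
            )
        )
        record_topic[rid] = topic.topic_id

    keyword_topic = {
        k: t.topic_id for t in topics for k in t.keyword_vocab
    }
    return corpus, {"record_topic": record_topic, "keyword_topic": keyword_topic}


def inject_burst_series(
    config: SynthConfig,
    keyword: str,
    window: tuple[int, int],
    multiplier: float,
) -> SynthConfig:
    """Return a config in which ``keyword``'s per-record inclusion rate is
    multiplied by ``multiplier`` for records whose year falls in ``window``
    (rates of all other keywords are unchanged up to renormalization).

    A multiplier of 1 returns the config unchanged.
    """
    if multiplier == 1:
        return config
    if not any(keyword in t.keyword_vocab for t in config.topics):
        raise ValueError(f"keyword {keyword!r} not in any topic vocabulary")
    years = config.all_years
    lo, hi = window
    if hi < years[0] or lo > years[-1]:
        raise ValueError(f"burst window {window} outside corpus years {years[0]}-{years[-1]}")
    bursts = dict(config.keyword_bursts)
    bursts[keyword] = (lo, hi, float(multiplier))
    return dataclasses.replace(config, keyword_bursts=tuple(sorted(bursts.items())))


def default_config(
    n_records: int = 300,
    n_topics: int = 5,
    keywords_per_topic: int = 14,
    years: tuple[int, int] = (2015, 2025),
    seed: int = 0,
    mixture_concentration: float = 9.0,
    rcr_gradient: bool = False,
) -> SynthConfig:
    """Reference synthetic study: disjoint topic vocabularies, uniform year
    profiles, and (optionally) a cluster-dependent RCR gradient."""
    lo, hi = years
    yrs = list(range(lo, hi + 1))
    uniform = tuple((y, 1.0 / len(yrs)) for y in yrs)
    topics = []
    for t in range(n_topics):
        kv = tuple(f"topic{t}_kw{j}" for j in range(keywords_per_topic))
        tv = tuple(f"tok{t}_{j}" for j in range(60))
        topics.append(
            TopicSpec(
                topic_id=t,
                keyword_vocab=kv,
                token_vocab=tv,
                year_profile=uniform,
                mean_rcr=(0.5 + 0.5 * t) if rcr_gradient else 1.0,
            )
        )
    return SynthConfig(
        n_records=n_records,
        topics=tuple(topics),
        background_vocab=tuple(f"bg_kw{j}" for j in range(10)),
        keywords_per_record=(3, 6),
        mixture_concentration=mixture_concentration,
        seed=seed,
        # with an RCR gradient, higher-impact topics are also more prevalent,
        # planting a positive strength-RCR association for validation tests
        topic_weights=tuple(1.0 + 0.5 * t for t in range(n_topics))
        if rcr_gradient
        else (),
    )
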