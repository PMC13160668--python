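"""Keyword selection rules and the weighted keyword co-occurrence network.

Frequency counts are per record (a keyword repeated within one record counts
once). The default edge weighting is *fractional counting*: a record carrying
m retained keywords contributes 1/(m-1) to each of its C(m,2) pairs, so each
record adds a total weight of m/2 to the network.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .records import BibRecord

__all__ = ["KeywordStats", "CoocNetwork", "keyword_frequencies", "select_keywords",
           "build_cooc"]

WEIGHTINGS = ("raw", "fractional", "association")


@dataclass
class KeywordStats:
    keyword: str
    frequency: int
    years: dict[int, int] = field(default_factory=dict)
    recent_fraction: float = 0.0


class CoocNetwork:
    """Weighted undirected keyword co-occurrence graph.

    Thin wrapper over :class:`networkx.Graph` exposing the node metrics used
    downstream (degree = incident edge count; strength = sum of incident edge
    weights).
    """

    def __init__(self, graph: nx.Graph, weighting: str = "fractional"):
        self.graph = graph
        self.weighting = weighting

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(a, b), max(a, b), float(d["weight"]))
            for a, b, d in self.graph.edges(data=True)
        )

    def degree(self, k: str) -> int:
        return self.graph.degree(k)

    def strength(self, k: str) -> float:
        return float(self.graph.degree(k, weight="weight"))

    def total_weight(self) -> float:
        return float(self.graph.size(weight="weight"))

    def node_metrics(self) -> pd.DataFrame:
        rows = [
            {
                "keyword": k,
                "freq": self.graph.nodes[k].get("freq", 0),
                "overall_degree": self.degree(k),
                "network_strength": self.strength(k),
            }
            for k in self.nodes
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.edges(), columns=["kw_a", "kw_b", "weight"]).to_csv(
            out / "edges.csv", index=False
        )
        self.node_metrics().to_csv(out / "node_metrics.csv", index=False)
        nx.write_graphml(self.graph, out / "network.graphml")


def keyword_frequencies(
    corpus: list[BibRecord],
    window: Optional[tuple[int, int]] = None,
    recent_window: int = 5,
    reference_year: Optional[int] = None,
) -> list[KeywordStats]:
    """Per-keyword record counts, per-year profiles over the full window, and
    the fraction of the keyword's records falling in the recent window
    (years strictly after ``reference_year - recent_window``)."""
    if not corpus:
        return []
    years_present = [r.year for r in corpus if r.year is not None]
    lo, hi = window if window else (min(years_present), max(years_present))
    if reference_year is None:
        reference_year = hi
    cutoff = reference_year - recent_window
    counts: dict[str, dict[int, int]] = {}
    for rec in corpus:
        if rec.year is None:
            continue
        for kw in dict.fromkeys(rec.author_keywords):
            counts.setdefault(kw, {y: 0 for y in range(lo, hi + 1)})
            if lo <= rec.year <= hi:
                counts[kw][rec.year] += 1
    stats = []
    for kw in sorted(counts):
        yrs = counts[kw]
        freq = sum(yrs.values())
        if freq == 0:
            continue
        recent = sum(n for y, n in yrs.items() if y > cutoff)
        stats.append(
            KeywordStats(keyword=kw, frequency=freq, years=yrs,
                         recent_fraction=recent / freq)
        )
    stats.sort(key=lambda s: (-s.frequency, s.keyword))
    return stats


def select_keywords(
    stats: list[KeywordStats],
    min_freq: int = 3,
    drop_top: int = 2,
) -> tuple[set[str], dict]:
    """Apply the two retention rules: drop keywords with frequency below
    ``min_freq``, then remove the ``drop_top`` most frequent of the survivors
    (ties at the boundary resolved by removing reverse-lexicographically).

    Returns the retained set and a log of what was removed.
    """
    survivors = [s for s in stats if s.frequency >= min_freq]
    if drop_top >= len(survivors):
        raise ValueError(
            f"drop_top={drop_top} >= {len(survivors)} surviving keywords"
        )
    # order for removal: most frequent first; within a frequency tie remove the
    # lexicographically later keyword first
    removal_order = sorted(survivors, key=lambda s: (s.frequency, s.keyword),
                           reverse=True)
    dropped_top = [s.keyword for s in removal_order[:drop_top]]
    retained = {s.keyword for s in survivors} - set(dropped_top)
    log = {
        "n_input": len(stats),
        "n_low_freq_removed": len(stats) - len(survivors),
        "dropped_top": dropped_top,
        "n_retained": len(retained),
    }
    return retained, log


def build_cooc(
    corpus: list[BibRecord],
    retained: Iterable[str],
    weighting: str = "fractional",
) -> CoocNetwork:
    """Build the co-occurrence network over ``retained`` keywords.

    An edge exists iff the pair co-occurs in at least one record. Weightings:
    ``raw`` counts co-occurring records; ``fractional`` (default) adds
    1/(m-1) per record with m retained keywords; ``association`` divides the
    raw count by sqrt(freq_a * freq_b).
    """
    retained = set(retained)
    if not retained:
        raise ValueError("retained keyword set is empty")
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    g = nx.Graph()
    g.add_nodes_from(sorted(retained))
    freq: dict[str, int] = {k: 0 for k in retained}
    raw: dict[tuple[str, str], float] = {}
    frac: dict[tuple[str, str], float] = {}
    for rec in corpus:
        kws = sorted(set(rec.author_keywords) & retained)
        for k in kws:
            freq[k] += 1
        m = len(kws)
        if m < 2:
            continue
        for a, b in itertools.combinations(kws, 2):
            raw[(a, b)] = raw.get((a, b), 0.0) + 1.0
            frac[(a, b)] = frac.get((a, b), 0.0) + 1.0 / (m - 1)
    for (a, b), w_raw in raw.items():
        if weighting == "raw":
            w = w_raw
        elif weighting == "fractional":
            w = frac[(a, b)]
        else:
            w = w_raw / math.sqrt(freq[a] * freq[b])
        g.add_edge(a, b, weight=w)
    nx.set_node_attributes(g, freq, "freq")
    return CoocNetwork(g, weighting=weighting)
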