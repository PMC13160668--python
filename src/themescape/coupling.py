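"""Intercluster coupling: pair strengths, bridging keywords, global bridging.

Coupling strength between clusters A and B is the sum of weights on edges
with one endpoint in each. A keyword's contribution to a pair is the total
weight of its edges crossing that boundary, so every cross edge is credited
to *both* endpoints (dual attribution) and contributions over a pair sum to
exactly twice the pair strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import CoocNetwork

__all__ = ["CouplingReport", "pair_strengths", "bridging_keywords",
           "global_bridging", "coupling_report"]

Pair = tuple[int, int]


@dataclass
class CouplingReport:
    pair_strength: dict[Pair, float] = field(default_factory=dict)
    bridging: dict[Pair, list[tuple[str, int, float]]] = field(default_factory=dict)
    global_bridging: dict[str, float] = field(default_factory=dict)
    noise_cluster_flag: str = (
        "cluster 1 is the heterogeneous unassigned (noise) set; its coupling "
        "values aggregate a mixed pool rather than a single cohesive theme"
    )


def _check_labels(net: CoocNetwork, labels: dict[str, int]) -> None:
    missing = [k for k in net.nodes if k not in labels]
    if missing:
        raise ValueError(f"unlabeled network node(s): {missing[:5]}")


def pair_strengths(net: CoocNetwork, labels: dict[str, int]) -> dict[Pair, float]:
    """Sum of weights on cross-cluster edges, per unordered cluster pair.

    The noise cluster (1) participates as a regular cluster.
    """
    _check_labels(net, labels)
    out: dict[Pair, float] = {}
    for a, b, w in net.edges():
        ca, cb = labels[a], labels[b]
        if ca == cb:
            continue
        pair = (min(ca, cb), max(ca, cb))
        out[pair] = out.get(pair, 0.0) + w
    return out


def bridging_keywords(
    net: CoocNetwork,
    labels: dict[str, int],
    pair: Pair,
    top_k: int | None = None,
) -> list[tuple[str, int, float]]:
    """Ranked (keyword, source_cluster, contribution) for one cluster pair.

    contribution(k) = total weight of k's edges crossing the pair boundary;
    both endpoints of a cross edge are credited. Ranking is by descending
    contribution, ties broken lexicographically.
    """
    if top_k is not None and top_k <= 0:
        raise ValueError("top_k must be positive")
    _check_labels(net, labels)
    pa, pb = min(pair), max(pair)
    contrib: dict[str, float] = {}
    for a, b, w in net.edges():
        ca, cb = labels[a], labels[b]
        if (min(ca, cb), max(ca, cb)) != (pa, pb) or ca == cb:
            continue
        contrib[a] = contrib.get(a, 0.0) + w
        contrib[b] = contrib.get(b, 0.0) + w
    ranked = sorted(contrib.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [(k, labels[k], v) for k, v in ranked]
    return rows[:top_k] if top_k is not None else rows


def global_bridging(net: CoocNetwork, labels: dict[str, int]) -> dict[str, float]:
    """Per-keyword total weight of edges whose other endpoint lies in a
    different cluster (0 for keywords with only intra-cluster edges and for
    isolated keywords)."""
    _check_labels(net, labels)
    out = {k: 0.0 for k in net.nodes}
    for a, b, w in net.edges():
        if labels[a] != labels[b]:
            out[a] += w
            out[b] += w
    return out


def coupling_report(
    net: CoocNetwork, labels: dict[str, int], top_k: int = 5
) -> CouplingReport:
    strengths = pair_strengths(net, labels)
    return CouplingReport(
        pair_strength=strengths,
        bridging={p: bridging_keywords(net, labels, p, top_k) for p in strengths},
        global_bridging=global_bridging(net, labels),
    )
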