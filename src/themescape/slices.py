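"""Time-sliced thematic evolution.

The corpus is partitioned into consecutive year windows; each slice's
co-occurrence network is clustered with spectral clustering (symmetric-
normalized Laplacian, row-normalized bottom-K eigenvectors, deterministic
seeded k-means). K is selected by maximizing weighted Newman-Girvan
modularity over a scan range, with a Davies-Bouldin elbow fallback when the
modularity curve is flat. Slice clusters are aligned to the global solution
by best-match Jaccard on keyword sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import davies_bouldin_score

from .clustering import ClusterSolution
from .network import CoocNetwork
from .records import BibRecord

__all__ = [
    "SliceSolution",
    "AlignmentMap",
    "DEFAULT_SLICES",
    "slice_corpus",
    "spectral_cluster",
    "modularity",
    "select_k",
    "align_to_global",
]

#: study-period slices bracketing the explosive-growth cutoff
DEFAULT_SLICES = ((2015, 2019), (2020, 2023), (2024, 2025))


@dataclass
class SliceSolution:
    slice_bounds: tuple[int, int]
    k: int
    labels: dict[str, int]
    modularity_q: float
    dbi: Optional[float]
    scan_table: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class AlignmentMap:
    rows: list[dict] = field(default_factory=list)
    threshold: float = 0.3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def slice_corpus(
    corpus: list[BibRecord],
    boundaries: tuple[tuple[int, int], ...] = DEFAULT_SLICES,
) -> tuple[list[list[BibRecord]], list[str]]:
    """Partition records into inclusive year ranges; ranges must be disjoint
    and ordered. Out-of-range (or undated) records are dropped with a log."""
    for (a1, b1), (a2, b2) in zip(boundaries, boundaries[1:]):
        if a1 > b1 or a2 > b2 or b1 >= a2:
            raise ValueError(f"slice ranges must be ordered and disjoint: {boundaries}")
    if len(boundaries) == 1 and boundaries[0][0] > boundaries[0][1]:
        raise ValueError(f"inverted slice range {boundaries[0]}")
    slices: list[list[BibRecord]] = [[] for _ in boundaries]
    dropped: list[str] = []
    for rec in corpus:
        placed = False
        for i, (lo, hi) in enumerate(boundaries):
            if rec.year is not None and lo <= rec.year <= hi:
                slices[i].append(rec)
                placed = True
                break
        if not placed:
            dropped.append(f"{rec.record_id} (year={rec.year}) outside all slices")
    return slices, dropped


def _adjacency(net: CoocNetwork) -> tuple[np.ndarray, list[str]]:
    nodes = net.nodes
    idx = {k: i for i, k in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for a, b, weight in net.edges():
        w[idx[a], idx[b]] = weight
        w[idx[b], idx[a]] = weight
    return w, nodes


def _spectral_embedding(w: np.ndarray, k: int) -> np.ndarray:
    """Row-normalized bottom-k eigenvectors of the symmetric-normalized
    Laplacian L = I - D^{-1/2} W D^{-1/2} (isolated nodes get zero rows)."""
    deg = w.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    lap = np.eye(len(w)) - inv_sqrt[:, None] * w * inv_sqrt[None, :]
    lap = (lap + lap.T) / 2.0
    vals, vecs = np.linalg.eigh(lap)
    emb = vecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        emb = np.where(norms > 1e-12, emb / norms, emb)
    return emb


def _farthest_point_init(x: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic greedy farthest-point centers; the first center is the
    seeded random pick, each next center maximizes the distance to the chosen
    set (ties to the lowest index)."""
    rng = np.random.default_rng(seed)
    centers = [int(rng.integers(len(x)))]
    d = np.linalg.norm(x - x[centers[0]], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d))
        centers.append(nxt)
        d = np.minimum(d, np.linalg.norm(x - x[nxt], axis=1))
    return x[centers].copy()


def _kmeans(x: np.ndarray, k: int, seed: int, max_iter: int = 100) -> np.ndarray:
    centers = _farthest_point_init(x, k, seed)
    labels = np.full(len(x), -1, dtype=int)
    for _it in range(max_iter):
        dists = np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=2)
        new_labels = np.argmin(dists, axis=1)  # lowest index wins ties
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            mask = labels == c
            if mask.any():
                centers[c] = x[mask].mean(axis=0)
    return labels


def spectral_cluster(
    net: CoocNetwork, k: int, seed: int = 42
) -> dict[str, int]:
    """Cluster the network's nodes into ``k`` groups (labels 0..k-1).

    Identical seed implies identical labels. Isolated nodes have a zero
    embedding row and land together wherever k-means puts the origin.
    """
    if k < 2:
        raise ValueError("K must be >= 2")
    w, nodes = _adjacency(net)
    if k > len(nodes):
        raise ValueError(f"K={k} exceeds {len(nodes)} nodes")
    emb = _spectral_embedding(w, k)
    labels = _kmeans(emb, k, seed)
    return dict(zip(nodes, (int(l) for l in labels)))


def modularity(net: CoocNetwork, labels: dict[str, int]) -> float:
    """Weighted Newman-Girvan modularity
    Q = sum_c [ w_in,c / m - (s_c / 2m)^2 ], with m the total edge weight,
    w_in,c the intra-cluster weight, and s_c the total strength of cluster c.
    """
    nodes = net.nodes
    if not nodes:
        raise ValueError("empty network")
    missing = [k for k in nodes if k not in labels]
    if missing:
        raise ValueError(f"unlabeled node(s): {missing[:5]}")
    m = net.total_weight()
    if m == 0:
        return 0.0
    w_in: dict[int, float] = {}
    for a, b, w in net.edges():
        if labels[a] == labels[b]:
            w_in[labels[a]] = w_in.get(labels[a], 0.0) + w
    strength: dict[int, float] = {}
    for k in nodes:
        strength[labels[k]] = strength.get(labels[k], 0.0) + net.strength(k)
    q = 0.0
    for c in strength:
        q += w_in.get(c, 0.0) / m - (strength[c] / (2.0 * m)) ** 2
    return q


def select_k(
    net: CoocNetwork,
    k_range: range = range(2, 21),
    seed: int = 42,
    flat_eps: float = 0.01,
) -> tuple[int, pd.DataFrame, str]:
    """Scan K over ``k_range``: K* = argmax modularity; when the modularity
    curve is flat (max - median < ``flat_eps``) fall back to the
    Davies-Bouldin elbow (largest positive second difference of the DBI
    curve). Silhouette and CH could be added to the scan table but are not
    used for selection. Returns (K*, scan table, decision note)."""
    n = len(net.nodes)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError(f"no feasible K in {k_range} for {n} nodes")
    w, _ = _adjacency(net)
    rows = []
    for k in ks:
        labels = spectral_cluster(net, k, seed)
        q = modularity(net, labels)
        emb = _spectral_embedding(w, k)
        lab_arr = np.array([labels[node] for node in net.nodes])
        dbi = None
        if len(set(lab_arr)) >= 2:
            try:
                dbi = float(davies_bouldin_score(emb, lab_arr))
            except ValueError:
                dbi = None
        rows.append({"K": k, "modularity": q, "dbi": dbi})
    scan = pd.DataFrame(rows)
    qs = scan["modularity"].to_numpy()
    if qs.max() - np.median(qs) >= flat_eps:
        k_star = int(scan.loc[scan["modularity"].idxmax(), "K"])
        note = "selected by modularity maximum"
    else:
        dbis = scan["dbi"].to_numpy(dtype=float)
        if len(dbis) >= 3 and np.isfinite(dbis).all():
            second = dbis[:-2] - 2 * dbis[1:-1] + dbis[2:]
            k_star = int(scan["K"].iloc[int(np.argmax(second)) + 1])
            note = "flat modularity curve; selected by Davies-Bouldin elbow"
        else:
            k_star = int(scan["K"].iloc[0])
            note = "flat modularity curve and no usable DBI curve; smallest K kept"
    return k_star, scan, note


def align_to_global(
    slice_labels: dict[str, int],
    global_solution: ClusterSolution,
    threshold: float = 0.3,
) -> AlignmentMap:
    """Map each slice cluster to the global cluster maximizing the Jaccard
    index of their keyword sets (computed on set intersections; the slice
    vocabulary need not be a subset of the global one)."""
    amap = AlignmentMap(threshold=threshold)
    global_sets = {
        int(c): global_solution.members(int(c))
        for c in np.unique(global_solution.labels)
    }
    slice_clusters: dict[int, set[str]] = {}
    for kw, c in slice_labels.items():
        slice_clusters.setdefault(c, set()).add(kw)
    for c in sorted(slice_clusters):
        sset = slice_clusters[c]
        if not sset:
            continue
        best_c, best_j = None, -1.0
        for gc in sorted(global_sets):
            gset = global_sets[gc]
            union = len(sset | gset)
            j = len(sset & gset) / union if union else 0.0
            if j > best_j:
                best_c, best_j = gc, j
        amap.rows.append(
            {
                "slice_cluster": c,
                "global_cluster": best_c,
                "jaccard": best_j,
                "matched": bool(best_j > threshold),
            }
        )
    return amap
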