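"""Thematic clustering: UMAP reduction of the hybrid similarity, HDBSCAN with
noise retained as cluster 1, centroid distances, and internal quality metrics.

Cluster numbering convention: density clusters are relabeled 2..C+1 in order
of descending size (ties broken by the lexicographically smallest member);
points HDBSCAN leaves unassigned become cluster 1 — an "incubator pool" of
peripheral or cross-cutting keywords that is retained in every output, but
excluded from silhouette / Calinski-Harabasz / Davies-Bouldin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .semantics import HybridSimilarity

__all__ = [
    "ClusterSolution",
    "ClusterMetrics",
    "HDBSCAN_PROFILES",
    "DEFAULT_SEEDS",
    "reduce_umap",
    "cluster_hdbscan",
    "centroid_distances",
    "internal_metrics",
    "bootstrap_cluster_jaccard",
]

HDBSCAN_PROFILES = {
    "balanced": {"min_cluster_size": 8, "min_samples": 5},
    "fine": {"min_cluster_size": 5, "min_samples": 3},
}

#: multi-seed stability protocol: 3 independent runs
DEFAULT_SEEDS = (11, 23, 42)

NOISE_LABEL = 1


@dataclass
class ClusterSolution:
    keywords: list[str]
    coords2d: np.ndarray
    labels: np.ndarray  # noise = 1, thematic clusters 2..C+1
    profile_name: str = ""
    seed: int = 0
    centroid_distance: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_thematic(self) -> int:
        return len([c for c in np.unique(self.labels) if c != NOISE_LABEL])

    def members(self, label: int) -> set[str]:
        return {k for k, l in zip(self.keywords, self.labels) if l == label}

    def label_map(self) -> dict[str, int]:
        return dict(zip(self.keywords, (int(l) for l in self.labels)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "keyword": self.keywords,
                "cluster": self.labels.astype(int),
                "u1": self.coords2d[:, 0],
                "u2": self.coords2d[:, 1],
                "centroid_distance": self.centroid_distance,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


@dataclass
class ClusterMetrics:
    silhouette: Optional[float] = None
    calinski_harabasz: Optional[float] = None
    davies_bouldin: Optional[float] = None
    ari_across_seeds: Optional[float] = None
    bootstrap_jaccard: dict[int, float] = field(default_factory=dict)


def reduce_umap(
    hybrid: HybridSimilarity,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 42,
) -> np.ndarray:
    """2D UMAP embedding of the precomputed hybrid distance (1 - s_hyb).

    Deterministic for a fixed seed on a given platform (single-threaded,
    ``random_state`` fixed).
    """
    n = len(hybrid.keywords)
    if n <= n_neighbors:
        raise ValueError(
            f"{n} keywords <= n_neighbors={n_neighbors}; lower n_neighbors"
        )
    import umap  # deferred: numba compilation is slow at import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric="precomputed",
            random_state=seed,
            n_jobs=1,
        )
        coords = reducer.fit_transform(hybrid.distance())
    return np.asarray(coords, dtype=float)


def _relabel(raw_labels: np.ndarray, keywords: Sequence[str]) -> np.ndarray:
    """Map HDBSCAN labels (-1 = noise) to the 1-based presentation scheme:
    noise -> 1; clusters -> 2..C+1 by descending size, ties by smallest
    member keyword."""
    labels = np.full(len(raw_labels), NOISE_LABEL, dtype=int)
    clusters = [c for c in np.unique(raw_labels) if c != -1]

    def sort_key(c: int):
        members = [keywords[i] for i in np.flatnonzero(raw_labels == c)]
        return (-len(members), min(members))

    for new, c in enumerate(sorted(clusters, key=sort_key), start=2):
        labels[raw_labels == c] = new
    return labels


def cluster_hdbscan(
    coords2d: np.ndarray,
    keywords: Sequence[str],
    profile: str = "balanced",
    seed: int = 42,
    profiles: Optional[dict] = None,
) -> ClusterSolution:
    """Density clustering of the 2D embedding under a named parameter profile.

    All points are covered: unassigned points form cluster 1 (never
    discarded). If everything is noise the solution has only cluster 1 and a
    warning is raised.
    """
    profiles = profiles or HDBSCAN_PROFILES
    if profile not in profiles:
        raise ValueError(f"unknown profile {profile!r}; have {sorted(profiles)}")
    params = profiles[profile]
    raw = HDBSCAN(**params).fit_predict(np.asarray(coords2d, dtype=float))
    labels = _relabel(raw, keywords)
    if (labels == NOISE_LABEL).all():
        warnings.warn("all points classified as noise (cluster 1)", stacklevel=2)
    sol = ClusterSolution(
        keywords=list(keywords),
        coords2d=np.asarray(coords2d, dtype=float),
        labels=labels,
        profile_name=profile,
        seed=seed,
    )
    sol.centroid_distance = centroid_distances(sol.coords2d, sol.labels)
    return sol


def centroid_distances(coords2d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Euclidean distance of each point to its own cluster's mean coordinate
    (the noise cluster uses the noise-set centroid; singletons get 0)."""
    coords2d = np.asarray(coords2d, dtype=float)
    labels = np.asarray(labels)
    out = np.zeros(len(labels))
    for c in np.unique(labels):
        mask = labels == c
        centroid = coords2d[mask].mean(axis=0)
        out[mask] = np.linalg.norm(coords2d[mask] - centroid, axis=1)
    return out


def internal_metrics(
    coords2d: np.ndarray,
    labels: np.ndarray,
    runs: Optional[list[ClusterSolution]] = None,
) -> ClusterMetrics:
    """Internal quality in the 2D space (noise excluded from silhouette, CH,
    and DBI; included in the across-seed adjusted Rand index).

    With fewer than 2 thematic clusters of size >= 2 the three geometric
    metrics are reported as not-applicable (``None``), never as zero.
    """
    coords2d = np.asarray(coords2d, dtype=float)
    labels = np.asarray(labels)
    metrics = ClusterMetrics()
    mask = labels != NOISE_LABEL
    them = labels[mask]
    uniq, sizes = np.unique(them, return_counts=True)
    if len(uniq) >= 2 and (sizes >= 2).all() and mask.sum() > len(uniq):
        pts = coords2d[mask]
        metrics.silhouette = float(silhouette_score(pts, them))
        metrics.calinski_harabasz = float(calinski_harabasz_score(pts, them))
        metrics.davies_bouldin = float(davies_bouldin_score(pts, them))
    if runs and len(runs) >= 2:
        aris = []
        for i in range(len(runs)):
            for j in range(i + 1, len(runs)):
                a, b = runs[i], runs[j]
                common = [k for k in a.keywords if k in set(b.keywords)]
                la = [a.label_map()[k] for k in common]
                lb = [b.label_map()[k] for k in common]
                aris.append(adjusted_rand_score(la, lb))
        metrics.ari_across_seeds = float(np.mean(aris))
    return metrics


def bootstrap_cluster_jaccard(
    base: ClusterSolution,
    resampled: list[ClusterSolution],
) -> dict[int, float]:
    """Per-cluster stability: for each base cluster, the best-match Jaccard
    against each resampled solution's clusters (greedy best match), averaged
    over resamples. The comparison is restricted to keywords present in both
    solutions."""
    out: dict[int, float] = {}
    for c in sorted(set(int(l) for l in base.labels)):
        base_set = base.members(c)
        scores = []
        for sol in resampled:
            universe = set(sol.keywords)
            bs = base_set & universe
            if not bs:
                continue
            best = 0.0
            for c2 in set(int(l) for l in sol.labels):
                other = sol.members(c2)
                inter = len(bs & other)
                union = len(bs | other)
                if union:
                    best = max(best, inter / union)
            scores.append(best)
        out[c] = float(np.mean(scores)) if scores else float("nan")
    return out
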