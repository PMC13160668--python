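"""Keyword-level semantic vectors and the hybrid semantic-structural similarity.

The semantic side aggregates document embeddings (title + abstract) at the
keyword level; the structural side is the cosine similarity of co-occurrence
weight profiles. The two are fused as a convex combination
``S_hyb = alpha * S_sem + (1 - alpha) * S_str``.

The shipped backend is a deterministic seeded random projection of token
counts: each token is mapped to a fixed Gaussian direction derived from a
stable hash of the token, and a document embeds as the normalized weighted
sum of its token directions. Token overlap therefore drives cosine
similarity, which is the only property the downstream contract requires, and
the whole pipeline runs offline. Transformer-based document encoders can be
plugged in through the same ``embed`` interface.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass
from typing import Optional, Protocol

import numpy as np

from .network import CoocNetwork
from .records import BibRecord

__all__ = [
    "EmbeddingBackend",
    "HashedProjectionBackend",
    "embed_documents",
    "keyword_vectors",
    "structural_similarity",
    "hybrid_similarity",
    "HybridSimilarity",
    "build_hybrid",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class EmbeddingBackend(Protocol):
    name: str
    dimension: int

    def embed(self, texts: list[str]) -> np.ndarray: ...


def _token_seed(token: str, salt: int) -> int:
    digest = hashlib.md5(f"{salt}:{token}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


class HashedProjectionBackend:
    """Deterministic offline document encoder.

    Every token gets a fixed unit-variance Gaussian direction in
    ``dimension``-dimensional space, seeded from a stable hash of the token
    (so the direction does not depend on the corpus); a document is the
    L2-normalized count-weighted sum of its token directions.
    """

    def __init__(self, dimension: int = 256, seed: int = 0, name: str = "hashed-projection"):
        self.dimension = int(dimension)
        self.seed = int(seed)
        self.name = f"{name}-d{dimension}"
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        v = self._cache.get(token)
        if v is None:
            rng = np.random.default_rng(_token_seed(token, self.seed))
            v = rng.standard_normal(self.dimension)
            self._cache[token] = v
        return v

    def embed(self, texts: list[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dimension))
        for i, text in enumerate(texts):
            tokens = _TOKEN_RE.findall(text.lower())
            if not tokens:
                continue
            acc = np.zeros(self.dimension)
            for tok in tokens:
                acc += self._token_vector(tok)
            norm = np.linalg.norm(acc)
            if norm > 0:
                out[i] = acc / norm
        return out


def embed_documents(
    corpus: list[BibRecord],
    backends: list[EmbeddingBackend],
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Embed each record's concatenated title + abstract with every backend,
    L2-normalizing each backend's sub-vector before concatenation so neither
    backend dominates, then renormalizing the concatenation.

    Records yielding a zero vector (no usable text) are excluded and listed in
    the returned flag list; dual-space retention downstream drops their
    keywords if no other record supports them.
    """
    if not backends:
        raise ValueError("at least one embedding backend is required")
    texts = [(r.title + " " + r.abstract).strip() for r in corpus]
    parts = []
    for be in backends:
        m = np.asarray(be.embed(texts), dtype=float)
        if m.shape != (len(corpus), be.dimension):
            raise ValueError(f"backend {be.name} returned shape {m.shape}")
        norms = np.linalg.norm(m, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(norms > 0, m / norms, 0.0)
        parts.append(m)
    full = np.hstack(parts)
    vectors: dict[str, np.ndarray] = {}
    failed: list[str] = []
    for rec, vec in zip(corpus, full):
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            failed.append(rec.record_id)
            continue
        vectors[rec.record_id] = vec / norm
    return vectors, failed


def keyword_vectors(
    doc_vectors: dict[str, np.ndarray],
    corpus: list[BibRecord],
    retained: set[str],
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Keyword vector = renormalized arithmetic mean of the vectors of the
    records containing the keyword. Keywords with no embedded record, or with
    a degenerate (cancelling) aggregate, are excluded and logged."""
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for rec in corpus:
        v = doc_vectors.get(rec.record_id)
        if v is None:
            continue
        for kw in set(rec.author_keywords) & retained:
            if kw in sums:
                sums[kw] = sums[kw] + v
                counts[kw] += 1
            else:
                sums[kw] = v.copy()
                counts[kw] = 1
    vectors: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for kw in sorted(retained):
        if kw not in sums:
            excluded.append(kw)
            continue
        mean = sums[kw] / counts[kw]
        norm = np.linalg.norm(mean)
        if norm < 1e-10:
            warnings.warn(f"degenerate aggregate vector for keyword {kw!r}",
                          stacklevel=2)
            excluded.append(kw)
            continue
        vectors[kw] = mean / norm
    return vectors, excluded


def structural_similarity(
    net: CoocNetwork, keywords: Optional[list[str]] = None
) -> tuple[np.ndarray, list[str]]:
    """Cosine similarity of co-occurrence weight profiles.

    For a pair (a, b) the profiles are the rows of the weighted adjacency
    with the entries at positions a and b zeroed in both rows, so the
    similarity reflects shared *third-party* neighborhoods only. Diagonal is
    1; rows of isolated nodes are zero off-diagonal.
    """
    keywords = keywords if keywords is not None else net.nodes
    if not keywords:
        raise ValueError("empty network")
    idx = {k: i for i, k in enumerate(keywords)}
    n = len(keywords)
    w = np.zeros((n, n))
    for a, b, weight in net.edges():
        if a in idx and b in idx:
            w[idx[a], idx[b]] = weight
            w[idx[b], idx[a]] = weight
    # W has zero diagonal, so zeroing positions a and b in both rows changes
    # only the norms: ||row_a||^2 loses W[a,b]^2, and the dot is unchanged.
    dots = w @ w.T
    sq = (w**2).sum(axis=1)
    na2 = sq[:, None] - w**2
    nb2 = sq[None, :] - w**2
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = dots / np.sqrt(na2 * nb2)
    sim[~np.isfinite(sim)] = 0.0
    np.fill_diagonal(sim, 1.0)
    return sim, keywords


@dataclass
class HybridSimilarity:
    """Fusion of semantic and structural keyword similarity.

    ``s_hyb = alpha * s_sem + (1 - alpha) * s_str`` elementwise; every matrix
    is symmetric with unit diagonal and ``s_hyb`` lies in the elementwise
    convex hull of the inputs.
    """

    keywords: list[str]
    s_sem: np.ndarray
    s_str: np.ndarray
    alpha: float

    @property
    def s_hyb(self) -> np.ndarray:
        return self.alpha * self.s_sem + (1 - self.alpha) * self.s_str

    def distance(self) -> np.ndarray:
        """Precomputed distance for dimensionality reduction: 1 - s_hyb,
        clipped to [0, 2], zero diagonal."""
        d = np.clip(1.0 - self.s_hyb, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
        return d


def hybrid_similarity(
    s_sem: np.ndarray,
    s_str: np.ndarray,
    alpha: float,
    keywords: list[str],
) -> HybridSimilarity:
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    s_sem = np.asarray(s_sem, dtype=float)
    s_str = np.asarray(s_str, dtype=float)
    if s_sem.shape != s_str.shape or s_sem.shape[0] != len(keywords):
        raise ValueError("matrix shapes and keyword list are inconsistent")
    return HybridSimilarity(keywords=list(keywords), s_sem=s_sem, s_str=s_str,
                            alpha=alpha)


def build_hybrid(
    corpus: list[BibRecord],
    net: CoocNetwork,
    backends: Optional[list[EmbeddingBackend]] = None,
    alpha: float = 0.5,
) -> tuple[HybridSimilarity, dict]:
    """End-to-end hybrid similarity over the dual-space retained keywords.

    Keywords must have a structural presence (a network node) *and* a valid
    semantic vector to survive fusion; those lacking either are dropped and
    logged.
    """
    backends = backends or [HashedProjectionBackend()]
    doc_vectors, failed_records = embed_documents(corpus, backends)
    kw_vecs, excluded = keyword_vectors(doc_vectors, corpus, set(net.nodes))
    keywords = [k for k in net.nodes if k in kw_vecs]
    if not keywords:
        raise ValueError("no keyword survives dual-space retention")
    mat = np.stack([kw_vecs[k] for k in keywords])
    s_sem = mat @ mat.T
    np.fill_diagonal(s_sem, 1.0)
    s_str, _ = structural_similarity(net, keywords)
    hyb = hybrid_similarity(s_sem, s_str, alpha, keywords)
    log = {
        "n_records_embedded": len(doc_vectors),
        "failed_records": failed_records,
        "keywords_dropped_semantic": excluded,
        "n_keywords": len(keywords),
        "alpha": alpha,
        "backends": [b.name for b in backends],
    }
    return hyb, log
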