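import numpy as np
import pytest

from themescape.network import CoocNetwork, build_cooc
from themescape.semantics import (
    HashedProjectionBackend,
    build_hybrid,
    embed_documents,
    hybrid_similarity,
    keyword_vectors,
    structural_similarity,
)

from conftest import make_record


class TestBackend:
    def test_deterministic_and_unit_norm(self):
        be = HashedProjectionBackend(dimension=64, seed=0)
        texts = ["alpha beta gamma", "delta epsilon"]
        v1, v2 = be.embed(texts), HashedProjectionBackend(64, 0).embed(texts)
        assert np.allclose(v1, v2)
        assert np.allclose(np.linalg.norm(v1, axis=1), 1.0, atol=1e-6)

    def test_identical_texts_cosine_one(self):
        be = HashedProjectionBackend(dimension=128)
        v = be.embed(["same text here", "same text here"])
        assert float(v[0] @ v[1]) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_token_sets_near_orthogonal(self):
        # 100 seeded pairs of disjoint-token documents at dimension 256
        be = HashedProjectionBackend(dimension=256, seed=0)
        rng = np.random.default_rng(1)
        for trial in range(100):
            a = " ".join(f"w{trial}a{i}" for i in rng.integers(0, 50, size=10))
            b = " ".join(f"w{trial}b{i}" for i in rng.integers(0, 50, size=10))
            va, vb = be.embed([a, b])
            assert abs(float(va @ vb)) < 0.2

    def test_shape_contract(self):
        be = HashedProjectionBackend(dimension=32)
        corpus = [make_record(f"r{i}", ["k"], abstract=f"text {i}") for i in range(5)]
        vectors, failed = embed_documents(corpus, [be])
        assert len(vectors) == 5 and not failed
        assert all(v.shape == (32,) for v in vectors.values())
        assert all(np.isclose(np.linalg.norm(v), 1.0) for v in vectors.values())

    def test_textless_record_flagged(self):
        corpus = [make_record("a", ["k"], title="", abstract="")]
        vectors, failed = embed_documents(corpus, [HashedProjectionBackend(16)])
        assert failed == ["a"] and not vectors

    def test_backend_concatenation_renormalized(self):
        corpus = [make_record("a", ["k"], abstract="alpha beta")]
        vectors, _ = embed_documents(
            corpus, [HashedProjectionBackend(16, seed=0), HashedProjectionBackend(8, seed=1)]
        )
        assert vectors["a"].shape == (24,)
        assert np.isclose(np.linalg.norm(vectors["a"]), 1.0)


class TestKeywordVectors:
    def test_singleton_keyword_gets_record_vector(self):
        corpus = [make_record("a", ["k"], abstract="unique words")]
        doc_vecs, _ = embed_documents(corpus, [HashedProjectionBackend(32)])
        kv, excluded = keyword_vectors(doc_vecs, corpus, {"k"})
        assert not excluded
        assert np.allclose(kv["k"], doc_vecs["a"])

    def test_cancellation_excluded_with_warning(self):
        v = np.zeros(4)
        v[0] = 1.0
        doc_vecs = {"a": v, "b": -v}
        corpus = [make_record("a", ["k"]), make_record("b", ["k"])]
        with pytest.warns(UserWarning, match="degenerate"):
            kv, excluded = keyword_vectors(doc_vecs, corpus, {"k"})
        assert excluded == ["k"] and not kv

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vecs = {f"r{i}": rng.standard_normal(8) for i in range(3)}
        vecs = {k: v / np.linalg.norm(v) for k, v in vecs.items()}
        corpus = [make_record(rid, ["k"]) for rid in vecs]
        kv, _ = keyword_vectors(vecs, corpus, {"k"})
        mean = np.mean([vecs[f"r{i}"] for i in range(3)], axis=0)
        assert np.allclose(kv["k"], mean / np.linalg.norm(mean), atol=1e-12)

    def test_keyword_without_embedded_record_excluded(self):
        kv, excluded = keyword_vectors({}, [make_record("a", ["k"])], {"k"})
        assert excluded == ["k"]


class TestStructural:
    @staticmethod
    def net_from_edges(edges):
        import networkx as nx

        g = nx.Graph()
        for a, b, w in edges:
            g.add_edge(a, b, weight=w)
        return CoocNetwork(g)

    def test_identical_profiles_similarity_one(self):
        # a and b connect to c and d with equal weights, not to each other
        net = self.net_from_edges(
            [("a", "c", 2.0), ("a", "d", 1.0), ("b", "c", 2.0), ("b", "d", 1.0)]
        )
        s, kws = structural_similarity(net)
        i, j = kws.index("a"), kws.index("b")
        assert s[i, j] == pytest.approx(1.0)

    def test_disjoint_neighborhoods_zero(self):
        net = self.net_from_edges([("a", "c", 1.0), ("b", "d", 1.0)])
        s, kws = structural_similarity(net)
        assert s[kws.index("a"), kws.index("b")] == 0.0

    def test_matches_brute_force_with_pair_zeroing(self):
        edges = [("a", "b", 1.5), ("a", "c", 2.0), ("b", "c", 0.5), ("c", "d", 1.0)]
        net = self.net_from_edges(edges)
        s, kws = structural_similarity(net)
        idx = {k: i for i, k in enumerate(kws)}
        w = np.zeros((4, 4))
        for a, b, wt in edges:
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = wt
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                va, vb = w[i].copy(), w[j].copy()
                va[[i, j]] = 0.0
                vb[[i, j]] = 0.0
                denom = np.linalg.norm(va) * np.linalg.norm(vb)
                expected = (va @ vb) / denom if denom > 0 else 0.0
                assert s[i, j] == pytest.approx(expected, abs=1e-12)

    def test_diagonal_one_isolated_rows_zero(self):
        net = self.net_from_edges([("a", "b", 1.0)])
        net.graph.add_node("iso")
        s, kws = structural_similarity(net)
        assert np.allclose(np.diag(s), 1.0)
        i = kws.index("iso")
        off = np.delete(s[i], i)
        assert np.allclose(off, 0.0)


class TestHybrid:
    rng = np.random.default_rng(7)

    @classmethod
    def random_sym(cls, n, low=0.0):
        m = cls.rng.uniform(low, 1.0, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        return m

    def test_alpha_boundaries_are_identities(self):
        s_sem, s_str = self.random_sym(4, -0.5), self.random_sym(4)
        kws = list("abcd")
        assert np.allclose(hybrid_similarity(s_sem, s_str, 1.0, kws).s_hyb, s_sem)
        assert np.allclose(hybrid_similarity(s_sem, s_str, 0.0, kws).s_hyb, s_str)

    def test_half_alpha_elementwise_mean(self):
        s_sem = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.0], [0.4, 0.0, 1.0]])
        s_str = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.8], [0.0, 0.8, 1.0]])
        h = hybrid_similarity(s_sem, s_str, 0.5, list("abc")).s_hyb
        assert np.allclose(h, (s_sem + s_str) / 2)

    def test_alpha_out_of_range_rejected(self):
        m = self.random_sym(3)
        with pytest.raises(ValueError, match="alpha"):
            hybrid_similarity(m, m, 1.5, list("abc"))

    def test_convexity_symmetry_unit_diagonal(self):
        s_sem, s_str = self.random_sym(6, -1.0), self.random_sym(6)
        h = hybrid_similarity(s_sem, s_str, 0.3, list("abcdef")).s_hyb
        assert np.allclose(h, h.T)
        assert np.allclose(np.diag(h), 1.0)
        assert (h >= np.minimum(s_sem, s_str) - 1e-12).all()
        assert (h <= np.maximum(s_sem, s_str) + 1e-12).all()

    def test_monotone_linear_in_alpha(self):
        s_sem, s_str = self.random_sym(5, -1.0), self.random_sym(5)
        kws = list("abcde")
        h25 = hybrid_similarity(s_sem, s_str, 0.25, kws).s_hyb
        h50 = hybrid_similarity(s_sem, s_str, 0.5, kws).s_hyb
        h75 = hybrid_similarity(s_sem, s_str, 0.75, kws).s_hyb
        assert np.allclose(h50 - h25, h75 - h50, atol=1e-12)

    def test_distance_clipped_zero_diagonal(self):
        s = self.random_sym(4, -1.0)
        h = hybrid_similarity(s, self.random_sym(4), 0.5, list("abcd"))
        d = h.distance()
        assert (d >= 0).all() and (d <= 2).all()
        assert np.allclose(np.diag(d), 0.0)


def test_planted_topic_separation(synth_study, synth_network):
    # same-topic keyword pairs are more similar than cross-topic pairs
    _, corpus, truth = synth_study
    _, _, net = synth_network
    hyb, log = build_hybrid(corpus, net)
    assert len(hyb.keywords) >= 50
    topic = np.array([truth["keyword_topic"].get(k, -1) for k in hyb.keywords])
    s = hyb.s_hyb
    same = s[np.equal.outer(topic, topic) & ~np.eye(len(topic), dtype=bool)]
    diff = s[~np.equal.outer(topic, topic)]
    assert same.mean() > diff.mean()
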