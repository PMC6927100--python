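import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetewalk import (
    EmbeddingTable,
    HeteroGraph,
    MetaPath,
    Schema,
    TrainConfig,
    auroc,
    cosine_score,
    cross_validate,
    make_split,
    rank_candidates,
    score_pairs,
)
from hetewalk.synthetic import default_spec, generate


def brute_force_auroc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCosine:
    def _emb(self, vectors):
        return EmbeddingTable(sorted(vectors), np.array([vectors[k] for k in sorted(vectors)], float))

    def test_identical_orthogonal_opposite(self):
        emb = self._emb({"a": [1, 0], "b": [1, 0], "c": [0, 1], "d": [-1, 0]})
        assert cosine_score(emb, "a", "b") == pytest.approx(1.0)
        assert cosine_score(emb, "a", "c") == pytest.approx(0.0)
        assert cosine_score(emb, "a", "d") == pytest.approx(-1.0)

    def test_symmetric_and_scale_invariant(self):
        emb = self._emb({"a": [2, 1], "b": [0.4, 0.2]})
        assert cosine_score(emb, "a", "b") == pytest.approx(1.0)
        assert cosine_score(emb, "a", "b") == cosine_score(emb, "b", "a")

    def test_zero_vector_is_scoring_error(self):
        emb = self._emb({"a": [0, 0], "b": [1, 0]})
        with pytest.raises(ValueError):
            cosine_score(emb, "a", "b")


class TestRankCandidates:
    @pytest.fixture
    def setup(self):
        schema = Schema({"gene", "disease"}, [("gene", "disease", "assoc")])
        g = HeteroGraph(schema)
        g.add_node("d1", "disease")
        for i in (1, 2, 3):
            g.add_node(f"g{i}", "gene")
        g.add_edge("d1", "g2", "assoc", 1.0)  # known association
        vecs = {"d1": [1, 0], "g1": [0.9, 0.1], "g2": [0.8, 0.6], "g3": [0, 1]}
        emb = EmbeddingTable(
            sorted(vecs), np.array([vecs[k] for k in sorted(vecs)], float)
        )
        return g, emb

    def test_descending_order(self, setup):
        g, emb = setup
        ranked = rank_candidates(emb, "d1", "gene", g, exclude_known=False)
        assert [n for n, _ in ranked.candidates] == ["g1", "g2", "g3"]
        scores = [s for _, s in ranked.candidates]
        assert scores == sorted(scores, reverse=True)

    def test_exclude_known_keeps_original_ranks(self, setup):
        g, emb = setup
        ranked = rank_candidates(emb, "d1", "gene", g, exclude_known=True)
        assert [n for n, _ in ranked.candidates] == ["g1", "g3"]
        assert ranked.original_ranks == {"g1": 1, "g3": 3}  # rank 2 was known

    def test_tie_breaks_on_node_id(self):
        schema = Schema({"gene", "disease"}, [("gene", "disease", "assoc")])
        g = HeteroGraph(schema)
        g.add_node("d1", "disease")
        g.add_node("gb", "gene")
        g.add_node("ga", "gene")
        vecs = {"d1": [1.0, 0.0], "ga": [1.0, 0.0], "gb": [2.0, 0.0]}
        emb = EmbeddingTable(sorted(vecs), np.array([vecs[k] for k in sorted(vecs)], float))
        ranked = rank_candidates(emb, "d1", "gene", g, exclude_known=False)
        assert [n for n, _ in ranked.candidates] == ["ga", "gb"]

    def test_missing_query_raises(self, setup):
        g, emb = setup
        with pytest.raises(KeyError):
            rank_candidates(emb, "d9", "gene", g)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_ties_is_half(self):
        assert auroc([0.5], [0.5]) == 0.5

    def test_mixed_example(self):
        assert auroc([0.8, 0.2], [0.5]) == 0.5  # (1 + 0) / 2

    def test_empty_is_usage_error(self):
        with pytest.raises(ValueError):
            auroc([], [0.5])

    @settings(max_examples=100, deadline=None)
    @given(
        pos=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
        neg=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
    )
    def test_equals_pairwise_ordering_fraction(self, pos, neg):
        # discrete scores force plenty of ties through the half-count path
        assert auroc(pos, neg) == pytest.approx(brute_force_auroc(pos, neg))


class TestScorePairs:
    def test_missing_nodes_score_zero_and_are_counted(self):
        emb = EmbeddingTable(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        scores, missing = score_pairs(emb, [("a", "b"), ("a", "zz")])
        assert scores[0] == pytest.approx(0.0)
        assert scores[1] == 0.0 and missing == 1


@pytest.fixture(scope="module")
def planted_net():
    return generate(default_spec(n_per_type=15, seed=21))


class TestSplitAndCV:
    def test_split_partitions_without_leakage(self, planted_net):
        g = planted_net.graph
        rng = np.random.default_rng(0)
        split = make_split(g, ("gene", "disease", "assoc"), 0.7, rng)
        train_s, test_s = set(split.train_edges), set(split.test_edges)
        assert not train_s & test_s
        assert len(split.negatives) == len(split.test_edges)
        known = train_s | test_s
        for a, b in split.negatives:
            assert (a, b) not in known and (b, a) not in known
            assert not g.has_edge(a, b)

    def test_split_ratio_respected(self, planted_net):
        rng = np.random.default_rng(1)
        split = make_split(planted_net.graph, ("gene", "disease", "assoc"), 0.8, rng)
        total = len(split.train_edges) + len(split.test_edges)
        assert len(split.train_edges) == round(0.8 * total)

    def test_cross_validate_reproducible_and_sane(self, planted_net):
        p = MetaPath(("gene", "gene", "disease"), ("sim", "assoc"))
        cfg = TrainConfig(dim=8, epochs=2, walks_per_node=5)
        r1 = cross_validate(
            planted_net.graph, ("gene", "disease", "assoc"), p, cfg,
            train_ratio=0.7, repeats=2, seed=5,
        )
        r2 = cross_validate(
            planted_net.graph, ("gene", "disease", "assoc"), p, cfg,
            train_ratio=0.7, repeats=2, seed=5,
        )
        assert r1.per_repeat == r2.per_repeat
        assert all(0.0 <= a <= 1.0 for a in r1.per_repeat)
        assert r1.mean_auroc == pytest.approx(np.mean(r1.per_repeat))

    def test_absent_relation_is_usage_error(self, planted_net):
        with pytest.raises(ValueError):
            cross_validate(
                planted_net.graph,
                ("gene", "disease", "nope"),
                MetaPath(("gene", "disease")),
                TrainConfig(dim=4, epochs=1),
                repeats=1,
            )
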