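import math

import numpy as np
import pytest

from hetewalk import (
    EmbeddingTable,
    MetaPath,
    TrainConfig,
    TrainingPair,
    Walk,
    WalkCorpus,
    extract_pairs,
    generate_corpus,
    pair_gradients,
    pair_log_likelihood,
    sample_negatives,
    train,
)
from hetewalk.synthetic import default_spec, degenerate_fixtures, generate


def _walk(*ids, complete=True):
    return Walk(tuple(ids), complete)


class TestExtractPairs:
    def test_three_node_walk_yields_three_unordered_pairs(self):
        pairs = extract_pairs(_walk("Disease1", "Disease2", "Gene1"))
        unordered = {frozenset(p) for p in pairs}
        assert unordered == {
            frozenset({"Disease1", "Disease2"}),
            frozenset({"Disease1", "Gene1"}),
            frozenset({"Disease2", "Gene1"}),
        }
        assert len(pairs) == 6  # both orientations of each

    def test_dead_end_single_node_walk_is_empty(self):
        assert extract_pairs(_walk("d1", complete=False)) == []

    @pytest.mark.parametrize("n, expected", [(2, 1), (3, 3), (4, 6)])
    def test_distinct_walk_gives_all_position_pairs(self, n, expected):
        ids = [f"n{i}" for i in range(n)]
        pairs = extract_pairs(_walk(*ids))
        assert len({frozenset(p) for p in pairs}) == expected

    def test_repeated_node_id_pairs_only_distinct_ids(self):
        pairs = extract_pairs(_walk("a", "b", "a"))
        assert all(x != y for x, y in pairs)
        assert {frozenset(p) for p in pairs} == {frozenset({"a", "b"})}
        assert len(pairs) == 4  # positions (0,1) and (1,2), both orientations


class TestSampleNegatives:
    def test_contract_type_and_exclusion(self, rng):
        net = generate(default_spec(n_per_type=10, seed=0))
        g = net.graph
        negs = sample_negatives(g, "gene003", 5, rng)
        assert len(negs) == 5
        assert all(g.node_type(n) == "gene" and n != "gene003" for n in negs)

    def test_uniform_law_over_eligible_nodes(self, fixtures, rng):
        g = fixtures["two_component"]  # 4 genes
        draws = sample_negatives(g, "g_a1", 100_000, rng)
        freqs = {n: draws.count(n) / 100_000 for n in set(draws)}
        assert set(freqs) == {"g_a2", "g_b1", "g_b2"}
        for f in freqs.values():
            assert abs(f - 1 / 3) < 0.01

    def test_single_node_of_type_is_an_error(self, fixtures, rng):
        with pytest.raises(ValueError):
            sample_negatives(fixtures["k11"], "g1", 5, rng)


class TestPairLogLikelihood:
    def test_all_zero_vectors(self):
        emb = EmbeddingTable(["a", "b", "c", "d"], np.zeros((4, 8)))
        pair = TrainingPair("a", "b", ("c", "d", "c", "d", "c"))
        assert pair_log_likelihood(emb, pair) == pytest.approx(6 * math.log(0.5))

    def test_saturated_positive_dot(self):
        m = np.zeros((3, 2))
        m[0] = [10.0, 0.0]
        m[1] = [5.0, 0.0]  # dot = 50
        emb = EmbeddingTable(["i", "j", "n"], m)
        ll = pair_log_likelihood(emb, TrainingPair("i", "j", ("n",) * 5))
        expected = math.log(1 / (1 + math.exp(-50))) + 5 * math.log(0.5)
        assert ll == pytest.approx(expected)

    def test_numerically_stable_at_extreme_dots(self):
        m = np.zeros((2, 1))
        m[0], m[1] = 700.0, 1.0
        emb = EmbeddingTable(["i", "j"], m)
        # |dot| = 700 both in the positive and the negated term
        pair = TrainingPair("i", "j", ("i",))
        assert np.isfinite(pair_log_likelihood(emb, pair))

    def test_matches_scalar_recomputation(self, rng):
        m = rng.normal(size=(4, 3))
        emb = EmbeddingTable(["i", "j", "n1", "n2"], m)
        pair = TrainingPair("i", "j", ("n1", "n2"))
        sig = lambda x: 1 / (1 + math.exp(-x))
        expected = (
            math.log(sig(float(m[0] @ m[1])))
            + math.log(sig(-float(m[0] @ m[2])))
            + math.log(sig(-float(m[0] @ m[3])))
        )
        assert pair_log_likelihood(emb, pair) == pytest.approx(expected, rel=1e-12)

    def test_invalid_pairs_rejected(self):
        with pytest.raises(ValueError):
            TrainingPair("a", "a", ("b",))
        with pytest.raises(ValueError):
            TrainingPair("a", "b", ("b",))


class TestGradients:
    def test_matches_finite_differences(self, rng):
        # central differences on the scalar objective, 20 random 5-d configs
        h = 1e-6
        for _ in range(20):
            xc = rng.normal(size=5)
            xo = rng.normal(size=5)
            Xn = rng.normal(size=(3, 5))

            def obj(xc, xo, Xn):
                ls = lambda x: -np.logaddexp(0.0, -x)
                return ls(xc @ xo) + sum(ls(-(xc @ xn)) for xn in Xn)

            gc, go, gn = pair_gradients(xc, xo, Xn)
            for vec, grad in [(xc, gc), (xo, go)]:
                num = np.zeros_like(vec)
                for k in range(vec.size):
                    e = np.zeros_like(vec)
                    e[k] = h
                    if vec is xc:
                        num[k] = (obj(xc + e, xo, Xn) - obj(xc - e, xo, Xn)) / (2 * h)
                    else:
                        num[k] = (obj(xc, xo + e, Xn) - obj(xc, xo - e, Xn)) / (2 * h)
                np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-8)
            for r in range(Xn.shape[0]):
                num = np.zeros(5)
                for k in range(5):
                    E = np.zeros_like(Xn)
                    E[r, k] = h
                    num[k] = (obj(xc, xo, Xn + E) - obj(xc, xo, Xn - E)) / (2 * h)
                np.testing.assert_allclose(gn[r], num, rtol=1e-5, atol=1e-8)


@pytest.fixture(scope="module")
def small_net():
    return generate(default_spec(n_per_type=15, seed=4))


@pytest.fixture(scope="module")
def small_corpus(small_net):
    p = MetaPath(("gene", "gene", "disease"), ("sim", "assoc"))
    return generate_corpus(small_net.graph, p, walks_per_node=5, seed=4)


class TestTrain:
    def test_bitwise_deterministic_given_seed(self, small_net, small_corpus):
        cfg = TrainConfig(dim=8, epochs=2, seed=11)
        e1 = train(small_corpus, small_net.graph, cfg)
        e2 = train(small_corpus, small_net.graph, cfg)
        assert e1.ids == e2.ids
        assert np.array_equal(e1.matrix, e2.matrix)

    def test_objective_non_decreasing_on_monitored_negatives(
        self, small_net, small_corpus
    ):
        cfg = TrainConfig(dim=8, epochs=4, seed=3, initial_learning_rate=0.01)
        emb = train(small_corpus, small_net.graph, cfg)
        hist = emb.metadata["objective_history"]
        assert len(hist) == cfg.epochs + 1
        assert hist[-1] > hist[0]
        assert all(b >= a - 1e-6 for a, b in zip(hist, hist[1:]))

    def test_every_walked_node_has_a_finite_vector(self, small_net, small_corpus):
        emb = train(small_corpus, small_net.graph, TrainConfig(dim=8, epochs=1, seed=0))
        walked = {n for w in small_corpus.walks for n in w.node_ids}
        assert walked == set(emb.ids)
        assert np.all(np.isfinite(emb.matrix))

    def test_planted_blocks_recovered_in_cosine_geometry(self):
        net = generate(default_spec(n_per_type=24, n_blocks=2, seed=8))
        p = MetaPath(("gene", "gene", "disease"), ("sim", "assoc"))
        corpus = generate_corpus(net.graph, p, walks_per_node=10, seed=8)
        emb = train(corpus, net.graph, TrainConfig(dim=16, epochs=5, seed=8))
        X = emb.matrix / np.linalg.norm(emb.matrix, axis=1, keepdims=True)
        blocks = np.array([net.blocks[n] for n in emb.ids])
        cos = X @ X.T
        same = cos[np.equal.outer(blocks, blocks) & ~np.eye(len(X), dtype=bool)]
        diff = cos[~np.equal.outer(blocks, blocks)]
        assert same.mean() > diff.mean()

    def test_disconnected_components_stay_apart(self, fixtures):
        g = fixtures["two_component"]
        p = MetaPath(("gene", "gene", "disease"), ("sim", "assoc"))
        corpus = generate_corpus(g, p, walks_per_node=30, seed=2)
        emb = train(corpus, g, TrainConfig(dim=8, epochs=5, seed=2))
        within = [
            float(emb.vector("g_a1") @ emb.vector("d_a1")),
            float(emb.vector("g_b1") @ emb.vector("d_b1")),
        ]
        across = [
            float(emb.vector("g_a1") @ emb.vector("d_b1")),
            float(emb.vector("g_b1") @ emb.vector("d_a1")),
        ]
        assert np.mean(within) > np.mean(across)

    def test_empty_corpus_is_usage_error(self, small_net):
        p = MetaPath(("gene", "gene", "disease"))
        empty = WalkCorpus([], p, 1, 0)
        with pytest.raises(ValueError):
            train(empty, small_net.graph, TrainConfig(dim=4))


class TestEmbeddingIO:
    def test_word2vec_text_round_trip_exact(self, tmp_path, rng):
        emb = EmbeddingTable(["a", "b", "c"], rng.normal(size=(3, 4)))
        path = tmp_path / "emb.txt"
        emb.save(path)
        loaded = EmbeddingTable.load(path)
        assert loaded.ids == emb.ids
        np.testing.assert_array_equal(loaded.matrix, emb.matrix)

    def test_header_matches_vocabulary(self, tmp_path, rng):
        emb = EmbeddingTable(["x", "y"], rng.normal(size=(2, 3)))
        path = tmp_path / "emb.txt"
        emb.save(path)
        assert path.read_text().splitlines()[0] == "2 3"

    def test_inconsistent_dim_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("2 3\na 1.0 2.0 3.0\nb 1.0 2.0\n")
        with pytest.raises(ValueError):
            EmbeddingTable.load(path)

    def test_wrong_row_count_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("3 2\na 1.0 2.0\nb 1.0 2.0\n")
        with pytest.raises(ValueError):
            EmbeddingTable.load(path)
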