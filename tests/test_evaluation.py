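import numpy as np
import pytest

from foodgraph import EmbeddingModel, cosine_similarity, pairing_query
from foodgraph.evaluation import (
    calibrate_threshold,
    cluster_and_score,
    confusion_metrics,
    jaccard_category_matrix,
    predict_relations,
)

from . import oracles


def model_from(vectors):
    tokens = sorted(vectors)
    mat = np.stack([vectors[t] for t in tokens])
    dim = mat.shape[1]
    return EmbeddingModel(
        {t: i for i, t in enumerate(tokens)},
        mat,
        np.zeros_like(mat),
        np.zeros((dim, 881)),
        np.zeros(881),
    )


def orthonormal_model(n=4, dim=4):
    eye = np.eye(dim)
    return model_from({f"e{k}": eye[k] for k in range(n)})


class TestCosine:
    def test_identical(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == 0.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            a, b = rng.standard_normal(5), rng.standard_normal(5)
            expected = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
            assert cosine_similarity(a, b) == pytest.approx(expected)


class TestPairingQuery:
    def test_single_token_ranks_itself_first(self):
        model = orthonormal_model()
        top = pairing_query(model, ["e1"], k=1)
        assert top == [("e1", pytest.approx(1.0))]

    def test_sum_query_ties_broken_by_id(self):
        model = orthonormal_model()
        top = pairing_query(model, ["e1", "e2"], k=2)
        assert [t for t, _ in top] == ["e1", "e2"]
        for _, score in top:
            assert score == pytest.approx(1 / np.sqrt(2))

    def test_unknown_token_named_in_error(self):
        model = orthonormal_model()
        with pytest.raises(KeyError, match="nope"):
            pairing_query(model, ["nope"], k=1)

    def test_candidate_restriction(self):
        model = orthonormal_model()
        top = pairing_query(model, ["e1"], k=2, candidates=["e2", "e3"])
        assert [t for t, _ in top] == ["e2", "e3"]

    def test_matches_full_scan_oracle(self):
        rng = np.random.default_rng(23)
        vectors = {f"t{k:02d}": rng.standard_normal(6) for k in range(30)}
        model = model_from(vectors)
        for trial in range(20):
            q = [f"t{rng.integers(30):02d}" for _ in range(int(rng.integers(1, 4)))]
            k = int(rng.integers(1, 31))
            got = pairing_query(model, q, k)
            query_vec = np.sum([vectors[t] for t in q], axis=0)
            expected = oracles.brute_topk(vectors, list(query_vec), k, sorted(vectors))
            assert [t for t, _ in got] == [t for t, _ in expected]
            for (_, s1), (_, s2) in zip(got, expected):
                assert s1 == pytest.approx(s2)


class TestClustering:
    def test_separated_blobs_give_nmi_one(self):
        rng = np.random.default_rng(3)
        vectors = {}
        labels = {}
        for b, center in enumerate([(0, 0), (50, 0), (0, 50)]):
            for k in range(10):
                tok = f"b{b}_{k}"
                vectors[tok] = np.asarray(center) + rng.normal(scale=0.1, size=2)
                labels[tok] = f"cat{b}"
        model = model_from(vectors)
        result = cluster_and_score(model, labels, k=3, seed=0)
        assert result.nmi == pytest.approx(1.0)

    def test_random_labels_give_near_zero_nmi(self):
        rng = np.random.default_rng(4)
        vectors = {f"t{k:03d}": rng.standard_normal(5) for k in range(300)}
        labels = {t: f"cat{rng.integers(3)}" for t in vectors}
        model = model_from(vectors)
        result = cluster_and_score(model, labels, k=3, seed=0)
        assert result.nmi < 0.05

    def test_fewer_labeled_than_k_rejected(self):
        model = orthonormal_model()
        with pytest.raises(ValueError):
            cluster_and_score(model, {"e1": "a", "e2": "b"}, k=3)

    def test_nmi_in_unit_interval_and_k_respected(self):
        rng = np.random.default_rng(5)
        vectors = {f"t{k}": rng.standard_normal(4) for k in range(40)}
        labels = {t: f"cat{rng.integers(4)}" for t in vectors}
        result = cluster_and_score(model_from(vectors), labels, k=4, seed=1)
        assert 0.0 <= result.nmi <= 1.0
        assert len(set(result.assignments.values())) <= 4


class TestJaccardMatrix:
    def test_identical_sets_same_category(self):
        sets = {"a": {"c1", "c2"}, "b": {"c1", "c2"}}
        cats, mat = jaccard_category_matrix(sets, {"a": "X", "b": "X"})
        assert cats == ["X"]
        assert mat[0, 0] == pytest.approx(1.0)

    def test_disjoint_sets_across_categories(self):
        sets = {"a": {"c1"}, "b": {"c2"}}
        cats, mat = jaccard_category_matrix(sets, {"a": "X", "b": "Y"})
        assert mat[0, 1] == pytest.approx(0.0)

    def test_singleton_category_diagonal_is_nan(self):
        sets = {"a": {"c1"}, "b": {"c1"}}
        cats, mat = jaccard_category_matrix(sets, {"a": "X", "b": "Y"})
        assert np.isnan(mat[0, 0]) and np.isnan(mat[1, 1])
        assert mat[0, 1] == pytest.approx(1.0)

    def test_empty_compound_set_rejected(self):
        with pytest.raises(ValueError):
            jaccard_category_matrix({"a": set()}, {"a": "X"})

    def test_matches_brute_force(self):
        rng = np.random.default_rng(31)
        universe = [f"c{k}" for k in range(12)]
        sets = {
            f"h{k}": set(rng.choice(universe, size=int(rng.integers(1, 6)), replace=False))
            for k in range(15)
        }
        categories = {h: f"cat{rng.integers(3)}" for h in sets}
        cats, mat = jaccard_category_matrix(sets, categories)
        bcats, bmat = oracles.brute_jaccard_matrix(sets, categories)
        assert cats == bcats
        for gi, g in enumerate(cats):
            for hi, h in enumerate(cats):
                expected = bmat[(g, h)]
                if expected is None:
                    assert np.isnan(mat[gi, hi])
                else:
                    assert mat[gi, hi] == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(32)
        universe = [f"c{k}" for k in range(8)]
        sets = {
            f"h{k}": set(rng.choice(universe, size=3, replace=False)) for k in range(10)
        }
        categories = {h: f"cat{rng.integers(3)}" for h in sets}
        _, mat = jaccard_category_matrix(sets, categories)
        np.testing.assert_array_equal(mat, mat.T)


class TestPredictRelations:
    def test_threshold_above_one_gives_empty(self):
        rng = np.random.default_rng(6)
        vectors = {f"t{k}": rng.standard_normal(4) for k in range(6)}
        model = model_from(vectors)
        got = predict_relations(model, ["t0", "t1"], ["t2", "t3"], threshold=1.0 + 1e-9)
        assert got == set()

    def test_threshold_minus_one_gives_complete_bipartite(self):
        rng = np.random.default_rng(7)
        vectors = {f"t{k}": rng.standard_normal(4) for k in range(6)}
        model = model_from(vectors)
        got = predict_relations(model, ["t0", "t1"], ["t2", "t3"], threshold=-1.0)
        assert got == {("t0", "t2"), ("t0", "t3"), ("t1", "t2"), ("t1", "t3")}

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        vectors = {f"t{k}": rng.standard_normal(4) for k in range(10)}
        model = model_from(vectors)
        compounds, foods = ["t0", "t1", "t2"], ["t5", "t6", "t7", "t8"]
        for threshold in (-0.5, 0.0, 0.3, 0.8):
            got = predict_relations(model, compounds, foods, threshold)
            expected = oracles.brute_threshold_edges(
                {t: list(v) for t, v in vectors.items()}, compounds, foods, threshold
            )
            assert got == expected

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        vectors = {f"t{k}": rng.standard_normal(4) for k in range(10)}
        model = model_from(vectors)
        compounds, foods = ["t0", "t1"], ["t5", "t6", "t7"]
        previous = None
        for threshold in (-1.0, -0.2, 0.2, 0.9):
            current = predict_relations(model, compounds, foods, threshold)
            if previous is not None:
                assert current <= previous
            previous = current


class TestConfusionMetrics:
    def test_printed_worked_example(self):
        # 53 known relations, 44 predictions, 38 known-true
        gold = {("c", f"g{k}") for k in range(53)}
        predicted = {("c", f"g{k}") for k in range(38)} | {
            ("c", f"u{k}") for k in range(6)
        }
        universe = gold | predicted | {("c", f"n{k}") for k in range(100)}
        result = confusion_metrics(predicted, gold, universe)
        assert result.n_pred == 44 and result.n_gold == 53
        assert round(result.precision, 3) == 0.864
        assert round(result.recall, 3) == 0.717
        assert round(result.f1, 3) == 0.784

    def test_perfect_prediction_mcc_zero_by_convention(self):
        edges = {("a", "b"), ("c", "d")}
        result = confusion_metrics(edges, edges, edges)
        assert result.accuracy == result.precision == result.recall == result.f1 == 1.0
        assert result.mcc == 0.0  # tn+fp and tn+fn factors are 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(set(), set(), set())

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics({("a", "b")}, set(), {("c", "d")})

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            universe = {("c", f"x{k}") for k in range(int(rng.integers(4, 30)))}
            pool = sorted(universe)
            gold = {pool[i] for i in rng.choice(len(pool), size=int(rng.integers(1, len(pool))), replace=False)}
            predicted = {pool[i] for i in rng.choice(len(pool), size=int(rng.integers(1, len(pool))), replace=False)}
            result = confusion_metrics(predicted, gold, universe)
            expected = oracles.brute_confusion(predicted, gold, universe)
            assert result.tp == expected["tp"]
            assert result.fp_unknown == expected["fp"]
            assert result.fn == expected["fn"]
            assert result.tn == expected["tn"]
            assert result.precision == pytest.approx(expected["precision"])
            assert result.recall == pytest.approx(expected["recall"])
            assert result.f1 == pytest.approx(expected["f1"])
            assert result.mcc == pytest.approx(expected["mcc"])
            assert result.accuracy == pytest.approx(expected["accuracy"])
            assert result.n_pred == result.tp + result.fp_unknown
            assert result.n_gold == result.tp + result.fn


class TestFingerprintAuc:
    def test_untrained_head_gives_half(self):
        from foodgraph import Fingerprint
        from foodgraph.evaluation import head_fingerprint_auc

        rng = np.random.default_rng(40)
        vectors = {f"c{k}": rng.standard_normal(4) for k in range(6)}
        model = model_from(vectors)  # zero head -> every prediction 0.5
        fps = {t: Fingerprint((rng.random(881) < 0.3).astype(np.uint8)) for t in vectors}
        assert head_fingerprint_auc(model, fps) == pytest.approx(0.5)

    def test_oracle_head_gives_one(self):
        from foodgraph import EmbeddingModel, Fingerprint
        from foodgraph.evaluation import head_fingerprint_auc

        rng = np.random.default_rng(41)
        n, dim = 6, 4
        tokens = [f"c{k}" for k in range(n)]
        fps = {t: Fingerprint((rng.random(881) < 0.3).astype(np.uint8)) for t in tokens}
        # one-hot embeddings and a head that maps each to its own labels
        X = np.eye(n)
        W = np.stack([fps[t].bits * 2.0 - 1.0 for t in tokens])  # (n, 881)
        model = EmbeddingModel(
            {t: i for i, t in enumerate(tokens)}, X, np.zeros_like(X), W, np.zeros(881)
        )
        assert head_fingerprint_auc(model, fps) == pytest.approx(1.0)

    def test_geometry_estimator_detects_planted_structure(self):
        from foodgraph import Fingerprint
        from foodgraph.evaluation import fingerprint_reconstruction_auc

        rng = np.random.default_rng(42)
        # two clusters of embeddings sharing distinct bit blocks
        vectors, fps = {}, {}
        for g, center in enumerate([np.ones(6), -np.ones(6)]):
            for k in range(8):
                tok = f"g{g}_{k}"
                vectors[tok] = center + rng.normal(scale=0.2, size=6)
                bits = np.zeros(881, dtype=np.uint8)
                bits[g * 50 : (g + 1) * 50] = 1
                fps[tok] = Fingerprint(bits)
        model = model_from(vectors)
        auc = fingerprint_reconstruction_auc(model, fps, bits=range(100))
        assert auc > 0.95

    def test_geometry_estimator_near_half_on_random(self):
        from foodgraph import Fingerprint
        from foodgraph.evaluation import fingerprint_reconstruction_auc

        rng = np.random.default_rng(43)
        vectors = {f"c{k}": rng.standard_normal(6) for k in range(20)}
        fps = {t: Fingerprint((rng.random(881) < 0.5).astype(np.uint8)) for t in vectors}
        model = model_from(vectors)
        auc = fingerprint_reconstruction_auc(model, fps)
        assert 0.4 < auc < 0.6


class TestCalibration:
    def test_picks_f1_maximizing_threshold(self):
        vectors = {
            "c": np.array([1.0, 0.0]),
            "f1": np.array([1.0, 0.1]),
            "f2": np.array([0.0, 1.0]),
            "f3": np.array([0.9, 0.4]),
        }
        model = model_from(vectors)
        gold = {("c", "f1"), ("c", "f3")}
        t = calibrate_threshold(model, ["c"], ["f1", "f2", "f3"], gold)
        predicted = predict_relations(model, ["c"], ["f1", "f2", "f3"], t)
        assert predicted == gold
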