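import numpy as np
import pytest

from chemvs.classifiers import (
    Engine,
    load_engine,
    make_engine,
    save_engine,
    similarity_screen,
)
from chemvs.classifiers.knn import knn_predict, train_knn
from chemvs.classifiers.pnn import pnn_predict, pnn_predict_batch, train_pnn
from chemvs.classifiers.svm import rbf_kernel, svm_decision, train_svm


def separable_blobs(n=40, dim=5, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    xp = rng.normal(loc=+sep / 2, scale=0.5, size=(n, dim))
    xn = rng.normal(loc=-sep / 2, scale=0.5, size=(n, dim))
    x = np.vstack([xp, xn])
    y = np.array([1] * n + [-1] * n)
    return x, y


class TestSVM:
    def test_symmetric_two_point_problem(self):
        # +1 at x=+1, -1 at x=-1: by symmetry the boundary is at 0 and b=0
        x = np.array([[1.0], [-1.0]])
        y = np.array([1, -1])
        m = train_svm(x, y)
        assert m.bias == pytest.approx(0.0, abs=1e-6)
        assert svm_decision(m, np.array([0.5])).label == 1
        assert svm_decision(m, np.array([-0.5])).label == -1
        # exact midpoint scores zero -> tie resolves to non-inhibitor
        assert svm_decision(m, np.array([0.0])).label == -1

    def test_hard_margin_separable_training_accuracy(self):
        x, y = separable_blobs()
        m = train_svm(x, y)
        pred = [svm_decision(m, row).label for row in x]
        assert (np.array(pred) == y).all()

    def test_training_point_duplicate_query_gets_own_label(self):
        x, y = separable_blobs(n=20)
        m = train_svm(x, y)
        assert svm_decision(m, x[0]).label == y[0]
        assert svm_decision(m, x[-1]).label == y[-1]

    def test_dual_feasibility(self):
        x, y = separable_blobs(seed=3)
        m = train_svm(x, y)
        assert np.all(np.abs(m.dual_coef) <= m.c * (1 + 1e-8))
        assert abs(m.dual_coef.sum()) < 1e-6

    def test_far_query_score_tends_to_bias(self):
        x, y = separable_blobs()
        m = train_svm(x, y)
        far = np.full(x.shape[1], 1e3)
        assert svm_decision(m, far).score == pytest.approx(m.bias, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((4, 2)), np.ones(4, dtype=int))

    def test_dimension_mismatch(self):
        x, y = separable_blobs()
        m = train_svm(x, y)
        with pytest.raises(ValueError):
            svm_decision(m, np.zeros(x.shape[1] + 1))

    def test_decision_deterministic(self):
        x, y = separable_blobs()
        m = train_svm(x, y)
        q = np.zeros(x.shape[1]) + 0.3
        assert svm_decision(m, q).score == svm_decision(m, q).score


class TestKNN:
    def test_query_on_training_point(self):
        m = train_knn(np.array([[0.0], [1.0]]), np.array([1, -1]), k=1)
        assert knn_predict(m, np.array([0.0])).label == 1

    def test_majority_vote(self):
        m = train_knn(np.array([[0.0], [0.1], [0.2], [5.0]]), np.array([1, 1, -1, -1]), k=3)
        assert knn_predict(m, np.array([0.0])).label == 1

    def test_vote_tie_resolves_to_negative(self):
        m = train_knn(np.array([[0.0], [1.0]]), np.array([1, -1]), k=2)
        assert knn_predict(m, np.array([0.5])).label == -1

    def test_distance_tie_breaks_by_training_index(self):
        # two equidistant neighbours with opposite labels; k=1 takes index 0
        m = train_knn(np.array([[1.0], [-1.0]]), np.array([1, -1]), k=1)
        assert knn_predict(m, np.array([0.0])).label == 1

    def test_k_bounds_validated(self):
        with pytest.raises(ValueError):
            train_knn(np.zeros((3, 1)), np.array([1, -1, 1]), k=4)


class TestPNN:
    def test_one_vector_per_class_nearest_wins(self):
        x = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, -1])
        for sigma in (0.01, 0.1, 1.0, 10.0):
            m = train_pnn(x, y, sigma=sigma)
            assert pnn_predict(m, np.array([0.4, 0.0])).label == 1, sigma
            assert pnn_predict(m, np.array([-0.4, 0.0])).label == -1, sigma

    def test_exact_midpoint_tie_resolves_to_negative(self):
        m = train_pnn(np.array([[1.0], [-1.0]]), np.array([1, -1]), sigma=0.5)
        assert pnn_predict(m, np.array([0.0])).label == -1

    def test_small_sigma_matches_nearest_neighbour(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(size=(60, 8))
        y = np.where(rng.uniform(size=60) < 0.4, 1, -1)
        if len(set(y)) < 2:
            y[0] = 1
        queries = rng.uniform(size=(50, 8))
        pnn = train_pnn(x, y, sigma=1e-3)
        knn = train_knn(x, y, k=1)
        pnn_labels = np.where(pnn_predict_batch(pnn, queries) > 0, 1, -1)
        knn_labels = [knn_predict(knn, q).label for q in queries]
        assert pnn_labels.tolist() == knn_labels

    def test_sigma_scaling_preserves_small_sigma_labels(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(30, 4))
        y = np.array([1, -1] * 15)
        q = rng.uniform(size=(20, 4))
        l1 = np.sign(pnn_predict_batch(train_pnn(x, y, sigma=1e-3), q))
        l2 = np.sign(pnn_predict_batch(train_pnn(x, y, sigma=2e-3), q))
        np.testing.assert_array_equal(l1, l2)

    def test_class_order_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(size=(20, 3))
        y = np.array([1, -1] * 10)
        q = rng.uniform(size=(10, 3))
        perm = rng.permutation(20)
        a = pnn_predict_batch(train_pnn(x, y, sigma=0.05), q)
        b = pnn_predict_batch(train_pnn(x[perm], y[perm], sigma=0.05), q)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_tiny_sigma_no_underflow_to_tie(self):
        """Log-domain accumulation keeps the default sigma=0.02 meaningful in
        98 dimensions, where the raw kernel terms underflow doubles."""
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(50, 98))
        y = np.array([1, -1] * 25)
        m = train_pnn(x, y, sigma=0.02)
        scores = pnn_predict_batch(m, rng.uniform(size=(20, 98)))
        assert np.all(scores != 0.0)
        assert np.all(np.isfinite(scores))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            train_pnn(np.zeros((3, 2)), np.array([1, 1, 1]))


class TestSimilarityScreen:
    def test_exact_copy_is_hit(self):
        a = np.array([[0.5, 0.5, 0.1]])
        lib = np.vstack([a[0], [0.9, 0.0, 0.0]])
        res = similarity_screen(a, lib, cutoff=0.9)
        assert res.hits.tolist() == [True, False]
        assert res.best_sim[0] == pytest.approx(1.0)

    def test_disjoint_support_no_hits(self):
        a = np.array([[1.0, 0.0]])
        lib = np.array([[0.0, 1.0], [0.0, 0.5]])
        assert similarity_screen(a, lib, cutoff=0.9).hits.sum() == 0

    def test_cutoff_zero_flags_any_nonzero_similarity(self):
        a = np.array([[1.0, 0.0]])
        lib = np.array([[0.5, 0.5], [0.0, 1.0]])
        res = similarity_screen(a, lib, cutoff=0.0)
        assert res.hits.tolist() == [True, False]

    def test_empty_active_set_rejected(self):
        with pytest.raises(ValueError):
            similarity_screen(np.empty((0, 3)), np.ones((2, 3)))


class TestEngineWrapper:
    @pytest.mark.parametrize("name", ["svm", "knn", "pnn", "tanimoto"])
    def test_fit_predict_and_json_roundtrip(self, tmp_path, name):
        x, y = separable_blobs(n=25, seed=7)
        eng = make_engine(name).fit(x, y)
        pred = eng.predict(x)
        assert set(pred.tolist()) <= {1, -1}
        p = tmp_path / f"{name}.json"
        save_engine(eng, p)
        eng2 = load_engine(p)
        np.testing.assert_allclose(eng2.decision_scores(x), eng.decision_scores(x))

    def test_engines_are_pure_functions_of_model_and_query(self):
        x, y = separable_blobs(n=15, seed=9)
        for name in ("svm", "knn", "pnn", "tanimoto"):
            eng = make_engine(name).fit(x, y)
            s1 = eng.decision_scores(x[:5])
            s2 = eng.decision_scores(x[:5])
            np.testing.assert_array_equal(s1, s2)

    def test_unknown_engine_rejected(self):
        with pytest.raises(ValueError):
            make_engine("random_forest")
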