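import numpy as np
import pytest

from dyespy import (
    ANNConfig,
    CosineNearestNeighborClassifier,
    MixtureLabel,
    MultilabelANN,
    PLSDAClassifier,
    make_phase1_model,
    predict_multilabel,
)
from dyespy.exceptions import DataError, TrainingError, UsageError

KINDS = ("LRDA", "PLSDA", "RFDA", "XGBDA", "ANNDA", "CSNNC")


def separable_dataset(rng, n_per_class=20, n_features=120, noise=0.0):
    """Two classes with disjoint active feature blocks."""
    X = np.zeros((2 * n_per_class, n_features))
    X[:n_per_class, :10] = 1.0 + noise * rng.normal(size=(n_per_class, 10))
    X[n_per_class:, 50:60] = 1.0 + noise * rng.normal(size=(n_per_class, 10))
    X += 0.01
    y = np.array(["oxidative"] * n_per_class + ["nonoxidative"] * n_per_class)
    return X, y


class TestPhase1Models:
    @pytest.mark.parametrize("kind", KINDS)
    def test_separable_clusters_fit_perfectly(self, kind, rng):
        X, y = separable_dataset(rng)
        model = make_phase1_model(kind, seed=0).fit(X, y)
        assert (model.predict(X) == y).all()

    @pytest.mark.parametrize("kind", KINDS)
    def test_single_class_input_rejected(self, kind):
        X = np.random.default_rng(0).random((6, 10))
        y = np.array(["oxidative"] * 6)
        with pytest.raises((TrainingError, ValueError)):
            make_phase1_model(kind, seed=0).fit(X, y)

    @pytest.mark.parametrize("kind", ("PLSDA", "RFDA", "ANNDA", "CSNNC"))
    def test_same_seed_same_predictions(self, kind, rng):
        X, y = separable_dataset(rng, noise=0.3)
        Xq = rng.random((15, X.shape[1]))
        a = make_phase1_model(kind, seed=3).fit(X, y).predict(Xq)
        b = make_phase1_model(kind, seed=3).fit(X, y).predict(Xq)
        assert (a == b).all()

    def test_plsda_caps_components_with_warning(self, rng):
        X, y = separable_dataset(rng, n_per_class=5)
        with pytest.warns(UserWarning, match="capped"):
            model = PLSDAClassifier(n_components=17).fit(X, y)
        assert model.n_components_ == 9  # n_samples - 1

    def test_noise_robustness_of_plsda_and_csnnc(self, rng):
        X, y = separable_dataset(rng, noise=0.0)
        Xt, yt = separable_dataset(np.random.default_rng(99), noise=0.05)
        for kind in ("PLSDA", "CSNNC"):
            model = make_phase1_model(kind, seed=0).fit(X, y)
            acc = np.mean(model.predict(Xt) == yt)
            assert acc >= 0.95


class TestCSNNC:
    def test_query_equal_to_reference(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        clf = CosineNearestNeighborClassifier().fit(X, np.array(["a", "b"]))
        label, sim = clf.classify([0.0, 1.0])
        assert label == "b" and sim == pytest.approx(1.0)

    def test_scale_invariance(self):
        X = np.array([[1.0, 0.2], [0.1, 1.0]])
        clf = CosineNearestNeighborClassifier().fit(X, np.array(["a", "b"]))
        label, sim = clf.classify(10.0 * np.array([1.0, 0.2]))
        assert label == "a" and sim == pytest.approx(1.0)

    def test_tie_resolves_to_earliest_reference_with_warning(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0]])  # identical directions
        clf = CosineNearestNeighborClassifier().fit(X, np.array(["a", "b"]))
        with pytest.warns(UserWarning, match="tie"):
            label, _ = clf.classify([3.0, 0.0])
        assert label == "a"

    def test_zero_vectors_rejected(self):
        with pytest.raises(DataError):
            CosineNearestNeighborClassifier().fit(
                np.array([[0.0, 0.0]]), np.array(["a"])
            )
        clf = CosineNearestNeighborClassifier().fit(
            np.array([[1.0, 0.0]]), np.array(["a"])
        )
        with pytest.raises(DataError):
            clf.classify([0.0, 0.0])


class TestMultilabelANN:
    def _toy(self, rng, n=30, k=3, d=60):
        X = np.zeros((n, d))
        Y = np.zeros((n, k))
        for i in range(n):
            j = i % k
            X[i, j * 15 : j * 15 + 10] = 1.0 + 0.05 * rng.normal(size=10)
            Y[i, j] = 1.0
        return X + 0.01, Y

    def test_separable_one_hot_perfect_training_subset_recall(self, rng):
        X, Y = self._toy(rng)
        cfg = ANNConfig(layers=(32,), dropout=0.0, epochs=120, eta=0.005,
                        batch_size=8)
        model = MultilabelANN(vocabulary=["A", "B", "C"], config=cfg,
                              random_state=0).fit(X, Y)
        preds = model.predict_mixtures(X)
        truths = [MixtureLabel.of("ABC"[int(np.argmax(row))]) for row in Y]
        assert all(len(p.esids & t.esids) >= 1 for p, t in zip(preds, truths))
        # training loss decreases
        assert model.loss_curve_[-1] < model.loss_curve_[0]

    def test_same_seed_identical_predictions(self, rng):
        X, Y = self._toy(rng)
        cfg = ANNConfig(layers=(16,), epochs=20, dropout=0.2)
        Xq = rng.random((5, X.shape[1]))
        a = MultilabelANN(config=cfg, random_state=4).fit(X, Y).predict_scores(Xq)
        b = MultilabelANN(config=cfg, random_state=4).fit(X, Y).predict_scores(Xq)
        np.testing.assert_array_equal(a, b)

    def test_all_zero_label_column_warns_and_never_predicted(self, rng):
        X, Y = self._toy(rng)
        Y[:, 2] = 0.0
        cfg = ANNConfig(layers=(16,), epochs=60, dropout=0.0, eta=0.005)
        with pytest.warns(UserWarning, match="never positive"):
            model = MultilabelANN(vocabulary=["A", "B", "C"], config=cfg,
                                  random_state=0).fit(X, Y)
        assert all("C" not in p.esids for p in model.predict_mixtures(X))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(TrainingError):
            MultilabelANN().fit(np.ones((4, 3)), np.ones((5, 2)))


class TestDecisionThreshold:
    class _Stub:
        vocabulary_ = ["AX", "BX", "CX"]

        def predict_scores(self, X):
            return np.array([[0.9, 0.4, 0.5]])

    def test_strictly_greater_than_half(self):
        # 0.9 -> called; 0.4 -> not; exactly 0.5 -> excluded (strict rule)
        label = predict_multilabel(self._Stub(), np.zeros(3))
        assert label.esids == frozenset({"AX"})

    def test_all_below_threshold_is_no_match(self):
        stub = self._Stub()
        stub.predict_scores = lambda X: np.array([[0.2, 0.5, 0.1]])
        label = predict_multilabel(stub, np.zeros(3))
        assert label.is_empty and str(label) == "No Match"


class TestANNConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(UsageError):
            ANNConfig(dropout=1.0)
        with pytest.raises(UsageError):
            ANNConfig(eta=0.0)
        with pytest.raises(UsageError):
            ANNConfig(optimizer="adamw")
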