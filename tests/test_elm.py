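"""Extreme learning machine: hidden layer, pseudoinverse solve, metrics."""

import numpy as np
import pytest

from dermfusion.datatypes import FeatureMatrix
from dermfusion.elm import (
    ELMClassifier, evaluate, hidden_matrix, init_hidden, load_model,
    predict_elm, save_model, train_elm,
)


class TestInitHidden:
    def test_deterministic_per_seed_and_in_range(self):
        w1, b1 = init_hidden(10, 5, seed=3)
        w2, b2 = init_hidden(10, 5, seed=3)
        np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(b1, b2)
        assert np.all(np.abs(w1) <= 1) and np.all(np.abs(b1) <= 1)
        w3, _ = init_hidden(10, 5, seed=4)
        assert not np.array_equal(w1, w3)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            init_hidden(0, 5, 0)


class TestHiddenMatrix:
    def test_zero_parameters_give_ones(self):
        H = hidden_matrix(np.ones((3, 2)), np.zeros((4, 2)), np.zeros(4))
        np.testing.assert_allclose(H, 1.0)

    def test_unit_preactivation(self):
        # w.x + c = 1 -> g = e^-1
        H = hidden_matrix(np.array([[1.0]]), np.array([[1.0]]), np.array([0.0]))
        assert H[0, 0] == pytest.approx(np.exp(-1))

    def test_entries_in_unit_interval(self, rng):
        H = hidden_matrix(rng.normal(size=(20, 6)),
                          rng.uniform(-1, 1, (15, 6)), rng.uniform(-1, 1, 15))
        assert np.all(H > 0) and np.all(H <= 1)

    def test_dim_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            hidden_matrix(rng.normal(size=(5, 3)),
                          rng.normal(size=(4, 2)), np.zeros(4))


class TestTraining:
    def test_interpolation_when_hidden_equals_samples(self):
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            X = g.normal(size=(10, 5))
            y = np.arange(10) % 2
            model = ELMClassifier(n_hidden=10, random_state=seed).fit(X, y)
            hits += int(np.mean(model.predict(X) == y) == 1.0)
        assert hits >= 99

    def test_beta_matches_lstsq_oracle(self, rng):
        # solve on a fixed random hidden matrix: pinv vs dense least squares
        for _ in range(5):
            H = rng.uniform(0, 1, size=(30, 20))
            B = rng.integers(0, 2, size=(30, 3)).astype(float)
            beta_pinv = np.linalg.pinv(H, rcond=1e-12) @ B
            beta_lstsq = np.linalg.lstsq(H, B, rcond=None)[0]
            np.testing.assert_allclose(beta_pinv, beta_lstsq, atol=1e-8)

    def test_duplicating_samples_leaves_beta_unchanged(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.arange(20) % 3
        m1 = ELMClassifier(n_hidden=8, random_state=0).fit(X, y)
        m2 = ELMClassifier(n_hidden=8, random_state=0).fit(
            np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(m1.output_weights_, m2.output_weights_,
                                   atol=1e-8)

    def test_residual_beats_random_perturbations(self, rng):
        X = rng.normal(size=(25, 4))
        y = np.arange(25) % 3
        model = ELMClassifier(n_hidden=10, random_state=1).fit(X, y)
        H = hidden_matrix(model._condition(X), model.input_weights_,
                          model.biases_)
        B = (y[:, None] == model.classes_[None, :]).astype(float)
        best = np.linalg.norm(H @ model.output_weights_ - B)
        for _ in range(100):
            alt = model.output_weights_ + rng.normal(
                scale=0.01, size=model.output_weights_.shape)
            assert np.linalg.norm(H @ alt - B) >= best - 1e-12

    def test_accuracy_non_decreasing_in_hidden_width(self, rng):
        X = np.vstack([rng.normal(size=(30, 4)) + m for m in (0, 3, 6)])
        y = np.repeat([0, 1, 2], 30)
        medians = []
        for L in (2, 10, 40):
            accs = [np.mean(ELMClassifier(n_hidden=L, random_state=s)
                            .fit(X, y).predict(X) == y) for s in range(10)]
            medians.append(np.median(accs))
        assert medians[0] <= medians[1] <= medians[2]

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            ELMClassifier().fit(rng.normal(size=(10, 3)), np.zeros(10))


class TestPrediction:
    def test_training_set_recovered_in_interpolation_regime(self):
        g = np.random.default_rng(0)
        X = g.normal(size=(10, 5))
        y = np.arange(10) % 2
        fm = FeatureMatrix(X, y)
        model = train_elm(fm, L=10, seed=0)
        np.testing.assert_array_equal(predict_elm(model, X), y)

    def test_column_permutation_with_matching_weights(self, rng):
        # permuting feature columns and hidden weights consistently leaves
        # the hidden layer, hence predictions, unchanged
        X = rng.normal(size=(40, 6))
        y = np.arange(40) % 2
        perm = rng.permutation(6)
        model = ELMClassifier(n_hidden=15, random_state=0,
                              scale_inputs=False).fit(X, y)
        H1 = hidden_matrix(X, model.input_weights_, model.biases_)
        H2 = hidden_matrix(X[:, perm], model.input_weights_[:, perm],
                           model.biases_)
        np.testing.assert_allclose(H1, H2, atol=1e-12)

    def test_single_row_input(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.arange(20) % 2
        model = ELMClassifier(n_hidden=5, random_state=0).fit(X, y)
        assert model.predict(X[:1]).shape == (1,)

    def test_roundtrip_through_json(self, rng, tmp_path):
        X = rng.normal(size=(30, 4))
        y = np.arange(30) % 3
        model = ELMClassifier(n_hidden=12, random_state=5).fit(X, y)
        save_model(model, tmp_path / "elm.json")
        loaded = load_model(tmp_path / "elm.json")
        np.testing.assert_array_equal(model.predict(X), loaded.predict(X))


class TestMetrics:
    def test_perfect_prediction(self):
        m = evaluate(["a", "b", "a"], ["a", "b", "a"])
        assert m.accuracy == 100.0 and m.precision == 100.0 and m.fdr == 0.0

    def test_hand_counted_two_class_case(self):
        m = evaluate(["A", "A", "B", "B"], ["A", "B", "B", "B"])
        assert m.accuracy == pytest.approx(75.0)
        assert m.precision == pytest.approx(75.0)  # macro of 1/2 and 1
        assert m.fdr == pytest.approx(25.0)

    def test_precision_plus_fdr_is_always_100(self, rng):
        for _ in range(20):
            truth = rng.integers(0, 4, size=50)
            pred = rng.integers(0, 4, size=50)
            m = evaluate(pred, truth, classes=np.arange(4))
            assert m.precision + m.fdr == pytest.approx(100.0)

    def test_permutation_invariant_to_sample_order(self, rng):
        truth = rng.integers(0, 3, size=40)
        pred = rng.integers(0, 3, size=40)
        perm = rng.permutation(40)
        m1 = evaluate(pred, truth, classes=np.arange(3))
        m2 = evaluate(pred[perm], truth[perm], classes=np.arange(3))
        assert m1.accuracy == m2.accuracy and m1.precision == m2.precision

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            evaluate(["a", "z"], ["a", "b"], classes=np.array(["a", "b"]))
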