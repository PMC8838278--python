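"""Extreme learning machine: a single-hidden-layer network whose hidden
parameters are random and fixed, and whose output weights are solved in
closed form by the Moore-Penrose pseudoinverse.

For training samples (a_i, b_i), hidden width L and activation g, the
hidden-output matrix is H[i, j] = g(w_j . a_i + c_j) with w_j, c_j drawn
uniformly from [-1, 1].  The one-hot target matrix B is approximated by
H @ beta, with beta = pinv(H) @ B the minimum-norm least-squares solution.
When L equals the number of distinct samples, H is square and generically
invertible, so the network interpolates the training set exactly.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.utils.validation import check_is_fitted

from .datatypes import FeatureMatrix, Metrics

__all__ = ["ELMClassifier", "init_hidden", "hidden_matrix", "train_elm",
           "predict_elm", "evaluate", "save_model", "load_model"]


def init_hidden(L: int, input_dim: int, seed: int):
    """Draw random hidden parameters: weights (L, d) and biases (L,) ~ U[-1, 1]."""
    if L < 1:
        raise ValueError("need at least one hidden node")
    if input_dim < 1:
        raise ValueError("need at least one input dimension")
    rng = np.random.default_rng(seed)
    weights = rng.uniform(-1.0, 1.0, size=(L, input_dim))
    biases = rng.uniform(-1.0, 1.0, size=L)
    return weights, biases


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "rbf":
        return np.exp(-(z**2))
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {activation!r}")


def hidden_matrix(X: np.ndarray, weights: np.ndarray, biases: np.ndarray,
                  activation: str = "rbf") -> np.ndarray:
    """Hidden-layer output H[i, j] = g(w_j . x_i + c_j).

    The default g is the Gaussian radial-basis squashing g(z) = exp(-z^2),
    applied to the affine pre-activation; entries lie in (0, 1].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != weights.shape[1]:
        raise ValueError(
            f"input dim {X.shape[1]} != hidden weight dim {weights.shape[1]}"
        )
    if activation == "rbf_distance":
        # centre-based Gaussian exp(-||x - w||^2); biases act as widths gamma
        sq = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-np.abs(biases) * sq)
    return _activate(X @ weights.T + biases, activation)


class ELMClassifier(BaseEstimator, ClassifierMixin):
    """Single-hidden-layer extreme learning machine classifier.

    Parameters
    ----------
    n_hidden : int or None, default None
        Hidden width L.  ``None`` uses min(1000, n_train // 2), keeping
        the network under-determined.
    activation : {"rbf", "rbf_distance", "sigmoid"}, default "rbf"
        Hidden squashing function; "rbf" is g(z) = exp(-z^2) on the affine
        pre-activation, "rbf_distance" the centre-based Gaussian
        exp(-|c_j| * ||x - w_j||^2).
    random_state : int, default 0
        Seed for the hidden weights and biases.
    scale_inputs : bool, default True
        Standardize columns and shrink by 1/sqrt(d) before the random
        affine map, keeping pre-activations O(1) regardless of input
        width.  Disable when inputs are already conditioned.

    Attributes
    ----------
    classes_ : ndarray of class labels, in sorted order.
    input_weights_ : (L, d) hidden weights.
    biases_ : (L,) hidden biases.
    output_weights_ : (L, C) solved weight matrix beta.
    """

    def __init__(self, n_hidden: int | None = None, activation: str = "rbf",
                 random_state: int = 0, scale_inputs: bool = True):
        self.n_hidden = n_hidden
        self.activation = activation
        self.random_state = random_state
        self.scale_inputs = scale_inputs

    def _condition(self, X: np.ndarray) -> np.ndarray:
        if not self.scale_inputs:
            return X
        return (X - self.offset_) / self.scale_

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, d = X.shape
        if n < 2:
            raise ValueError("need at least two training samples")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training labels contain a single class")

        if self.scale_inputs:
            self.offset_ = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            self.scale_ = sd * np.sqrt(d)
        Xc = self._condition(X)

        # hidden width stays below the sample count: a square H interpolates
        # the training set and generalizes poorly
        L = self.n_hidden if self.n_hidden is not None else min(1000, max(1, n // 2))
        self.input_weights_, self.biases_ = init_hidden(L, d, self.random_state)
        H = hidden_matrix(Xc, self.input_weights_, self.biases_, self.activation)

        # one-hot coding with {0,1} targets, one column per class
        B = (y[:, None] == self.classes_[None, :]).astype(float)
        self.output_weights_ = np.linalg.pinv(H, rcond=1e-12) @ B
        return self

    def decision_function(self, X):
        check_is_fitted(self, "output_weights_")
        Xc = self._condition(np.atleast_2d(np.asarray(X, dtype=float)))
        H = hidden_matrix(Xc, self.input_weights_, self.biases_, self.activation)
        return H @ self.output_weights_

    def predict(self, X):
        scores = self.decision_function(X)
        # np.argmax breaks ties toward the lowest class index
        return self.classes_[np.argmax(scores, axis=1)]


def train_elm(features: FeatureMatrix, L: int | None = None, seed: int = 0,
              activation: str = "rbf") -> ELMClassifier:
    """Fit an :class:`ELMClassifier` on a labeled feature matrix."""
    model = ELMClassifier(n_hidden=L, activation=activation, random_state=seed)
    return model.fit(features.values, features.labels)


def predict_elm(model: ELMClassifier, X) -> np.ndarray:
    """Predict class labels with a trained ELM."""
    return model.predict(X)


def evaluate(predicted, truth, classes=None, elapsed_time: float = 0.0) -> Metrics:
    """Accuracy, macro precision and FDR (percent) plus the confusion table.

    Macro precision averages TP/(TP+FP) over classes; a class that is never
    predicted contributes 0.  FDR is reported as 100 - precision, the
    convention of dermoscopy benchmarking tables.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([truth, predicted]))
    classes = np.asarray(classes)
    known = set(classes.tolist())
    for lab in np.concatenate([truth, predicted]):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}")

    conf = confusion_matrix(truth, predicted, labels=classes)
    total = conf.sum()
    accuracy = 100.0 * np.trace(conf) / total
    col_sums = conf.sum(axis=0)  # predictions per class
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(col_sums > 0, np.diag(conf) / np.maximum(col_sums, 1), 0.0)
    precision = 100.0 * per_class.mean()
    return Metrics(
        accuracy=float(accuracy),
        precision=float(precision),
        fdr=float(100.0 - precision),
        confusion=conf,
        classes=classes,
        elapsed_time=elapsed_time,
    )


def save_model(model: ELMClassifier, path) -> None:
    """Persist a trained ELM as JSON (weights, biases, beta, classes)."""
    import json
    from pathlib import Path

    check_is_fitted(model, "output_weights_")
    payload = {
        "activation": model.activation,
        "random_state": model.random_state,
        "scale_inputs": model.scale_inputs,
        "classes": np.asarray(model.classes_).tolist(),
        "input_weights": model.input_weights_.tolist(),
        "biases": model.biases_.tolist(),
        "output_weights": model.output_weights_.tolist(),
        "offset": model.offset_.tolist() if model.scale_inputs else None,
        "scale": model.scale_.tolist() if model.scale_inputs else None,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> ELMClassifier:
    """Restore an ELM persisted by :func:`save_model`."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    model = ELMClassifier(
        n_hidden=len(payload["biases"]), activation=payload["activation"],
        random_state=payload["random_state"], scale_inputs=payload["scale_inputs"])
    model.classes_ = np.asarray(payload["classes"])
    model.input_weights_ = np.asarray(payload["input_weights"], float)
    model.biases_ = np.asarray(payload["biases"], float)
    model.output_weights_ = np.asarray(payload["output_weights"], float)
    if payload["scale_inputs"]:
        model.offset_ = np.asarray(payload["offset"], float)
        model.scale_ = np.asarray(payload["scale"], float)
    return model
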