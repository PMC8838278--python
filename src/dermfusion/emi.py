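"""Fuzzy entropy-mutual information (EMI) filter feature selection.

Each feature is min-max normalized to [0, 1] and read as a fuzzy
membership vector; its fuzzy entropy

    FE = -K * sum( m*log(m) + (1-m)*log(1-m) )

is zero for crisp (0/1) memberships and maximal at 0.5.  Mutual
information of the (binned) feature with the class label measures
relevance.  The combined score

    s_j = MI_j * FE_j / max_k FE_k

weights relevance by relative fuzziness, suppressing near-constant
columns; features scoring at least the mean score are selected.  All
entropies use the natural logarithm (nats).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import FeatureMatrix, SelectionResult

__all__ = ["fuzzy_entropy", "joint_and_conditional_entropy",
           "mutual_information", "EMISelector", "emi_select"]


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log(p) with the 0*log(0) := 0 convention."""
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = p[pos] * np.log(p[pos])
    return out


def fuzzy_entropy(memberships, K: float = 1.0) -> float:
    """Shannon-style entropy of fuzzy membership degrees in [0, 1]."""
    m = np.asarray(memberships, dtype=float).ravel()
    if m.size == 0:
        raise ValueError("empty membership vector")
    if np.any((m < 0) | (m > 1)):
        raise ValueError("memberships must lie in [0, 1]")
    if K <= 0:
        raise ValueError("K must be positive")
    return float(-K * np.sum(_xlogx(m) + _xlogx(1.0 - m)))


def joint_and_conditional_entropy(joint: np.ndarray) -> dict:
    """Joint entropy H(X,Y) and conditional entropy H(X|Y) of a joint table.

    ``joint[i, j] = p(x_i, y_j)``; rows index X, columns Y.  Returns nats.
    """
    p = np.asarray(joint, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("joint probabilities must sum to 1")
    h_joint = float(-np.sum(_xlogx(p)))
    p_y = p.sum(axis=0)
    h_y = float(-np.sum(_xlogx(p_y)))
    # H(X|Y) = H(X,Y) - H(Y); avoids forming p(x|y) for empty columns
    return {"joint_entropy": h_joint, "conditional_entropy": h_joint - h_y}


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin codes for continuous input; categorical passed through."""
    x = np.asarray(x)
    if x.dtype.kind in "OUSb" or (x.dtype.kind in "iu" and np.unique(x).size <= n_bins):
        _, codes = np.unique(x, return_inverse=True)
        return codes
    x = x.astype(float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)


def _joint_table(cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    table = np.zeros((cx.max() + 1, cy.max() + 1))
    np.add.at(table, (cx, cy), 1.0)
    return table / table.sum()


def mutual_information(x, y, n_bins: int = 16) -> float:
    """Empirical mutual information I(X;Y) in nats, from a binned joint table.

    Continuous inputs are equal-width binned into ``n_bins``; categorical
    inputs (strings, or integers with few levels) are used as-is.
    Non-negative and symmetric; satisfies I = H(X) + H(Y) - H(X,Y).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two samples")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = _joint_table(_discretize(x, n_bins), _discretize(y, n_bins))
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    pos = p > 0
    return float(np.sum(p[pos] * np.log(p[pos] / (px @ py)[pos])))


class EMISelector(SelectorMixin, BaseEstimator):
    """Filter selector scoring features by fuzzy entropy x mutual information.

    Deterministic given its inputs (binning is deterministic; no RNG).

    Parameters
    ----------
    n_bins : int, default 16
        Equal-width bins for the MI estimate.
    K : float, default 1.0
        Fuzzy-entropy scale constant.

    Attributes
    ----------
    support_ : boolean mask of selected features.
    fuzzy_entropy_ : per-feature fuzzy entropy of the normalized column.
    mi_ : per-feature mutual information with the class label.
    scores_ : combined scores s_j = MI_j * FE_j / max FE.
    threshold_ : mean combined score used as the selection cut.
    """

    def __init__(self, n_bins: int = 16, K: float = 1.0):
        self.n_bins = n_bins
        self.K = K

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.unique(y).size < 2:
            raise ValueError("labels contain a single class")
        n, D = X.shape

        fe = np.zeros(D)
        mi = np.zeros(D)
        for j in range(D):
            col = X[:, j]
            lo, hi = col.min(), col.max()
            if hi == lo:
                fe[j] = 0.0  # constant column: no informative variance
                mi[j] = 0.0
                continue
            memberships = (col - lo) / (hi - lo)
            fe[j] = fuzzy_entropy(memberships, self.K)
            mi[j] = mutual_information(col, y, self.n_bins)

        if fe.max() == 0.0:
            raise ValueError("no informative variance in any feature")
        scores = mi * fe / fe.max()
        threshold = scores.mean()
        support = scores >= threshold
        if not support.any():
            support[int(np.argmax(scores))] = True

        self.fuzzy_entropy_ = fe
        self.mi_ = mi
        self.scores_ = scores
        self.threshold_ = float(threshold)
        self.support_ = support
        self.n_features_in_ = D
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def emi_select(features: FeatureMatrix, n_bins: int = 16, K: float = 1.0) -> SelectionResult:
    """Run EMI filter selection on a labeled feature matrix."""
    sel = EMISelector(n_bins=n_bins, K=K)
    sel.fit(features.values, features.labels)
    return SelectionResult(sel.support_, sel.scores_, "emi")
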