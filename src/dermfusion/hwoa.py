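"""Hybrid whale-optimization feature selection.

The whale optimization algorithm (WOA) searches continuous positions in
[0, 1]^D, one coordinate per feature.  Each iteration every agent either
(a) encircles the best-known solution, (b) follows a logarithmic spiral
around it, or (c) explores relative to a random agent; the shrink
coefficient alpha decays linearly 2 -> 0 over iterations, moving the swarm
from exploration to exploitation.  Positions binarize at a threshold into
feature masks, scored by the wrapper fitness

    Fit = alpha_w * err + beta_w * |R| / D

where err is the validation error of a small extreme learning machine
trained on the candidate subset and |R|/D the selected fraction.  The
best-ever position is finally refined by an absolute-mean-deviation (AMD)
cut: features whose position score clears the AMD of the score vector are
retained (with a top-k fallback so the selection is never empty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .datatypes import FeatureMatrix, SelectionResult
from .elm import ELMClassifier
from .enhance import compute_amd

__all__ = ["FitnessConfig", "update_shrink", "woa_position_update", "fitness",
           "binarize_position", "amd_refine", "woa_minimize", "HWOASelector",
           "hwoa_select"]


def woa_minimize(objective, dim: int, n_agents: int = 30,
                 max_iterations: int = 200, seed: int = 0):
    """Minimize ``objective`` over [0, 1]^dim with the WOA update rules.

    Elitist: the best-ever position and fitness are tracked across
    iterations, so the returned trace is non-increasing.  Returns
    ``(best_position, best_fitness, trace)``.
    """
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, 1.0, size=(n_agents, dim))
    fits = np.array([objective(p) for p in positions])
    best_idx = int(np.argmin(fits))
    best_pos = positions[best_idx].copy()
    best_fit = float(fits[best_idx])

    trace = []
    for t in range(max_iterations):
        alpha = update_shrink(t, max_iterations)
        for i in range(n_agents):
            j = int(rng.integers(n_agents))
            positions[i] = woa_position_update(
                positions[i], best_pos, positions[j], alpha,
                r=rng.uniform(0.0, 1.0, dim),
                h=rng.uniform(-1.0, 1.0),
                ran=rng.uniform(0.0, 1.0),
            )
            fit = float(objective(positions[i]))
            if fit < best_fit:
                best_fit = fit
                best_pos = positions[i].copy()
        trace.append(best_fit)
    return best_pos, best_fit, np.asarray(trace)


@dataclass
class FitnessConfig:
    """Weights and evaluation settings of the wrapper fitness.

    ``alpha_weight`` multiplies the classification error, ``beta_weight``
    the selected-feature fraction; they must sum to 1.  The error is
    measured by an ELM with ``elm_hidden_nodes`` hidden units on an
    internal holdout of ``validation_fraction`` of the training data,
    split with ``fitness_seed`` so all candidates face the same data.
    """

    alpha_weight: float = 0.99
    beta_weight: float = 0.01
    elm_hidden_nodes: int = 50
    validation_fraction: float = 0.3
    fitness_seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_weight < 0 or self.beta_weight < 0:
            raise ValueError("fitness weights must be non-negative")
        if abs(self.alpha_weight + self.beta_weight - 1.0) > 1e-9:
            raise ValueError("alpha_weight + beta_weight must equal 1")


def update_shrink(t: int, max_iterations: int) -> float:
    """Linearly decaying shrink coefficient: 2 - t * 2 / maxIt."""
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if not 0 <= t <= max_iterations:
        raise ValueError("iteration index out of range")
    return 2.0 - t * 2.0 / max_iterations


def woa_position_update(position: np.ndarray, best: np.ndarray,
                        random_agent: np.ndarray, shrink_alpha: float,
                        r: np.ndarray, h: float, ran: float,
                        spiral_b: float = 1.0) -> np.ndarray:
    """One WOA move for a single agent; result clamped to [0, 1]^D.

    ``r`` is a U[0,1] D-vector, ``h`` a U[-1,1] scalar, ``ran`` a U[0,1]
    scalar.  With ``ran < 0.5`` the coefficient vector V2 = 2*alpha*r -
    alpha decides between encircling the best solution (|V2| < 1, measured
    in the infinity norm) and exploring around ``random_agent`` (|V2| >=
    1); with ``ran >= 0.5`` the agent spirals toward the best solution
    with pitch ``spiral_b``.
    """
    position = np.asarray(position, dtype=float)
    best = np.asarray(best, dtype=float)
    random_agent = np.asarray(random_agent, dtype=float)
    r = np.asarray(r, dtype=float)
    if not (position.shape == best.shape == random_agent.shape == r.shape):
        raise ValueError("position, best, random_agent and r must share one dimension")

    v1 = 2.0 * r
    v2 = 2.0 * shrink_alpha * r - shrink_alpha
    if ran < 0.5:
        if np.max(np.abs(v2)) < 1.0:
            # encircling: contract toward the best-known solution
            psi = np.abs(v1 * best - position)
            new = best - v2 * psi
        else:
            # exploration: move relative to a randomly chosen agent
            psi = np.abs(v1 * random_agent - position)
            new = np.abs(random_agent - psi * v2)
    else:
        # spiral bubble-net move around the best solution
        psi = np.abs(best - position)
        new = psi * np.exp(spiral_b * h) * np.cos(2.0 * np.pi * h) + best
    return np.clip(new, 0.0, 1.0)


def fitness(error_rate: float, n_selected: int, total_features: int,
            config: FitnessConfig) -> float:
    """Wrapper fitness: alpha_w * error + beta_w * (|R| / D); lower is better."""
    if n_selected == 0:
        raise ValueError("empty subset")
    if not 1 <= n_selected <= total_features:
        raise ValueError("n_selected out of range")
    return (config.alpha_weight * error_rate
            + config.beta_weight * n_selected / total_features)


def binarize_position(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Feature j selected iff position_j >= threshold (inclusive).

    An all-off vector is repaired by forcing on the single largest
    coordinate, so every candidate mask is evaluable.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    position = np.asarray(position, dtype=float)
    mask = position >= threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return mask


def amd_refine(best_position: np.ndarray, min_features: int = 1) -> np.ndarray:
    """AMD cut over the best position's scores.

    Retains features whose score is at least the absolute mean deviation
    of the score vector; if fewer than ``min_features`` survive, the
    top-``min_features`` by score are retained instead.
    """
    scores = np.asarray(best_position, dtype=float)
    if scores.size < 1:
        raise ValueError("empty score vector")
    if not 1 <= min_features <= scores.size:
        raise ValueError("min_features out of range")
    md = compute_amd(scores, scores.mean())
    mask = scores >= md
    if mask.sum() < min_features:
        order = np.argsort(scores)[::-1]
        mask = np.zeros(scores.size, dtype=bool)
        mask[order[:min_features]] = True
    return mask


class HWOASelector(SelectorMixin, BaseEstimator):
    """Wrapper feature selector driven by whale optimization.

    Continuous WOA search over [0, 1]^D subset encodings, ELM validation
    error as the dominant fitness term, AMD refinement of the best
    position.  Deterministic given ``random_state``.

    Parameters
    ----------
    n_agents : int, default 20
        Swarm size.
    max_iterations : int, default 100
        WOA iterations.
    threshold : float, default 0.5
        Binarization cut on position coordinates.
    min_features : int or None, default None
        Floor for the AMD refinement; ``None`` uses 5% of D (at least 1).
    alpha_weight, beta_weight : float
        Fitness weights on error and subset fraction (sum to 1).
    elm_hidden_nodes : int, default 50
        Hidden width of the fitness ELM.
    validation_fraction : float, default 0.3
        Internal holdout fraction for the error estimate.
    n_eval_splits : int, default 4
        Internal holdouts whose errors are averaged per candidate; one
        split is cheapest but its noise lets lucky masks become
        unbeatable incumbents.
    random_state : int, default 0
        Master seed for agent initialization, update draws and the
        internal split.

    Attributes
    ----------
    support_ : boolean mask of selected features.
    scores_ : best continuous position found.
    fitness_trace_ : best-so-far fitness per iteration (non-increasing).
    best_fitness_ : final best fitness.
    """

    def __init__(self, n_agents: int = 20, max_iterations: int = 100,
                 threshold: float = 0.5, min_features: int | None = None,
                 alpha_weight: float = 0.99, beta_weight: float = 0.01,
                 elm_hidden_nodes: int = 50, validation_fraction: float = 0.3,
                 n_eval_splits: int = 4, random_state: int = 0):
        self.n_agents = n_agents
        self.max_iterations = max_iterations
        self.threshold = threshold
        self.min_features = min_features
        self.alpha_weight = alpha_weight
        self.beta_weight = beta_weight
        self.elm_hidden_nodes = elm_hidden_nodes
        self.validation_fraction = validation_fraction
        self.n_eval_splits = n_eval_splits
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("need a 2-D matrix with at least two features")
        if np.unique(y).size < 2:
            raise ValueError("labels contain a single class")
        n, D = X.shape
        cfg = FitnessConfig(self.alpha_weight, self.beta_weight,
                            self.elm_hidden_nodes, self.validation_fraction,
                            fitness_seed=self.random_state)

        # fixed internal splits: all candidates see the same data; averaging
        # over a few splits de-noises the error estimate
        splits = []
        for s in range(max(1, self.n_eval_splits)):
            idx_tr, idx_va = train_test_split(
                np.arange(n), test_size=cfg.validation_fraction,
                random_state=cfg.fitness_seed + s, stratify=y)
            splits.append((X[idx_tr], y[idx_tr], X[idx_va], y[idx_va]))
        cache: dict[bytes, float] = {}

        def evaluate_mask(mask: np.ndarray) -> float:
            key = np.packbits(mask).tobytes()
            if key not in cache:
                errs = []
                for X_tr, y_tr, X_va, y_va in splits:
                    model = ELMClassifier(n_hidden=cfg.elm_hidden_nodes,
                                          random_state=cfg.fitness_seed)
                    model.fit(X_tr[:, mask], y_tr)
                    errs.append(float(np.mean(model.predict(X_va[:, mask]) != y_va)))
                cache[key] = fitness(float(np.mean(errs)), int(mask.sum()), D, cfg)
            return cache[key]

        best_pos, best_fit, trace = woa_minimize(
            lambda p: evaluate_mask(binarize_position(p, self.threshold)),
            dim=D, n_agents=self.n_agents,
            max_iterations=self.max_iterations, seed=self.random_state)

        floor = self.min_features
        if floor is None:
            floor = max(1, int(round(0.05 * D)))
        self.support_ = amd_refine(best_pos, floor)
        self.scores_ = best_pos
        self.fitness_trace_ = np.asarray(trace)
        self.best_fitness_ = best_fit
        self.n_features_in_ = D
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def hwoa_select(features: FeatureMatrix, n_agents: int = 20,
                max_iterations: int = 100, seed: int = 0,
                **kwargs) -> SelectionResult:
    """Run HWOA selection on a labeled feature matrix."""
    sel = HWOASelector(n_agents=n_agents, max_iterations=max_iterations,
                       random_state=seed, **kwargs)
    sel.fit(features.values, features.labels)
    return SelectionResult(sel.support_, sel.scores_, "hwoa", sel.fitness_trace_)
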