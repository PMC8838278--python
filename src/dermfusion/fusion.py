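"""Feature fusion by (multiset) canonical correlation analysis.

Two (or three) feature sets observed on the same samples are fused by
finding per-set projection directions that maximize cross-set correlation.
For two sets X, Y with within-covariances Zxx, Zyy and cross-covariance
Zxy, the directions solve the generalized eigenproblem

    Zxx^-1 Zxy Zyy^-1 Zyx a_x = lambda a_x ,   lambda = rho^2,

whose eigenvalues are the squared canonical correlations.  For three sets
the sum-of-pairwise-correlations (MAXVAR-style) multiset formulation is
solved: C a = lambda D a with C the full cross-covariance block matrix and
D the block-diagonal of within-covariances.  Within-set blocks are ridge
regularized so rank-deficient selected-feature blocks stay solvable.  The
fused matrix concatenates the projected sets, sorts columns by decreasing
variance, and prunes near-duplicate columns by a greedy correlation scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .datatypes import FeatureMatrix

__all__ = ["FusionResult", "covariance_blocks", "solve_mdcca", "fuse",
           "remove_redundant", "MultisetCCAFuser"]


@dataclass
class FusionResult:
    """Projections, canonical values and bookkeeping of one fusion run."""

    projections: list  # per-set (d_k, d) matrices
    canonical_values: np.ndarray  # eigenvalues, descending
    canonical_correlations: np.ndarray  # sqrt of clipped eigenvalues
    ridge: float
    means: list = field(default_factory=list)  # per-set column means
    fused: np.ndarray | None = None
    kept_columns: np.ndarray | None = None
    column_order: np.ndarray | None = None  # variance sort applied to fused


def _validate_sets(sets) -> list[np.ndarray]:
    mats = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sets]
    if not 2 <= len(mats) <= 3:
        raise ValueError("fusion supports 2 or 3 feature sets")
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("all sets must share the same sample rows")
    if n < 2:
        raise ValueError("need at least two samples")
    return mats


def covariance_blocks(sets) -> dict:
    """Column-centered sample covariance blocks (n-1 denominator).

    Returns ``{"within": [Z_kk...], "cross": {(k, l): Z_kl...}}`` for every
    ordered pair; blocks are exactly symmetric where expected.
    """
    mats = _validate_sets(sets)
    n = mats[0].shape[0]
    centered = [m - m.mean(axis=0) for m in mats]
    within = [(c.T @ c) / (n - 1) for c in centered]
    cross = {}
    for k in range(len(mats)):
        for l in range(len(mats)):
            if k != l:
                cross[(k, l)] = (centered[k].T @ centered[l]) / (n - 1)
    return {"within": within, "cross": cross}


def _ridged(block: np.ndarray, ridge_scale: float) -> tuple[np.ndarray, float]:
    d = block.shape[0]
    eps = ridge_scale * np.trace(block) / d if np.trace(block) > 0 else ridge_scale
    return block + eps * np.eye(d), eps


def solve_mdcca(sets, d: int | None = None, ridge: float = 1e-6) -> FusionResult:
    """Solve the CCA generalized eigenproblem over 2 or 3 feature sets.

    Returns the ``d`` leading eigenpairs (eigenvalues descending);
    projection columns are normalized so each projected variate has unit
    variance on the fitting data.  ``d=None`` keeps every eigenvalue above
    1e-8, capped at the smallest set dimension.
    """
    mats = _validate_sets(sets)
    dims = [m.shape[1] for m in mats]
    d_max = min(dims)
    if d is not None and d > d_max:
        raise ValueError(f"d={d} exceeds smallest set dimension {d_max}")

    blocks = covariance_blocks(mats)
    within = blocks["within"]
    cross = blocks["cross"]

    if len(mats) == 2:
        zxx, eps = _ridged(within[0], ridge)
        zyy, _ = _ridged(within[1], ridge)
        zxy, zyx = cross[(0, 1)], cross[(1, 0)]
        m = scipy.linalg.solve(zxx, zxy) @ scipy.linalg.solve(zyy, zyx)
        vals, vecs = scipy.linalg.eig(m)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite eigen-solution")
        vals = vals.real
        vecs = vecs.real
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        n_keep = d if d is not None else max(1, min(d_max, int(np.sum(vals > 1e-8))))
        vals, ax = vals[:n_keep], vecs[:, :n_keep]
        # partner directions: a_y proportional to Zyy^-1 Zyx a_x
        ay = scipy.linalg.solve(zyy, zyx @ ax)
        projections = [ax, ay]
    else:
        # three sets: sum-of-pairwise-correlations multiset CCA
        dtot = sum(dims)
        C = np.zeros((dtot, dtot))
        D = np.zeros((dtot, dtot))
        offs = np.concatenate([[0], np.cumsum(dims)])
        for k in range(3):
            wk, eps = _ridged(within[k], ridge)
            D[offs[k]:offs[k + 1], offs[k]:offs[k + 1]] = wk
            for l in range(3):
                if k != l:
                    C[offs[k]:offs[k + 1], offs[l]:offs[l + 1]] = cross[(k, l)]
        vals, vecs = scipy.linalg.eigh(C, D)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        n_keep = d if d is not None else max(1, min(d_max, int(np.sum(vals > 1e-8))))
        vals = vals[:n_keep]
        projections = [vecs[offs[k]:offs[k + 1], :n_keep] for k in range(3)]
        eps = ridge

    # normalize each projection column to unit projected variance
    normed = []
    for a, w in zip(projections, within):
        var = np.einsum("ij,jk,ki->i", a.T, w, a)
        var = np.where(var > 0, var, 1.0)
        normed.append(a / np.sqrt(var))

    # for m = 3 the eigenvalues are pairwise-correlation sums, not rho^2
    corrs = (np.sqrt(np.clip(vals, 0.0, None)) if len(mats) == 2
             else np.full(len(vals), np.nan))
    return FusionResult(
        projections=normed,
        canonical_values=np.asarray(vals, float),
        canonical_correlations=np.asarray(corrs, float),
        ridge=float(eps),
        means=[m.mean(axis=0) for m in mats],
    )


def fuse(sets, result: FusionResult) -> np.ndarray:
    """Project each centered set and concatenate; columns variance-sorted.

    The column order used is recorded on ``result.column_order``.
    """
    mats = _validate_sets(sets)
    if len(mats) != len(result.projections):
        raise ValueError("set count does not match fitted projections")
    parts = []
    for m, a, mu in zip(mats, result.projections, result.means):
        if m.shape[1] != a.shape[0]:
            raise ValueError(
                f"set width {m.shape[1]} does not match projection rows {a.shape[0]}"
            )
        parts.append((m - mu) @ a)
    fused = np.hstack(parts)
    order = np.argsort(fused.var(axis=0))[::-1]
    result.column_order = order
    result.fused = fused[:, order]
    return result.fused


def remove_redundant(fused: np.ndarray, corr_threshold: float = 0.95):
    """Greedy left-to-right pruning of near-duplicate columns.

    Columns are assumed variance-sorted; column j is dropped when its
    absolute Pearson correlation with any already-kept column exceeds the
    threshold, or when it duplicates a kept column exactly.  Returns
    ``(pruned, kept_indices)``.
    """
    if not 0.0 < corr_threshold <= 1.0:
        raise ValueError("corr_threshold must lie in (0, 1]")
    X = np.atleast_2d(np.asarray(fused, dtype=float))
    n, d = X.shape
    kept: list[int] = []
    centered = X - X.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    for j in range(d):
        drop = False
        for k in kept:
            if np.array_equal(X[:, j], X[:, k]):
                drop = True
                break
            if norms[j] > 0 and norms[k] > 0:
                r = abs(centered[:, j] @ centered[:, k] / (norms[j] * norms[k]))
                if r > corr_threshold:
                    drop = True
                    break
        if not drop:
            kept.append(j)
    kept_arr = np.asarray(kept, dtype=int)
    return X[:, kept_arr], kept_arr


class MultisetCCAFuser(BaseEstimator):
    """Canonical-correlation fusion of 2-3 feature sets as an estimator.

    ``fit`` solves the eigenproblem on training sets; ``transform``
    projects new sets with the fitted directions, applies the fitted
    column order, and keeps the columns that survived pruning on the
    training data.

    The estimator defaults differ from the bare :func:`solve_mdcca`
    operation: sample canonical correlations saturate near 1 whenever the
    observation count is comparable to the set widths, so the fuser uses a
    heavy relative ridge (1.0, i.e. shrinkage of each within-block toward
    its average variance) and keeps only the components whose eigenvalue
    exceeds the mean eigenvalue (Kaiser-style cut).  Both revert to the
    raw eigen-solve by passing ``ridge`` small and ``d`` explicitly.

    Parameters
    ----------
    d : int or None, default None
        Projection pairs to keep; ``None`` keeps eigenvalues above the
        mean eigenvalue.
    ridge : float, default 1.0
        Relative ridge added to within-set covariance blocks
        (``eps = ridge * trace(Z_kk) / d_k``).
    corr_threshold : float, default 0.95
        Absolute-correlation cut of the redundancy pruning.

    Attributes
    ----------
    result_ : the :class:`FusionResult` of the fit.
    kept_columns_ : fused-column indices surviving pruning.
    n_features_out_ : fused width after pruning.
    """

    def __init__(self, d: int | None = None, ridge: float = 1.0,
                 corr_threshold: float = 0.95):
        self.d = d
        self.ridge = ridge
        self.corr_threshold = corr_threshold

    def fit(self, sets, y=None):
        result = solve_mdcca(sets, d=self.d, ridge=self.ridge)
        if self.d is None:
            lam = result.canonical_values
            d_auto = max(1, int(np.sum(lam > lam.mean())))
            result.projections = [a[:, :d_auto] for a in result.projections]
            result.canonical_values = lam[:d_auto]
            result.canonical_correlations = result.canonical_correlations[:d_auto]
        fused = fuse(sets, result)
        _, kept = remove_redundant(fused, self.corr_threshold)
        result.kept_columns = kept
        self.result_ = result
        self.kept_columns_ = kept
        self.n_features_out_ = kept.size
        return self

    def transform(self, sets) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise ValueError("fuser not fitted; call fit first")
        mats = _validate_sets(sets)
        parts = []
        for m, a, mu in zip(mats, self.result_.projections, self.result_.means):
            if m.shape[1] != a.shape[0]:
                raise ValueError("set width does not match fitted projections")
            parts.append((m - mu) @ a)
        fused = np.hstack(parts)[:, self.result_.column_order]
        return fused[:, self.kept_columns_]

    def fit_transform(self, sets, y=None):
        return self.fit(sets).transform(sets)


def fuse_feature_matrices(features: FeatureMatrix, mask_a, mask_b,
                          d: int | None = None, ridge: float = 1.0,
                          corr_threshold: float = 0.95) -> FeatureMatrix:
    """Fuse two selected views of one feature matrix into a new matrix."""
    fuser = MultisetCCAFuser(d=d, ridge=ridge, corr_threshold=corr_threshold)
    sets = [features.values[:, np.asarray(mask_a)], features.values[:, np.asarray(mask_b)]]
    fused = fuser.fit_transform(sets)
    return FeatureMatrix(fused, features.labels, source="mdcca-fused")
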