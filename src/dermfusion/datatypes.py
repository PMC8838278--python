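"""Shared data containers: feature matrices, selection masks, metrics."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """Samples-by-features table with per-sample class labels.

    The currency of every stage after feature extraction.  ``values`` is an
    ``(n_samples, n_features)`` float array; ``labels`` holds one categorical
    class identifier per row.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_samples, n_features)")
        if self.values.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.labels)} labels"
            )
        if self.values.shape[1] < 1:
            raise ValueError("need at least one feature column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.feature_names is not None and len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match feature count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        """Column subset by boolean mask or index array."""
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        names = None
        if self.feature_names is not None:
            names = [self.feature_names[i] for i in idx]
        return FeatureMatrix(self.values[:, idx], self.labels, names, self.source)

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"f{i}" for i in range(self.n_features)]
        df = pd.DataFrame(self.values, columns=names)
        df["label"] = self.labels
        return df

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, index=False, sep=sep)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "") -> "FeatureMatrix":
        if "label" not in df.columns:
            raise ValueError("feature table must contain a 'label' column")
        labels = df["label"].to_numpy()
        vals = df.drop(columns=["label"])
        return cls(vals.to_numpy(dtype=float), labels, list(vals.columns), source)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "FeatureMatrix":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls.from_frame(pd.read_csv(path, sep=sep), source=str(path))


@dataclass
class SelectionResult:
    """Outcome of a feature-selection stage.

    ``mask`` flags the selected columns, ``scores`` carries the continuous
    per-feature score the mask was derived from (WOA position values or
    EMI combined scores), and ``fitness_trace`` the best-so-far optimizer
    fitness per iteration (empty for filter methods).
    """

    mask: np.ndarray
    scores: np.ndarray
    method: str
    fitness_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.mask.shape != self.scores.shape:
            raise ValueError("mask and scores must have the same length")
        if self.n_selected < 1:
            raise ValueError("selection must retain at least one feature")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "indices": self.indices.tolist(),
            "n_features": int(self.mask.size),
            "scores": self.scores.tolist(),
            "fitness_trace": np.asarray(self.fitness_trace, float).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        payload = json.loads(Path(path).read_text())
        mask = np.zeros(payload["n_features"], dtype=bool)
        mask[payload["indices"]] = True
        return cls(mask, np.asarray(payload["scores"], float), payload["method"],
                   np.asarray(payload["fitness_trace"], float))


@dataclass
class Metrics:
    """Classification report: accuracy, macro precision, FDR (all percent).

    FDR follows the convention of dermoscopy benchmarking tables:
    ``fdr = 100 - precision``.
    """

    accuracy: float
    precision: float
    fdr: float
    confusion: np.ndarray
    classes: np.ndarray
    elapsed_time: float = 0.0

    def as_dict(self) -> dict:
        return {
            "accuracy": float(self.accuracy),
            "precision": float(self.precision),
            "fdr": float(self.fdr),
            "confusion": np.asarray(self.confusion).tolist(),
            "classes": [str(c) for c in self.classes],
            "elapsed_time": float(self.elapsed_time),
        }
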