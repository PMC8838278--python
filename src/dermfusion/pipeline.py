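"""End-to-end orchestration and the evaluation protocol.

Runs the full chain — enhancement, feature extraction, HWOA and EMI
selection, canonical-correlation fusion, ELM classification — and the four
benchmark experiments on a shared split:

1. classification on the original deep features,
2. on the HWOA-selected subset,
3. on the EMI-selected subset,
4. on the fused (MdCCA) selected sets.

The protocol is a stratified 50:50 train/test holdout by default, with
stratified 10-fold cross-validation behind a flag.  One master seed fans
out to per-stage seeds through a counter-based derivation, so the whole
run is reproducible and each stage independently so.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .datatypes import FeatureMatrix, Metrics
from .elm import ELMClassifier, evaluate
from .emi import EMISelector
from .enhance import AMDSkewnessEnhancer
from .features import ToyBackbone
from .fusion import MultisetCCAFuser
from .hwoa import HWOASelector
from .synthetic import SyntheticSpec, make_features, make_images

logger = logging.getLogger("dermfusion")

__all__ = ["PipelineConfig", "RunReport", "split_data", "run_pipeline",
           "derive_seed"]

_STAGES = ("split", "hwoa", "emi", "elm", "images", "features")


def derive_seed(master_seed: int, stage: str) -> int:
    """Counter-based per-stage seed derivation from one master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; echoed verbatim into the report."""

    seed: int = 0
    holdout_fraction: float = 0.5
    cv_folds: int = 10
    use_cv: bool = False
    # selection
    n_agents: int = 20
    max_iterations: int = 100
    n_eval_splits: int = 4
    elm_hidden_nodes_fitness: int = 50
    emi_n_bins: int = 16
    # fusion
    corr_threshold: float = 0.95
    ridge: float = 1.0
    # classification
    elm_hidden_nodes: int | None = None
    # experiment toggles
    run_original: bool = True
    run_hwoa: bool = True
    run_emi: bool = True
    run_fused: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.use_cv and self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2 in CV mode")


@dataclass
class RunReport:
    """Per-experiment metrics, selection counts, timings and config echo."""

    config: dict
    experiments: dict = field(default_factory=dict)  # name -> Metrics dict
    selected_counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config,
            "experiments": self.experiments,
            "selected_counts": self.selected_counts,
            "timings": self.timings,
            "seeds": self.seeds,
        }, indent=2))


def split_data(features: FeatureMatrix, holdout_fraction: float = 0.5,
               cv_folds: int | None = None, seed: int = 0):
    """Stratified holdout (default) or stratified K-fold assignments.

    Holdout mode returns ``(train_idx, test_idx)``; CV mode (``cv_folds``
    given) returns a list of ``(train_idx, test_idx)`` pairs partitioning
    the index set.  Deterministic per seed; every class appears in train.
    """
    y = features.labels
    classes, counts = np.unique(y, return_counts=True)
    if features.n_samples < 2 * classes.size:
        raise ValueError("need at least two samples per class on average")
    if cv_folds is not None:
        if counts.min() < cv_folds:
            raise ValueError(
                f"class with {counts.min()} sample(s) cannot be split into {cv_folds} folds")
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        return list(skf.split(features.values, y))
    train_idx, test_idx = train_test_split(
        np.arange(features.n_samples), test_size=holdout_fraction,
        random_state=seed, stratify=y)
    return train_idx, test_idx


def _classify(X_tr, y_tr, X_te, y_te, classes, n_hidden, seed) -> Metrics:
    t0 = time.perf_counter()
    model = ELMClassifier(n_hidden=n_hidden, random_state=seed)
    model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    elapsed = time.perf_counter() - t0
    return evaluate(pred, y_te, classes, elapsed_time=elapsed)


def run_experiments(features: FeatureMatrix, config: PipelineConfig) -> RunReport:
    """The four benchmark experiments on one labeled feature matrix."""
    seeds = {s: derive_seed(config.seed, s) for s in _STAGES}
    report = RunReport(config=asdict(config), seeds=seeds)

    train_idx, test_idx = split_data(
        features, config.holdout_fraction, seed=seeds["split"])
    X, y = features.values, features.labels
    X_tr, y_tr, X_te, y_te = X[train_idx], y[train_idx], X[test_idx], y[test_idx]
    classes = features.classes

    def record(name: str, metrics: Metrics) -> None:
        report.experiments[name] = metrics.as_dict()
        logger.info("experiment %-8s acc=%.2f%% prec=%.2f%% fdr=%.2f%% (%.2fs)",
                    name, metrics.accuracy, metrics.precision, metrics.fdr,
                    metrics.elapsed_time)

    if config.run_original:
        record("original", _classify(X_tr, y_tr, X_te, y_te, classes,
                                     config.elm_hidden_nodes, seeds["elm"]))

    hwoa_mask = emi_mask = None
    if config.run_hwoa or config.run_fused:
        t0 = time.perf_counter()
        hwoa = HWOASelector(
            n_agents=config.n_agents, max_iterations=config.max_iterations,
            elm_hidden_nodes=config.elm_hidden_nodes_fitness,
            n_eval_splits=config.n_eval_splits,
            random_state=seeds["hwoa"])
        hwoa.fit(X_tr, y_tr)
        hwoa_mask = hwoa.support_
        report.timings["hwoa_select"] = time.perf_counter() - t0
        report.selected_counts["hwoa"] = int(hwoa_mask.sum())
    if config.run_hwoa:
        record("hwoa", _classify(X_tr[:, hwoa_mask], y_tr, X_te[:, hwoa_mask],
                                 y_te, classes, config.elm_hidden_nodes, seeds["elm"]))

    if config.run_emi or config.run_fused:
        t0 = time.perf_counter()
        emi = EMISelector(n_bins=config.emi_n_bins)
        emi.fit(X_tr, y_tr)
        emi_mask = emi.support_
        report.timings["emi_select"] = time.perf_counter() - t0
        report.selected_counts["emi"] = int(emi_mask.sum())
    if config.run_emi:
        record("emi", _classify(X_tr[:, emi_mask], y_tr, X_te[:, emi_mask],
                                y_te, classes, config.elm_hidden_nodes, seeds["elm"]))

    if config.run_fused:
        t0 = time.perf_counter()
        fuser = MultisetCCAFuser(ridge=config.ridge,
                                 corr_threshold=config.corr_threshold)
        fuser.fit([X_tr[:, hwoa_mask], X_tr[:, emi_mask]])
        F_tr = fuser.transform([X_tr[:, hwoa_mask], X_tr[:, emi_mask]])
        F_te = fuser.transform([X_te[:, hwoa_mask], X_te[:, emi_mask]])
        report.timings["fusion"] = time.perf_counter() - t0
        report.selected_counts["fused"] = int(F_tr.shape[1])
        record("fused", _classify(F_tr, y_tr, F_te, y_te, classes,
                                  config.elm_hidden_nodes, seeds["elm"]))

    return report


def run_pipeline(config: PipelineConfig,
                 features: FeatureMatrix | None = None,
                 images=None, labels=None,
                 synthetic_spec: SyntheticSpec | None = None,
                 n_images: int | None = None, n_classes: int = 7,
                 image_size: int = 64, contrast: float = 1.0,
                 enhance: bool = True, report_path: str | Path | None = None) -> RunReport:
    """Execute the enabled stages end to end and return the run report.

    Input priority: an explicit ``features`` matrix; else ``images`` +
    ``labels`` (enhanced and passed through the toy backbone); else
    ``n_images`` toy lesion images from the synthetic generator; else a
    ``synthetic_spec`` feature matrix (defaulting to the standard
    benchmark spec when nothing is supplied).
    """
    seeds = {s: derive_seed(config.seed, s) for s in _STAGES}
    if features is None:
        if images is None and n_images is not None:
            images, labels = make_images(n_images, n_classes, image_size,
                                         contrast, seed=seeds["images"])
        if images is not None:
            if labels is None or len(labels) != len(images):
                raise ValueError("images require one label each")
            t0 = time.perf_counter()
            if enhance:
                enhancer = AMDSkewnessEnhancer()
                images = enhancer.fit(images).transform(images)
            values = ToyBackbone().fit(images).transform(images)
            features = FeatureMatrix(values, np.asarray(labels), source="toy-backbone")
            logger.info("extracted %dx%d features in %.2fs",
                        *features.values.shape, time.perf_counter() - t0)
        else:
            spec = synthetic_spec or SyntheticSpec(seed=seeds["features"])
            features, _ = make_features(spec)

    report = run_experiments(features, config)
    if report_path is not None:
        report.to_json(report_path)
    return report
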