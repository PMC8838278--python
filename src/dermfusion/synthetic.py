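"""Synthetic fixtures with known ground truth.

Two generators stand in for the dermoscopy study data so every stage is
testable without a download:

* :func:`make_features` draws class-conditional feature matrices with a
  known split into informative, redundant and pure-noise columns — the
  statistical premise the selectors are built on (a minority of
  class-separating columns hidden among correlated and irrelevant ones).
* :func:`make_images` renders toy lesion images: an elliptical "lesion"
  with class-dependent colour offset, eccentricity and internal texture on
  a smoothed-noise background.  The ``contrast`` knob scales every
  class-dependent difference, so ``contrast=0`` is an exact null (images
  carry no class signal at all).

Both are bit-reproducible per seed and expose their ground truth (column
index sets; per-image lesion masks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .datatypes import FeatureMatrix

__all__ = ["SyntheticSpec", "make_features", "make_images"]


@dataclass
class SyntheticSpec:
    """Parameters of the class-conditional feature generator.

    ``class_separation`` is the spread of per-column class means in units
    of the within-class noise sigma (columns have unit noise variance).
    Seven classes by default, mirroring the seven-lesion-class setting.
    """

    n_samples: int = 200
    n_classes: int = 7
    n_informative: int = 8
    n_redundant: int = 4
    n_noise: int = 48
    class_separation: float = 3.0
    imbalance: float = 0.0  # 0 = balanced; 1 = maximally skewed class sizes
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def _class_sizes(spec: SyntheticSpec) -> np.ndarray:
    base = np.full(spec.n_classes, spec.n_samples // spec.n_classes)
    base[: spec.n_samples % spec.n_classes] += 1
    if spec.imbalance > 0:
        # geometric tilt, renormalized to the same total
        w = (1.0 - 0.9 * spec.imbalance) ** np.arange(spec.n_classes)
        tilted = np.maximum(2, np.round(spec.n_samples * w / w.sum()).astype(int))
        while tilted.sum() > spec.n_samples:
            tilted[np.argmax(tilted)] -= 1
        while tilted.sum() < spec.n_samples:
            tilted[np.argmin(tilted)] += 1
        base = tilted
    return base


def make_features(spec: SyntheticSpec):
    """Labeled feature matrix plus ground-truth column index sets.

    Informative columns are class-conditional Gaussians with unit sigma;
    each column's class means are a seeded random permutation of equally
    spaced levels spanning ``class_separation`` sigma, so every
    informative column separates classes on its own while different
    columns order the classes differently (jointly complementary).
    Redundant columns are random linear combinations of the informative
    block plus N(0, 0.01) noise; noise columns are standard normal.
    Returns ``(FeatureMatrix, {"informative", "redundant", "noise"})``.
    """
    if spec.n_samples < 2 * spec.n_classes:
        raise ValueError("need at least two samples per class")
    if spec.n_informative < 1:
        raise ValueError("need at least one informative feature")
    if min(spec.n_redundant, spec.n_noise) < 0 or spec.n_classes < 2:
        raise ValueError("infeasible synthetic spec")
    rng = np.random.default_rng(spec.seed)

    sizes = _class_sizes(spec)
    labels = np.repeat(np.arange(spec.n_classes), sizes)
    n = labels.size

    # per-column class means: permuted equally spaced levels over the span
    levels = np.linspace(-0.5, 0.5, spec.n_classes) * spec.class_separation
    means = np.column_stack([rng.permutation(levels) for _ in range(spec.n_informative)])
    informative = means[labels] + rng.standard_normal((n, spec.n_informative))

    mix = rng.standard_normal((spec.n_informative, spec.n_redundant))
    mix /= np.linalg.norm(mix, axis=0, keepdims=True)
    redundant = informative @ mix + 0.1 * rng.standard_normal((n, spec.n_redundant))

    noise = rng.standard_normal((n, spec.n_noise))

    values = np.hstack([informative, redundant, noise])
    perm = rng.permutation(spec.n_features)
    values = values[:, perm]
    inv = np.argsort(perm)
    truth = {
        "informative": np.sort(inv[: spec.n_informative]),
        "redundant": np.sort(inv[spec.n_informative: spec.n_informative + spec.n_redundant]),
        "noise": np.sort(inv[spec.n_informative + spec.n_redundant:]),
    }
    names = [f"f{i}" for i in range(spec.n_features)]
    fm = FeatureMatrix(values, labels, names, source=f"synthetic(seed={spec.seed})")
    return fm, truth


def make_images(n: int, n_classes: int = 7, size: int = 64,
                contrast: float = 1.0, seed: int = 0,
                return_masks: bool = False):
    """Toy lesion images: textured background + class-coded ellipse.

    Each RGB image (``size x size x 3``, 0-255 scale) is a smoothed-noise
    background with one elliptical lesion whose colour offset, eccentricity
    and internal texture depend on the class label; ``contrast`` in [0, 1]
    scales every class-dependent term (0 leaves pure background).  Returns
    ``(images, labels)`` or ``(images, labels, masks)`` with the boolean
    lesion masks.
    """
    if size < 16:
        raise ValueError("size must be at least 16")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    if n < 1 or n_classes < 1:
        raise ValueError("need n >= 1 images and n_classes >= 1")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_classes
    labels = rng.permutation(labels)

    # one colour direction, eccentricity and texture frequency per class
    angles = 2 * np.pi * np.arange(n_classes) / n_classes
    colour_dirs = np.column_stack([
        np.cos(angles), np.sin(angles), np.cos(2 * angles)])
    colour_dirs /= np.linalg.norm(colour_dirs, axis=1, keepdims=True)
    eccentricities = np.linspace(1.0, 2.2, n_classes)
    texture_freq = np.linspace(2.0, 8.0, n_classes)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    images, masks = [], []
    for lab in labels:
        background = 120.0 + 25.0 * gaussian_filter(
            rng.standard_normal((size, size, 3)), sigma=(3, 3, 0))
        cy, cx = rng.uniform(0.35 * size, 0.65 * size, size=2)
        radius = rng.uniform(0.18, 0.26) * size
        theta = rng.uniform(0, np.pi)
        ecc = eccentricities[lab]
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask = (u / radius) ** 2 + (v / (radius / ecc)) ** 2 <= 1.0

        offset = contrast * 60.0 * colour_dirs[lab]
        texture = contrast * 15.0 * np.sin(
            texture_freq[lab] * 2 * np.pi * u / size)
        img = background.copy()
        img[mask] += offset[None, :] + texture[mask, None]
        images.append(np.clip(img, 0.0, 255.0))
        masks.append(mask)

    if return_masks:
        return images, labels, masks
    return images, labels
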