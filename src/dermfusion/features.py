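"""Feature matrices from images: CNN primitive operators, a deterministic
toy backbone, and an adapter contract for real pretrained backbones.

The full study extracts 1056-dimensional vectors from the global average
pool layer of a fine-tuned NasNet-Large; training such a backbone needs a
GPU and pretrained weights, so here the pretrained path is an adapter
(:class:`ExternalBackbone`) that accepts any ``images -> matrix`` callable
and validates its output, while :class:`ToyBackbone` provides a small,
fully deterministic feature extractor built from the same primitive
operators (valid convolution, ReLU, pooling) so the downstream selection /
fusion / classification stages are testable on any machine.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import FeatureMatrix
from .enhance import _as_channels, compute_amd

__all__ = [
    "conv2d_valid", "relu", "pool2d", "softmax",
    "ToyBackbone", "ExternalBackbone", "extract_features",
]


def conv2d_valid(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid-mode 2-D cross-correlation: z[i,j] = sum_ab k[a,b] x[i+a, j+b].

    Output dims are (H - n + 1, W - n + 1) for an n x n kernel; the kernel
    must fit inside the image.
    """
    img = np.asarray(image, dtype=float)
    ker = np.asarray(kernel, dtype=float)
    if img.ndim != 2 or ker.ndim != 2:
        raise ValueError("conv2d_valid expects 2-D image and kernel")
    kh, kw = ker.shape
    h, w = img.shape
    if kh > h or kw > w:
        raise ValueError("kernel larger than image")
    # sliding-window view keeps this O(HW k^2) without a Python quad loop
    windows = np.lib.stride_tricks.sliding_window_view(img, (kh, kw))
    return np.einsum("ijab,ab->ij", windows, ker)


def relu(values: np.ndarray) -> np.ndarray:
    """Elementwise max(0, z)."""
    return np.maximum(0.0, np.asarray(values, dtype=float))


def pool2d(values: np.ndarray, window: int, stride: int, mode: str = "max") -> np.ndarray:
    """Window pooling with output dims W2 = (W1 - G)/Z + 1 (and same for H).

    ``(W1 - G)`` and ``(H1 - G)`` must be exact multiples of the stride;
    modes are ``max``, ``average`` and ``min``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("pool2d expects a 2-D grid")
    h, w = x.shape
    g, z = int(window), int(stride)
    if g > h or g > w:
        raise ValueError("pooling window larger than input")
    if z < 1:
        raise ValueError("stride must be >= 1")
    if (h - g) % z or (w - g) % z:
        raise ValueError("(dim - window) must be an exact multiple of stride")
    h2, w2 = (h - g) // z + 1, (w - g) // z + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (g, g))[::z, ::z]
    if mode == "max":
        return windows.max(axis=(2, 3))
    if mode == "average":
        return windows.mean(axis=(2, 3))
    if mode == "min":
        return windows.min(axis=(2, 3))
    raise ValueError(f"unknown pooling mode {mode!r}")


def softmax(q: np.ndarray) -> np.ndarray:
    """Stable softmax: exp(x_i - max) / sum; positive components summing to 1."""
    v = np.asarray(q, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty vector")
    e = np.exp(v - v.max())
    return e / e.sum()


_BOX3 = np.full((3, 3), 1.0 / 9.0)  # fixed smoothing kernel of the toy path


class ToyBackbone(BaseEstimator, TransformerMixin):
    """Deterministic patch-statistics feature extractor.

    Each channel is smoothed with a 3x3 box kernel (valid convolution),
    rectified, average-pooled 2x2, then partitioned into a ``grid x grid``
    patch lattice; per patch the mean, standard deviation and absolute mean
    deviation are computed and concatenated.  Feature width is
    ``grid^2 * channels * 3``, bitwise reproducible for identical inputs.

    Parameters
    ----------
    grid : int, default 4
        Patches per side.
    pool_mode : {"average", "max", "min"}, default "average"
        Pooling mode applied after rectification.
    """

    def __init__(self, grid: int = 4, pool_mode: str = "average"):
        self.grid = grid
        self.pool_mode = pool_mode

    def fit(self, images, y=None):
        self.n_features_out_ = None  # set on first transform
        return self

    def _image_vector(self, image: np.ndarray) -> np.ndarray:
        img = _as_channels(image)
        feats = []
        for c in range(img.shape[2]):
            chan = conv2d_valid(img[:, :, c], _BOX3)
            chan = relu(chan)
            h, w = chan.shape
            if h >= 4 and w >= 4 and (h - 2) % 2 == 0 and (w - 2) % 2 == 0:
                chan = pool2d(chan, 2, 2, self.pool_mode)
            h, w = chan.shape
            g = self.grid
            if h < g or w < g:
                raise ValueError(f"image too small for a {g}x{g} patch grid")
            row_edges = np.linspace(0, h, g + 1).astype(int)
            col_edges = np.linspace(0, w, g + 1).astype(int)
            for i in range(g):
                for j in range(g):
                    patch = chan[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
                    m = patch.mean()
                    feats.extend((m, patch.std(), compute_amd(patch, m)))
        return np.asarray(feats)

    def transform(self, images) -> np.ndarray:
        rows = [self._image_vector(im) for im in images]
        out = np.vstack(rows)
        self.n_features_out_ = out.shape[1]
        return out


class ExternalBackbone(BaseEstimator, TransformerMixin):
    """Adapter for a pretrained CNN feature extractor.

    Wraps any callable mapping a list of images to an ``(n, d)`` matrix
    (e.g. global-average-pool activations of a fine-tuned network) and
    validates that every call returns a consistent width.

    Parameters
    ----------
    extract_fn : callable
        ``images -> (n_images, d) array``.
    layer : str, default "global_average_pool"
        Name of the extraction layer, recorded as provenance.
    expected_width : int or None
        If given, the returned width is validated against it (1056 for the
        NasNet-Large average-pool layer).
    """

    def __init__(self, extract_fn=None, layer: str = "global_average_pool",
                 expected_width: int | None = None):
        self.extract_fn = extract_fn
        self.layer = layer
        self.expected_width = expected_width

    def fit(self, images, y=None):
        return self

    def transform(self, images) -> np.ndarray:
        if self.extract_fn is None:
            raise ValueError("no extract_fn supplied to ExternalBackbone")
        out = np.asarray(self.extract_fn(images), dtype=float)
        if out.ndim != 2 or out.shape[0] != len(images):
            raise ValueError(
                f"backbone returned shape {out.shape} for {len(images)} images"
            )
        if self.expected_width is not None and out.shape[1] != self.expected_width:
            raise ValueError(
                f"backbone width {out.shape[1]} != expected {self.expected_width}"
            )
        if not np.all(np.isfinite(out)):
            raise ValueError("backbone returned non-finite features")
        return out


def extract_features(images, labels, backbone=None, source: str = "toy") -> FeatureMatrix:
    """Run a backbone over ``images`` and package the result.

    ``backbone`` defaults to a fresh :class:`ToyBackbone`; any fitted
    transformer with the same contract (``transform(images) -> matrix``)
    can be substituted.
    """
    if len(images) == 0:
        raise ValueError("empty image list")
    if len(images) != len(labels):
        raise ValueError("one label per image required")
    backbone = backbone if backbone is not None else ToyBackbone()
    values = backbone.fit(images).transform(images)
    return FeatureMatrix(values, np.asarray(labels), source=source)
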