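"""Watershed over-segmentation of the smoothed gradient magnitude.

Produces superpixels: connected catchment basins of the Sobel gradient
magnitude of the pre-processed image, summarized by their mean intensity,
area, and 4-neighbour adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional, Set, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from .core import Slice, as_slice

SOBEL_X = np.array([[-1, 0, 1],
                    [-2, 0, 2],
                    [-1, 0, 1]], dtype=np.float64)
SOBEL_Y = np.array([[-1, -2, -1],
                    [0, 0, 0],
                    [1, 2, 1]], dtype=np.float64)


@dataclass(frozen=True)
class GradientImage:
    """Non-negative gradient magnitude field."""

    magnitude: np.ndarray

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude, dtype=np.float64)
        if mag.ndim != 2:
            raise ValueError("gradient magnitude must be 2D")
        if not np.all(np.isfinite(mag)) or mag.min() < 0:
            raise ValueError("gradient magnitude must be finite and >= 0")
        object.__setattr__(self, "magnitude", mag)

    @property
    def source_shape(self) -> tuple:
        return self.magnitude.shape


@dataclass(frozen=True)
class GaussianParams:
    sigma: float = 1.0
    truncate: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class SuperpixelGraph:
    """Complete label partition with per-segment summaries.

    ``labels`` uses ids ``0..k-1`` with every pixel assigned;
    ``mean_intensity``/``area_px`` are arrays indexed by label; ``adjacency``
    holds unordered label pairs sharing a 4-neighbour pixel edge.
    """

    labels: np.ndarray
    mean_intensity: np.ndarray
    area_px: np.ndarray
    adjacency: FrozenSet[Tuple[int, int]]

    @property
    def n_segments(self) -> int:
        return len(self.area_px)

    def neighbors(self) -> Dict[int, Set[int]]:
        nbrs: Dict[int, Set[int]] = {i: set() for i in range(self.n_segments)}
        for a, b in self.adjacency:
            nbrs[a].add(b)
            nbrs[b].add(a)
        return nbrs


def sobel_gradient_magnitude(img) -> GradientImage:
    """Euclidean norm of the two Sobel convolution responses.

    True convolution (kernel flipped) with reflected borders.
    """
    s = as_slice(img)
    a = s.astype_float()
    dx = ndi.convolve(a, SOBEL_X, mode="reflect")
    dy = ndi.convolve(a, SOBEL_Y, mode="reflect")
    return GradientImage(np.hypot(dx, dy))


def gaussian_smooth(grad: GradientImage,
                    params: GaussianParams = GaussianParams()) -> GradientImage:
    """Normalized sampled-Gaussian smoothing; ``sigma == 0`` is the identity."""
    if params.sigma == 0:
        return grad
    sm = ndi.gaussian_filter(grad.magnitude, sigma=params.sigma,
                             truncate=params.truncate, mode="reflect")
    return GradientImage(np.maximum(sm, 0.0))


def watershed_partition(grad: GradientImage) -> np.ndarray:
    """Flooding watershed from all regional minima, 8-connected basins.

    Every pixel belongs to exactly one catchment basin; no watershed-line
    pixels are left unlabelled.  Returns labels ``0..k-1``.
    """
    labels = watershed(grad.magnitude, connectivity=2, watershed_line=False)
    return labels.astype(np.int64) - int(labels.min())


def label_adjacency(labels: np.ndarray) -> FrozenSet[Tuple[int, int]]:
    """Unordered pairs of labels sharing a horizontal/vertical pixel edge."""
    pairs: Set[Tuple[int, int]] = set()
    for a, b in ((labels[:, :-1], labels[:, 1:]),
                 (labels[:-1, :], labels[1:, :])):
        diff = a != b
        lo = np.minimum(a[diff], b[diff])
        hi = np.maximum(a[diff], b[diff])
        pairs.update(zip(lo.tolist(), hi.tolist()))
    return frozenset(pairs)


def summarize_superpixels(labels: np.ndarray, intensity) -> SuperpixelGraph:
    """Summarize a complete label partition over an intensity image."""
    intensity = as_slice(intensity)
    labels = np.asarray(labels)
    if labels.shape != intensity.shape:
        raise ValueError("label map and intensity image shapes differ")
    k = int(labels.max()) + 1
    flat = labels.ravel()
    area = np.bincount(flat, minlength=k)
    if np.any(area == 0):
        raise ValueError("labels must be contiguous 0..k-1 with no gaps")
    sums = np.bincount(flat, weights=intensity.astype_float().ravel(),
                       minlength=k)
    return SuperpixelGraph(labels=labels,
                           mean_intensity=sums / area,
                           area_px=area,
                           adjacency=label_adjacency(labels))
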