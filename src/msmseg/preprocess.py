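"""Pre-processing stage: plateauing, adaptive contrast, edge-preserving filtering.

The raw photon-count image is first flattened into contiguous plateaus with a
combined white/black top-hat transform, then contrast-stretched with a
contrast-limited adaptive histogram equalization (CLAHE), and finally
denoised with an 8-neighbour anisotropic (Perona--Malik style) diffusion that
smooths along, but not across, edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import Slice, as_slice, clip_to_uint8


@dataclass(frozen=True)
class StructuringElement:
    """Flat disk-shaped structuring element with its origin at the center."""

    mask: np.ndarray
    diameter_px: int


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the 8-neighbour anisotropic diffusion.

    ``K`` controls edge sensitivity of the diffusion coefficient
    ``1 / (1 + (delta/K)**2)``; ``lam`` weights the per-iteration update;
    ``iterations`` is the number of explicit time steps; ``eta`` is the
    neighbourhood size and is fixed to 8.
    """

    K: float = 15.0
    lam: float = 1.0
    iterations: int = 10
    eta: int = 8

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lam must lie in [0, 1]")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.eta != 8:
            raise ValueError("eta is fixed to 8")


def make_disk_se(diameter_px: int) -> StructuringElement:
    """Build a boolean Euclidean disk of the given odd diameter.

    A pixel belongs to the disk iff its Euclidean distance from the center
    is at most ``(diameter_px - 1) / 2``.
    """
    if diameter_px < 1 or diameter_px % 2 == 0:
        raise ValueError(f"diameter must be odd and >= 1, got {diameter_px}")
    r = (diameter_px - 1) // 2
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    mask = (xx * xx + yy * yy) <= r * r
    return StructuringElement(mask=mask, diameter_px=diameter_px)


def plateau_transform(img, se: StructuringElement) -> Slice:
    """Add white and black top-hats to the image (plateau formation).

    Computes ``I + (I - opening(I)) + (closing(I) - I)`` in a signed wide
    integer range and saturate-clips the result back to [0, 255].  Borders
    are reflected.
    """
    s = as_slice(img)
    a = s.pixels.astype(np.int32)
    opened = ndi.grey_opening(a, footprint=se.mask, mode="reflect")
    closed = ndi.grey_closing(a, footprint=se.mask, mode="reflect")
    # I + T_w + T_b == I + (I - I∘H) + (I·H - I) == I - opening + closing
    out = a + (a - opened) + (closed - a)
    return s.with_pixels(clip_to_uint8(out))


def _tile_mapping(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    """Clipped-histogram CDF mapping of one tile, as a 256-entry LUT."""
    hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
    npix = tile.size
    if clip_limit > 0 and np.isfinite(clip_limit):
        # clip at a multiple of the uniform bin height, then redistribute
        # the excess equally over all bins
        threshold = clip_limit * npix / 256.0
        excess = np.maximum(hist - threshold, 0.0).sum()
        hist = np.minimum(hist, threshold) + excess / 256.0
    cdf = np.cumsum(hist)
    return np.rint(255.0 * cdf / npix).astype(np.float64)


def clahe(img, tile_px: int = 16, clip_limit: float = 2.0) -> Slice:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into square tiles of ``tile_px`` pixels (the image
    is reflect-padded up to a multiple of the tile size); each tile's
    histogram is clipped at ``clip_limit`` times the uniform bin height
    before its CDF mapping is computed, and per-pixel output is the bilinear
    interpolation between the mappings of the four nearest tile centers.
    Pass ``clip_limit=np.inf`` to disable clipping.
    """
    if tile_px < 2:
        raise ValueError("tile_px must be >= 2")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    s = as_slice(img)
    h, w = s.shape
    gh = -(-h // tile_px)
    gw = -(-w // tile_px)
    padded = np.pad(s.pixels, ((0, gh * tile_px - h), (0, gw * tile_px - w)),
                    mode="reflect")

    maps = np.empty((gh, gw, 256), dtype=np.float64)
    for ti in range(gh):
        for tj in range(gw):
            tile = padded[ti * tile_px:(ti + 1) * tile_px,
                          tj * tile_px:(tj + 1) * tile_px]
            maps[ti, tj] = _tile_mapping(tile, clip_limit)

    # bilinear interpolation between tile-center mappings, clamped at borders
    yy = (np.arange(h) - (tile_px - 1) / 2.0) / tile_px
    xx = (np.arange(w) - (tile_px - 1) / 2.0) / tile_px
    y0 = np.clip(np.floor(yy).astype(int), 0, gh - 1)
    x0 = np.clip(np.floor(xx).astype(int), 0, gw - 1)
    y1 = np.clip(y0 + 1, 0, gh - 1)
    x1 = np.clip(x0 + 1, 0, gw - 1)
    fy = np.clip(yy - np.floor(yy), 0.0, 1.0)
    fx = np.clip(xx - np.floor(xx), 0.0, 1.0)
    fy[yy < 0] = 0.0
    fx[xx < 0] = 0.0

    vals = s.pixels.astype(int)
    m00 = maps[y0[:, None], x0[None, :], vals]
    m01 = maps[y0[:, None], x1[None, :], vals]
    m10 = maps[y1[:, None], x0[None, :], vals]
    m11 = maps[y1[:, None], x1[None, :], vals]
    fy2 = fy[:, None]
    fx2 = fx[None, :]
    out = ((1 - fy2) * ((1 - fx2) * m00 + fx2 * m01)
           + fy2 * ((1 - fx2) * m10 + fx2 * m11))
    return s.with_pixels(clip_to_uint8(out))


_OFFSETS = [(-1, 0), (1, 0), (0, -1), (0, 1),
            (-1, -1), (-1, 1), (1, -1), (1, 1)]


def _shift_reflect(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    padded = np.pad(arr, 1, mode="reflect")
    h, w = arr.shape
    return padded[1 + dy:1 + dy + h, 1 + dx:1 + dx + w]


def diffuse_float(arr: np.ndarray, params: DiffusionParams) -> np.ndarray:
    """Run the 8-neighbour diffusion on a float array without clipping."""
    out = np.asarray(arr, dtype=np.float64).copy()
    for _ in range(params.iterations):
        update = np.zeros_like(out)
        for dy, dx in _OFFSETS:
            diff = _shift_reflect(out, dy, dx) - out
            coeff = 1.0 / (1.0 + (diff / params.K) ** 2)
            update += coeff * diff
        out += (params.lam / 8.0) * update
    return out


def anisotropic_diffuse(img, params: DiffusionParams) -> Slice:
    """Edge-preserving smoothing by iterated 8-neighbour diffusion.

    Each directional diffusion coefficient is computed from the directional
    intensity difference of the current iterate; all 8 directions are
    weighted equally; borders are reflected.  Internal arithmetic is
    real-valued and the result is clipped to [0, 255] only at the end.
    """
    s = as_slice(img)
    out = diffuse_float(s.astype_float(), params)
    return s.with_pixels(clip_to_uint8(out))
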