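"""Core data types shared across the pipeline."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import tifffile

log = logging.getLogger("msmseg")

#: default lateral sampling step of the tomograph data, micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 0.39


@dataclass(frozen=True)
class Slice:
    """A single 2D 8-bit intensity image (grey value = photon count).

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W)
        Intensity values in ``[0, 255]``.
    pixel_size_um : float
        Lateral sampling step in micrometres.
    depth_um : float, optional
        Axial depth of the slice inside its stack, if known.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    depth_um: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"slice must be 2D, got shape {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(f"slice must be at least 3x3, got {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def with_pixels(self, pixels: np.ndarray) -> "Slice":
        """Return a copy of this slice carrying new pixel data."""
        return Slice(pixels=pixels, pixel_size_um=self.pixel_size_um,
                     depth_um=self.depth_um)


def as_slice(img, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
             depth_um: Optional[float] = None) -> Slice:
    """Coerce an array-like (or a Slice) to a :class:`Slice`."""
    if isinstance(img, Slice):
        return img
    return Slice(np.asarray(img), pixel_size_um=pixel_size_um, depth_um=depth_um)


def clip_to_uint8(arr: np.ndarray) -> np.ndarray:
    """Round and saturate-clip a real-valued array to the 8-bit range."""
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def read_slices(path) -> list:
    """Read a single- or multi-page grayscale TIFF into a list of Slices.

    16-bit input is accepted and linearly rescaled to 8 bit (with a
    warning); multi-channel input is rejected.
    """
    data = tifffile.imread(path)
    if data.ndim == 2:
        pages = [data]
    elif data.ndim == 3:
        pages = list(data)
    else:
        raise ValueError(f"unsupported TIFF layout with shape {data.shape}")
    out = []
    for page in pages:
        if page.ndim != 2:
            raise ValueError("multi-channel images are not supported")
        if page.dtype == np.uint8:
            out.append(Slice(page))
        elif page.dtype == np.uint16:
            warnings.warn("16-bit input rescaled linearly to 8 bit")
            hi = max(int(page.max()), 1)
            out.append(Slice((page.astype(np.float64) * 255.0 / hi)
                             .round().astype(np.uint8)))
        else:
            raise ValueError(f"unsupported pixel type {page.dtype}")
    return out


def write_label_map(path, labels: np.ndarray) -> None:
    """Write an integer label map as a single-page TIFF (16- or 32-bit)."""
    labels = np.asarray(labels)
    if labels.max() > 65535:
        tifffile.imwrite(path, labels.astype(np.uint32))
    else:
        tifffile.imwrite(path, labels.astype(np.uint16))


def write_image(path, img) -> None:
    if isinstance(img, Slice):
        img = img.pixels
    tifffile.imwrite(path, np.asarray(img))
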