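"""Seeded synthetic phantoms with pixel-exact ground truth.

Each phantom emulates the statistical structure of label-free two-photon
autofluorescence slices of epidermis: bright speckled cytoplasm rings, dark
near-circular nuclei, a dark granular intercellular matrix, a radial signal
drop toward the image edges, optional broken ("open") cell boundaries, and
additive Gaussian noise.  Depth series shrink cells and reduce contrast
slice by slice.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .core import Slice, clip_to_uint8
from .evaluation import CERTAIN, UNCERTAIN, GroundTruth, NoiseSpec, add_noise_and_psnr


@dataclass(frozen=True)
class PhantomSpec:
    shape_px: Tuple[int, int] = (512, 512)
    n_cells: int = 12
    cell_radius_px: Tuple[float, float] = (34.0, 40.0)
    nucleus_radius_fraction: Tuple[float, float] = (0.42, 0.47)
    matrix_mean: float = 60.0
    cytoplasm_mean: float = 200.0
    nucleus_mean: float = 30.0
    speckle_strength: float = 0.03
    matrix_granularity: float = 0.15
    shading_strength: float = 0.04
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    open_boundary_fraction: float = 0.0
    boundary_deform: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.nucleus_mean < self.cytoplasm_mean
                and self.matrix_mean < self.cytoplasm_mean):
            raise ValueError("cytoplasm must be brighter than nucleus and matrix")
        lo, hi = self.nucleus_radius_fraction
        if not (0 < lo <= hi < 1):
            raise ValueError("nucleus_radius_fraction must lie in (0, 1)")
        for v in (self.matrix_mean, self.cytoplasm_mean, self.nucleus_mean):
            if not (0 <= v <= 255):
                raise ValueError("intensity means must lie in [0, 255]")
        if not (0.0 <= self.open_boundary_fraction <= 1.0):
            raise ValueError("open_boundary_fraction must lie in [0, 1]")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["shape_px"] = tuple(d["shape_px"])
        d["cell_radius_px"] = tuple(d["cell_radius_px"])
        d["nucleus_radius_fraction"] = tuple(d["nucleus_radius_fraction"])
        d["noise"] = NoiseSpec(**d["noise"])
        return cls(**d)


def _smooth_field(rng: np.random.Generator, shape, scale_px: float) -> np.ndarray:
    """Zero-mean, unit-std smooth Gaussian random field."""
    field = rng.standard_normal(shape)
    field = ndi.gaussian_filter(field, sigma=scale_px, mode="reflect")
    std = field.std()
    return field / std if std > 0 else field


def _place_cells(rng: np.random.Generator, spec: PhantomSpec):
    h, w = spec.shape_px
    r_lo, r_hi = spec.cell_radius_px
    margin = 6.0
    centers: List[Tuple[float, float]] = []
    radii: List[float] = []
    attempts = 0
    while len(centers) < spec.n_cells:
        attempts += 1
        if attempts > 4000 * spec.n_cells:
            raise ValueError(
                f"infeasible packing: placed {len(centers)} of "
                f"{spec.n_cells} cells with radii {spec.cell_radius_px} "
                f"in a {h}x{w} image")
        r = rng.uniform(r_lo, r_hi)
        cy = rng.uniform(r + margin, h - r - margin)
        cx = rng.uniform(r + margin, w - r - margin)
        if all((cy - oy) ** 2 + (cx - ox) ** 2 >= (r + orad + margin) ** 2
               for (oy, ox), orad in zip(centers, radii)):
            centers.append((cy, cx))
            radii.append(r)
    return centers, radii


def _cell_masks(rng, spec, cy, cx, r):
    """Deformed-ellipse cell mask and interior circular nucleus mask."""
    h, w = spec.shape_px
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    aspect = rng.uniform(0.75, 1.0)
    rot = rng.uniform(0, np.pi)
    u = np.cos(rot) * dx + np.sin(rot) * dy
    v = -np.sin(rot) * dx + np.cos(rot) * dy
    rho = np.hypot(u / 1.0, v / aspect)
    k1, k2 = rng.integers(2, 5), rng.integers(5, 8)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    deform = 1.0 + spec.boundary_deform * (
        0.7 * np.sin(k1 * theta + p1) + 0.3 * np.sin(k2 * theta + p2))
    cell = rho <= r * deform
    f = rng.uniform(*spec.nucleus_radius_fraction)
    nucleus = (dy ** 2 + dx ** 2) <= (f * r * aspect * 0.95) ** 2
    return cell, nucleus & cell


def generate_phantom(spec: PhantomSpec) -> Tuple[Slice, GroundTruth]:
    """Render a phantom slice and its ground truth, fully seed-determined."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_px
    centers, radii = _place_cells(rng, spec)

    cell_labels = np.zeros((h, w), dtype=np.int32)
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    certainty = {}
    n_open = int(round(spec.open_boundary_fraction * spec.n_cells))
    open_ids = set(rng.choice(np.arange(1, spec.n_cells + 1), size=n_open,
                              replace=False).tolist()) if n_open else set()

    img = spec.matrix_mean * (
        1.0 + spec.matrix_granularity * _smooth_field(rng, (h, w), 1.5))

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    for obj, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        cell, nucleus = _cell_masks(rng, spec, cy, cx, r)
        if obj in open_ids:
            # carve an angular wedge out of the cytoplasm so the nucleus
            # touches the matrix; the wedge reverts to matrix intensity
            theta = np.arctan2(yy - cy, xx - cx)
            t0 = rng.uniform(-np.pi, np.pi)
            width = rng.uniform(0.5, 0.9)
            dtheta = np.angle(np.exp(1j * (theta - t0)))
            wedge = (np.abs(dtheta) <= width / 2) & cell & ~nucleus
            cell = cell & ~wedge
            certainty[obj] = UNCERTAIN
        else:
            certainty[obj] = CERTAIN
        cell_labels[cell] = obj
        nucleus_labels[nucleus] = obj
        speckle = 1.0 + spec.speckle_strength * _smooth_field(
            rng, (h, w), 2.0)
        cyto = cell & (nucleus_labels != obj)
        img[cyto] = (spec.cytoplasm_mean * speckle)[cyto]
        img[nucleus] = spec.nucleus_mean * (
            1.0 + 0.03 * _smooth_field(rng, (h, w), 2.0))[nucleus]

    # radial cosine-squared shading toward image border
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    rad = np.hypot(yy - cy0, xx - cx0) / np.hypot(cy0, cx0)
    img *= (1.0 - spec.shading_strength) + spec.shading_strength * (
        np.cos(0.5 * np.pi * rad) ** 2)

    slc = Slice(clip_to_uint8(img))
    if spec.noise.sigma > 0:
        slc, _ = add_noise_and_psnr(slc, spec.noise)
    gt = GroundTruth(nucleus_labels=nucleus_labels, cell_labels=cell_labels,
                     certainty=certainty)
    return slc, gt


def depth_series(base_spec: PhantomSpec, n_slices: int,
                 size_decay: float,
                 contrast_decay: float = 0.0) -> List[Tuple[Slice, GroundTruth]]:
    """Generate a depth series with shrinking cells and fading contrast.

    Cell radii scale by ``size_decay`` per slice; nucleus/cytoplasm and
    matrix/cytoplasm contrasts shrink linearly by ``contrast_decay`` per
    slice.  Stops with an error if radii would fall below 3 px.
    """
    if not (0.0 < size_decay <= 1.0):
        raise ValueError("size_decay must lie in (0, 1]")
    out = []
    for i in range(n_slices):
        scale = size_decay ** i
        r_lo, r_hi = base_spec.cell_radius_px
        if r_lo * scale < 3.0:
            raise ValueError(
                f"cell radius fell below 3 px at slice {i} "
                f"(scale {scale:.3f}); shorten the series or weaken the decay")
        shrink = max(0.0, 1.0 - contrast_decay * i)
        cyto = base_spec.matrix_mean + (
            base_spec.cytoplasm_mean - base_spec.matrix_mean) * shrink
        nuc = cyto - (base_spec.cytoplasm_mean - base_spec.nucleus_mean) * shrink
        spec_i = replace(base_spec,
                         cell_radius_px=(r_lo * scale, r_hi * scale),
                         cytoplasm_mean=float(cyto),
                         nucleus_mean=float(max(0.0, nuc)),
                         seed=base_spec.seed + i,
                         noise=replace(base_spec.noise,
                                       seed=base_spec.noise.seed + i))
        out.append(generate_phantom(spec_i))
    return out
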