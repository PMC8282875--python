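"""Semantic assignment: from merged segments to nucleus/cytoplasm/matrix.

Reconstructs the enclosure hierarchy of the final segment map, iteratively
labels every segment as potential nucleus or potential cell via the
outer-cell/inner-nucleus (OCIN) sign relation, computes the four segment
features (stability, contour gradient, compactness, hierarchy index), scores
nucleus candidates by the 2-norm distance of their normalized feature vector
to the ideal-nucleus reference, thresholds the scores scene-relatively, and
emits the final class map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import perimeter as _pixel_perimeter
from skimage.measure import perimeter_crofton as _crofton_perimeter

from .core import Slice, as_slice
from .oversegmentation import label_adjacency

log = logging.getLogger("msmseg")

NUCLEUS_CANDIDATE = "nucleus-candidate"
CELL_CANDIDATE = "cell-candidate"


@dataclass(frozen=True)
class SegmentHierarchy:
    """Full-enclosure parent/child relations between segments."""

    nodes: FrozenSet[int]
    parent_of: Dict[int, int]
    residual: FrozenSet[int]


@dataclass(frozen=True)
class SegmentFeatures:
    label: int
    S: float
    grad: float
    C: float
    H: int
    ocin_class: str


@dataclass(frozen=True)
class QualityScore:
    label: int
    d: float
    selected: bool = False


@dataclass(frozen=True)
class ClassMap:
    """Per-pixel class (0 matrix, 1 cytoplasm, 2 nucleus) plus object ids."""

    classes: np.ndarray
    nucleus_labels: Tuple[int, ...]
    cytoplasm_of: Dict[int, Tuple[int, ...]]

    MATRIX = 0
    CYTOPLASM = 1
    NUCLEUS = 2


def _boundary_lengths(labels: np.ndarray) -> Dict[Tuple[int, int], int]:
    """Number of 4-neighbour pixel edges between each pair of labels."""
    out: Dict[Tuple[int, int], int] = {}
    for a, b in ((labels[:, :-1], labels[:, 1:]),
                 (labels[:-1, :], labels[1:, :])):
        diff = a != b
        lo = np.minimum(a[diff], b[diff]).tolist()
        hi = np.maximum(a[diff], b[diff]).tolist()
        for pair in zip(lo, hi):
            out[pair] = out.get(pair, 0) + 1
    return out


def _border_labels(labels: np.ndarray) -> Set[int]:
    return set(np.concatenate([labels[0], labels[-1],
                               labels[:, 0], labels[:, -1]]).tolist())


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def build_enclosure_hierarchy(final_labels: np.ndarray) -> SegmentHierarchy:
    """Record a parent for every segment fully enclosed by a single other.

    Enclosure is judged on the segment's outer boundary: the segment mask is
    hole-filled, and the segment is a child of ``p`` iff every 4-neighbour
    pixel outside the filled mask carries the single label ``p`` (so a ring
    is a child of its surround regardless of what sits in its hole).
    Segments touching the image border are never children; everything
    without a parent goes to the residual.
    """
    labels = np.asarray(final_labels)
    border = _border_labels(labels)
    nodes = set(np.unique(labels).tolist())
    parent_of: Dict[int, int] = {}
    slices = ndi.find_objects(labels + 1)
    for seg in nodes:
        if seg in border:
            continue
        slc = slices[seg]
        # pad the crop so dilation can reach the outer boundary
        y0, y1 = slc[0].start, slc[0].stop
        x0, x1 = slc[1].start, slc[1].stop
        wider = (slice(max(y0 - 1, 0), min(y1 + 1, labels.shape[0])),
                 slice(max(x0 - 1, 0), min(x1 + 1, labels.shape[1])))
        crop = labels[wider]
        mask = crop == seg
        filled = ndi.binary_fill_holes(mask)
        outside = ndi.binary_dilation(filled, structure=_CROSS) & ~filled
        outer = set(np.unique(crop[outside]).tolist()) - {seg}
        if len(outer) == 1:
            parent_of[seg] = int(next(iter(outer)))
    residual = nodes - set(parent_of)
    return SegmentHierarchy(nodes=frozenset(nodes), parent_of=dict(parent_of),
                            residual=frozenset(residual))


def _sign_sum(child: int, counterparts: Iterable[int],
              means: np.ndarray,
              lengths: Dict[Tuple[int, int], int],
              raw_sums: Optional[Dict[Tuple[int, int], float]] = None) -> float:
    """Boundary sum of (inner - outer) intensities against the counterparts.

    In segment-mean mode each boundary pixel pair contributes the difference
    of the two segment means, so the sum is boundary-length weighted.
    """
    total = 0.0
    for other in counterparts:
        pair = (min(child, other), max(child, other))
        m = lengths.get(pair, 0)
        if m == 0:
            continue
        if raw_sums is not None:
            s = raw_sums[pair]
            total += s if child < other else -s
        else:
            total += m * (means[child] - means[other])
    return total


def _raw_boundary_sums(labels: np.ndarray,
                       intensity: np.ndarray) -> Dict[Tuple[int, int], float]:
    """Sum of (I_lo_side - I_hi_side) over boundary pixel pairs, keyed (lo, hi)."""
    out: Dict[Tuple[int, int], float] = {}
    inten = np.asarray(intensity, dtype=np.float64)
    for a, b, ia, ib in ((labels[:, :-1], labels[:, 1:],
                          inten[:, :-1], inten[:, 1:]),
                         (labels[:-1, :], labels[1:, :],
                          inten[:-1, :], inten[1:, :])):
        diff = a != b
        lo = np.minimum(a[diff], b[diff])
        hi = np.maximum(a[diff], b[diff])
        sign = np.where(a[diff] < b[diff], 1.0, -1.0)
        val = sign * (ia[diff] - ib[diff])
        for pair, v in zip(zip(lo.tolist(), hi.tolist()), val.tolist()):
            out[pair] = out.get(pair, 0.0) + v
    return out


def ocin_assign(final_labels: np.ndarray,
                means: np.ndarray,
                hierarchy: Optional[SegmentHierarchy] = None,
                boundary_mode: str = "segment-mean",
                intensity: Optional[np.ndarray] = None,
                max_iter: int = 64) -> Dict[int, Tuple[str, int]]:
    """Iterative OCIN labelling; returns {label: (ocin_class, H)}.

    Iteration 1 labels every fully enclosed child by the sign of the
    boundary sum of inner-minus-outer intensities (negative -> nucleus
    candidate).  In later iterations a residual segment qualifies when
    exactly one of its adjacent segments is still unlabelled; the sign is
    evaluated against that pseudo-parent alone, with labels frozen at
    iteration start.  Positive signs become cell candidates; negative signs
    become nucleus candidates unless two negatively signed qualifiers are
    adjacent, in which case both stay residual.  A stalled iteration falls
    back to the sign of (own mean - area-weighted neighbour mean).
    """
    labels = np.asarray(final_labels)
    if hierarchy is None:
        hierarchy = build_enclosure_hierarchy(labels)
    lengths = _boundary_lengths(labels)
    raw_sums = None
    if boundary_mode == "raw-pixel":
        if intensity is None:
            raise ValueError("raw-pixel mode needs the intensity image")
        raw_sums = _raw_boundary_sums(labels, intensity)
    elif boundary_mode != "segment-mean":
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")

    nbrs: Dict[int, Set[int]] = {n: set() for n in hierarchy.nodes}
    for (a, b) in lengths:
        nbrs[a].add(b)
        nbrs[b].add(a)

    assigned: Dict[int, Tuple[str, int]] = {}
    # iteration 1: fully enclosed children
    for child, parent in hierarchy.parent_of.items():
        sign = _sign_sum(child, [parent], means, lengths, raw_sums)
        cls = NUCLEUS_CANDIDATE if sign < 0 else CELL_CANDIDATE
        assigned[child] = (cls, 1)

    residual = set(hierarchy.nodes) - set(assigned)
    iteration = 1
    while residual and iteration < max_iter:
        iteration += 1
        frozen = set(assigned)
        candidates: Dict[int, Tuple[float, int]] = {}
        for seg in residual:
            unlabelled = [n for n in nbrs[seg] if n not in frozen]
            if len(unlabelled) == 1:
                pseudo = unlabelled[0]
                candidates[seg] = (
                    _sign_sum(seg, [pseudo], means, lengths, raw_sums), pseudo)
        newly: Dict[int, str] = {}
        negatives = {s for s, (v, _) in candidates.items() if v < 0}
        for seg, (value, _pseudo) in candidates.items():
            if value >= 0:
                newly[seg] = CELL_CANDIDATE
            elif not (negatives & nbrs[seg]):
                newly[seg] = NUCLEUS_CANDIDATE
            # adjacent negative signs stay residual
        if not newly:
            log.warning("OCIN iteration %d stalled with %d residual segments;"
                        " applying neighbour-mean fallback",
                        iteration, len(residual))
            area = np.bincount(labels.ravel(),
                               minlength=int(labels.max()) + 1)
            for seg in residual:
                neigh = list(nbrs[seg])
                if neigh:
                    w = area[neigh].astype(float)
                    nb_mean = float(np.average(means[neigh], weights=w))
                else:
                    nb_mean = float(means[seg])
                cls = (NUCLEUS_CANDIDATE if means[seg] - nb_mean < 0
                       else CELL_CANDIDATE)
                assigned[seg] = (cls, iteration)
            residual = set()
            break
        for seg, cls in newly.items():
            assigned[seg] = (cls, iteration)
        residual -= set(newly)
    if residual:
        raise RuntimeError("OCIN labelling failed to terminate")
    return assigned


def compactness(segment_mask: np.ndarray, method: str = "crofton") -> float:
    """Isoperimetric ratio P^2 / (4 pi A); 1 for a circle."""
    mask = np.asarray(segment_mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty segment mask")
    if method == "crofton":
        p = float(_crofton_perimeter(mask, directions=4))
    elif method == "pixel-count":
        p = float(_pixel_perimeter(mask, neighborhood=4))
    else:
        raise ValueError(f"unknown perimeter method {method!r}")
    return p * p / (4.0 * np.pi * area)


def _inner_contour(mask: np.ndarray) -> np.ndarray:
    eroded = ndi.binary_erosion(mask, structure=np.array([[0, 1, 0],
                                                          [1, 1, 1],
                                                          [0, 1, 0]], bool),
                                border_value=0)
    return mask & ~eroded


def contour_gradient(segment_mask: np.ndarray, img) -> float:
    """Mean central-difference gradient magnitude along the inner contour."""
    mask = np.asarray(segment_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty segment mask")
    s = as_slice(img)
    if mask.shape != s.shape:
        raise ValueError("mask and image shapes differ")
    gy, gx = np.gradient(s.astype_float())
    mag = np.hypot(gx, gy)
    return float(mag[_inner_contour(mask)].mean())


def compute_segment_features(final_labels: np.ndarray,
                             stability_seg: np.ndarray,
                             intensity,
                             ocin: Dict[int, Tuple[str, int]],
                             perimeter: str = "crofton") -> List[SegmentFeatures]:
    """Assemble the per-segment feature records for all segments."""
    labels = np.asarray(final_labels)
    s = as_slice(intensity)
    gy, gx = np.gradient(s.astype_float())
    mag = np.hypot(gx, gy)
    feats: List[SegmentFeatures] = []
    objects = ndi.find_objects(labels + 1)  # include label 0
    for lab, slc in enumerate(objects):
        if slc is None:
            continue
        mask = labels[slc] == lab
        contour = _inner_contour(mask)
        grad = float(mag[slc][contour].mean()) if contour.any() else 0.0
        cls, h = ocin[lab]
        feats.append(SegmentFeatures(
            label=lab,
            S=float(stability_seg[lab]),
            grad=grad,
            C=compactness(mask, method=perimeter),
            H=int(h),
            ocin_class=cls,
        ))
    return feats


def quality_scores(features: Sequence[SegmentFeatures],
                   msm_max: float, i_max: float,
                   ocin_max: Optional[int] = None) -> List[QualityScore]:
    """2-norm distance of each nucleus candidate to the ideal reference.

    The normalized feature vector is
    ``(S/MSM_max, grad/I_max, (C_max+1-C)/C_max, (OCIN_max+1-H)/OCIN_max)``
    and the reference is all ones; only nucleus candidates are scored.
    ``C_max`` is the scene maximum over the scored candidates; ``ocin_max``
    defaults to the candidates' maximum hierarchy index.
    """
    if msm_max <= 0 or i_max <= 0:
        raise ValueError("msm_max and i_max must be positive")
    cands = [f for f in features if f.ocin_class == NUCLEUS_CANDIDATE]
    if not cands:
        return []
    c_max = max(f.C for f in cands)
    h_max = ocin_max if ocin_max is not None else max(f.H for f in cands)
    ones = np.ones(4)
    scores = []
    for f in cands:
        v = np.array([f.S / msm_max,
                      f.grad / i_max,
                      (c_max + 1.0 - f.C) / c_max,
                      (h_max + 1.0 - f.H) / h_max])
        scores.append(QualityScore(label=f.label,
                                   d=float(np.linalg.norm(v - ones))))
    return scores


def select_nuclei(scores: Sequence[QualityScore],
                  t_qual: float) -> List[QualityScore]:
    """Scene-relative selection: keep d strictly below
    ``(max(d) - min(d)) * (1 - t_qual) + min(d)``."""
    if not (0.0 <= t_qual <= 1.0):
        raise ValueError("t_qual must lie in [0, 1]")
    if not scores:
        return []
    d = np.array([sc.d for sc in scores])
    threshold = (d.max() - d.min()) * (1.0 - t_qual) + d.min()
    return [QualityScore(label=sc.label, d=sc.d, selected=sc.d < threshold)
            for sc in scores]


def assign_classes(final_labels: np.ndarray,
                   selected: Iterable[int],
                   ocin: Dict[int, Tuple[str, int]],
                   adjacency: Optional[FrozenSet[Tuple[int, int]]] = None,
                   background_label: Optional[int] = None) -> ClassMap:
    """Selected segments become nuclei; adjacent cell candidates become their
    cytoplasm; everything else is intercellular matrix.

    ``background_label`` (the residual background of the multi-stage merge)
    is never promoted to cytoplasm.
    """
    labels = np.asarray(final_labels)
    if adjacency is None:
        adjacency = label_adjacency(labels)
    selected = set(int(s) for s in selected)
    nbrs: Dict[int, Set[int]] = {}
    for a, b in adjacency:
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)

    cyto_of: Dict[int, Tuple[int, ...]] = {}
    cyto_set: Set[int] = set()
    for nuc in sorted(selected):
        partners = tuple(sorted(
            n for n in nbrs.get(nuc, set())
            if n not in selected and n != background_label
            and ocin[n][0] == CELL_CANDIDATE))
        cyto_of[nuc] = partners
        cyto_set.update(partners)

    n_seg = int(labels.max()) + 1
    lut = np.full(n_seg, ClassMap.MATRIX, dtype=np.uint8)
    lut[list(cyto_set)] = ClassMap.CYTOPLASM
    lut[list(selected)] = ClassMap.NUCLEUS
    return ClassMap(classes=lut[labels],
                    nucleus_labels=tuple(sorted(selected)),
                    cytoplasm_of=cyto_of)
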