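"""Multi-stage merging of watershed superpixels.

A flooding process merges adjacent superpixels whose mean-intensity
difference stays below a threshold; running it at a ladder of thresholds and
logically combining the per-stage object masks yields the final segment map,
in which high-contrast objects are locked in first and lower-contrast
objects may only appear in still-unclaimed background.  A per-pixel
stability index counts in how many stage conjunctions a pixel persists as
foreground.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .oversegmentation import SuperpixelGraph

#: 8-connectivity structure used for object connected components
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MergeThresholdLadder:
    """Strictly increasing merge thresholds; default 10*i for i=1..7."""

    thresholds: Tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70)

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if len(t) == 0:
            raise ValueError("ladder must contain at least one threshold")
        if any(x <= 0 for x in t):
            raise ValueError("thresholds must be positive")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", t)

    @property
    def n(self) -> int:
        return len(self.thresholds)

    def processing_order(self, order: str = "desc") -> Tuple[float, ...]:
        """Thresholds in stage-processing order (high contrast first)."""
        if order == "desc":
            return tuple(sorted(self.thresholds, reverse=True))
        if order == "asc":
            return tuple(sorted(self.thresholds))
        raise ValueError(f"unknown order {order!r}")


@dataclass(frozen=True)
class MergedPartition:
    """Complete partition after one flooding merge at a single threshold."""

    labels: np.ndarray
    mean_intensity: np.ndarray
    area_px: np.ndarray
    background_label: int

    @property
    def n_segments(self) -> int:
        return len(self.area_px)


@dataclass(frozen=True)
class MultiStageResult:
    """Outcome of the logical stage combination.

    ``intermediates`` are the accumulated object-label maps, one per stage;
    ``final_labels`` uses 0 for the single residual background segment and
    1..M for object components; ``stability_px`` counts conjunction hits per
    pixel; ``stability_seg[label]`` is the per-segment aggregate.
    """

    intermediates: List[np.ndarray]
    final_labels: np.ndarray
    mean_intensity: np.ndarray
    stability_px: np.ndarray
    stability_seg: np.ndarray
    n_stages: int


def flood_merge(graph: SuperpixelGraph, t_m: float) -> MergedPartition:
    """Flooding-based merge of adjacent superpixels at threshold ``t_m``.

    A queue of regions ordered by current mean intensity (ascending, ties by
    lowest label) is processed: the lowest region absorbs, one at a time, the
    adjacent region with the smallest current-mean absolute difference, as
    long as that difference is at most ``t_m``.  Merged means are pixel-area-
    weighted; the process repeats until no adjacent pair qualifies.
    The background is the largest contiguous segment (ties: lowest mean).
    """
    if t_m < 0:
        raise ValueError("t_m must be >= 0")
    k = graph.n_segments
    parent = np.arange(k)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    mean = graph.mean_intensity.astype(np.float64).copy()
    area = graph.area_px.astype(np.int64).copy()
    nbrs = [set() for _ in range(k)]
    for a, b in graph.adjacency:
        nbrs[a].add(b)
        nbrs[b].add(a)

    # A popped region absorbs qualifying neighbours one at a time (smallest
    # current-mean difference first) and is re-queued after every merge; a
    # region with no qualifying neighbour goes dormant.  Dormant pairs can
    # only start qualifying when one side's mean changes, and every mean
    # change re-queues the changed region, so no qualifying pair is missed.
    heap = [(mean[i], i) for i in range(k)]
    heapq.heapify(heap)
    while heap:
        m, r = heapq.heappop(heap)
        if find(r) != r or mean[r] != m:
            continue  # stale entry
        best = None
        for nb in nbrs[r]:
            d = abs(mean[r] - mean[nb])
            if d <= t_m and (best is None or (d, nb) < best):
                best = (d, nb)
        if best is None:
            continue
        nb = best[1]
        root, other = (r, nb) if r < nb else (nb, r)
        parent[other] = root
        total = area[root] + area[other]
        mean[root] = (mean[root] * area[root] + mean[other] * area[other]) / total
        area[root] = total
        for x in nbrs[other]:
            nbrs[x].discard(other)
            if x != root:
                nbrs[x].add(root)
                nbrs[root].add(x)
        nbrs[root].discard(other)
        nbrs[other] = set()
        heapq.heappush(heap, (mean[root], root))

    roots = np.array([find(i) for i in range(k)])
    uniq = np.unique(roots)
    remap = np.zeros(k, dtype=np.int64)
    remap[uniq] = np.arange(len(uniq))
    new_of_sp = remap[roots]
    labels = new_of_sp[graph.labels]
    out_mean = mean[uniq]
    out_area = area[uniq]
    # background: maximal area, ties broken by lowest mean then lowest label
    order = np.lexsort((np.arange(len(uniq)), out_mean, -out_area))
    background = int(order[0])
    return MergedPartition(labels=labels, mean_intensity=out_mean,
                           area_px=out_area, background_label=background)


def object_mask(part: MergedPartition) -> np.ndarray:
    """Boolean mask of all non-background pixels."""
    return part.labels != part.background_label


def combine_stages(parts: Sequence[MergedPartition],
                   intensity: Optional[np.ndarray] = None) -> MultiStageResult:
    """Logical combination of per-stage object masks (processing order).

    Stage 1 objects are adopted verbatim.  At every later stage, each
    non-background segment of that stage is added only if it does not
    intersect the accumulated object mask; segments with any overlap are
    discarded whole, so previously extracted objects are never decomposed.
    The final map labels the adopted segments 1..M (keeping their per-stage
    identity) and the residual background as segment 0.
    """
    if not parts:
        raise ValueError("need at least one stage")
    shape = parts[0].labels.shape
    if any(p.labels.shape != shape for p in parts):
        raise ValueError("stage partitions must share one shape")

    # Accumulate the object mask stage by stage; pixels adopted at a stage
    # keep that stage's segment labels, so touching objects (e.g. a nucleus
    # inside its cytoplasm ring) stay distinct segments in the final map.
    acc = object_mask(parts[0]).copy()
    stage_of = np.full(shape, -1, dtype=np.int16)
    seg_of = np.zeros(shape, dtype=np.int64)
    stage_of[acc] = 0
    seg_of[acc] = parts[0].labels[acc]
    interm_masks = [acc.copy()]
    for idx, part in enumerate(parts[1:], start=1):
        # adopt every non-background stage segment that lies wholly in the
        # still-unclaimed background; segments with any overlap with the
        # accumulated objects are discarded whole, so earlier objects are
        # never decomposed or regrown
        keep = np.ones(part.n_segments, dtype=bool)
        keep[part.background_label] = False
        keep[np.unique(part.labels[acc])] = False
        new = keep[part.labels]
        if new.any():
            stage_of[new] = idx
            seg_of[new] = part.labels[new]
            acc |= new
        interm_masks.append(acc.copy())

    # relabel (stage, per-stage segment) pairs to 1..M; residual background
    # stays one segment with label 0
    max_seg = max(int(p.labels.max()) + 1 for p in parts)
    code = np.where(acc, (stage_of.astype(np.int64) + 1) * max_seg + seg_of, 0)
    uniq, final_labels = np.unique(code, return_inverse=True)
    final_labels = final_labels.reshape(shape).astype(np.int64)
    if uniq[0] != 0:  # no background pixel left: shift object ids up
        final_labels += 1
    n_obj = int(final_labels.max())

    if intensity is not None:
        intensity = np.asarray(intensity, dtype=np.float64)
        if intensity.shape != shape:
            raise ValueError("intensity shape mismatch")
        sums = np.bincount(final_labels.ravel(), weights=intensity.ravel(),
                           minlength=n_obj + 1)
        counts = np.bincount(final_labels.ravel(), minlength=n_obj + 1)
        mean_intensity = sums / np.maximum(counts, 1)
    else:
        mean_intensity = np.full(n_obj + 1, np.nan)

    intermediates = [ndi.label(m, structure=_STRUCT8)[0].astype(np.int64)
                     for m in interm_masks]
    stability_px, stability_seg = _stability(interm_masks, parts, final_labels,
                                             n_obj + 1)
    return MultiStageResult(intermediates=intermediates,
                            final_labels=final_labels,
                            mean_intensity=mean_intensity,
                            stability_px=stability_px,
                            stability_seg=stability_seg,
                            n_stages=len(parts))


def _stability(interm_masks, parts, final_labels, n_seg,
               aggregate: str = "mean"):
    n = len(parts)
    px = np.zeros(final_labels.shape, dtype=np.int32)
    for i in range(n - 1):
        px += (interm_masks[i] & object_mask(parts[i + 1])).astype(np.int32)
    if aggregate == "mean":
        sums = np.bincount(final_labels.ravel(), weights=px.ravel(),
                           minlength=n_seg)
        counts = np.bincount(final_labels.ravel(), minlength=n_seg)
        seg = sums / np.maximum(counts, 1)
    elif aggregate == "median":
        seg = ndi.labeled_comprehension(px, final_labels,
                                        np.arange(n_seg), np.median, float, 0.0)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return px, seg


def stability_map(result: MultiStageResult,
                  parts: Sequence[MergedPartition],
                  aggregate: str = "mean"):
    """Per-pixel stability count and per-segment aggregate.

    A pixel scores one point for every stage ``i`` in 1..n-1 where it is
    object both in the accumulated mask of stage ``i`` and in the flooded
    mask of stage ``i+1`` (processing order).
    """
    if len(parts) < 2:
        raise ValueError("stability needs at least two stages")
    interm_masks = [lab > 0 for lab in result.intermediates]
    n_seg = int(result.final_labels.max()) + 1
    return _stability(interm_masks, parts, result.final_labels, n_seg,
                      aggregate=aggregate)


def run_multistage(graph: SuperpixelGraph,
                   ladder: MergeThresholdLadder = MergeThresholdLadder(),
                   intensity: Optional[np.ndarray] = None,
                   order: str = "desc",
                   stability_aggregate: str = "mean"):
    """Run flooding merges at every threshold and combine the stages."""
    parts = [flood_merge(graph, t) for t in ladder.processing_order(order)]
    result = combine_stages(parts, intensity=intensity)
    if stability_aggregate != "mean":
        px, seg = stability_map(result, parts, aggregate=stability_aggregate)
        result = MultiStageResult(intermediates=result.intermediates,
                                  final_labels=result.final_labels,
                                  mean_intensity=result.mean_intensity,
                                  stability_px=px, stability_seg=seg,
                                  n_stages=result.n_stages)
    return result, parts
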