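"""Evaluation protocol: Dice, object matching, threshold sweep, registration,
and the Gaussian-noise robustness experiment."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Slice, as_slice

log = logging.getLogger("msmseg")

CERTAIN = "certain"
UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class GroundTruth:
    """Expert reference: nucleus and cell label maps plus per-object certainty."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    certainty: Dict[int, str]

    def __post_init__(self) -> None:
        for obj in self.object_ids():
            if obj not in self.certainty:
                raise ValueError(f"certainty missing for object {obj}")

    def object_ids(self) -> List[int]:
        ids = np.unique(self.nucleus_labels)
        return [int(i) for i in ids if i != 0]

    def certain_ids(self) -> List[int]:
        return [i for i in self.object_ids() if self.certainty[i] == CERTAIN]

    def uncertain_ids(self) -> List[int]:
        return [i for i in self.object_ids() if self.certainty[i] == UNCERTAIN]

    def nucleus_mask(self, include_uncertain: bool = True) -> np.ndarray:
        if include_uncertain:
            return self.nucleus_labels > 0
        keep = np.isin(self.nucleus_labels, self.certain_ids())
        return keep


@dataclass(frozen=True)
class NoiseSpec:
    mu: float = 0.0
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class EvalReport:
    tp: int = 0
    tp_uncertain: int = 0
    fp: int = 0
    fn: int = 0
    fn_uncertain: int = 0
    dice: float = float("nan")
    pixel_accuracy: float = float("nan")


def dice(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Pixelwise Dice coefficient 2TP/(2TP+FP+FN); both empty -> 1."""
    pred = np.asarray(pred_mask, dtype=bool)
    gt = np.asarray(gt_mask, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    if tp + fp + fn == 0:
        return 1.0  # convention: two empty masks are identical
    return 2.0 * tp / (2.0 * tp + fp + fn)


def _overlap_pairs(pred_labels: np.ndarray, gt_labels: np.ndarray):
    """(overlap, gt_id, pred_id) triples for all positively overlapping pairs."""
    pred = np.asarray(pred_labels)
    gt = np.asarray(gt_labels)
    both = (pred > 0) & (gt > 0)
    if not both.any():
        return []
    pairs, counts = np.unique(
        np.stack([gt[both], pred[both]]), axis=1, return_counts=True)
    return [(int(c), int(g), int(p))
            for (g, p), c in zip(pairs.T, counts)]


def match_nuclei(pred_labels: np.ndarray, gt: GroundTruth,
                 min_overlap_px: int = 1) -> EvalReport:
    """One-to-one greedy object matching by descending overlap area.

    Matched ground-truth objects count as TP (split by certainty), unmatched
    predictions as FP, unmatched ground-truth objects as FN (split by
    certainty).
    """
    pred = np.asarray(pred_labels)
    triples = [t for t in _overlap_pairs(pred, gt.nucleus_labels)
               if t[0] >= min_overlap_px]
    triples.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_gt: set = set()
    matched_pred: set = set()
    for _, g, p in triples:
        if g in matched_gt or p in matched_pred:
            continue
        matched_gt.add(g)
        matched_pred.add(p)

    report = EvalReport()
    for g in gt.object_ids():
        unc = gt.certainty[g] == UNCERTAIN
        if g in matched_gt:
            if unc:
                report.tp_uncertain += 1
            else:
                report.tp += 1
        else:
            if unc:
                report.fn_uncertain += 1
            else:
                report.fn += 1
    pred_ids = set(int(i) for i in np.unique(pred) if i != 0)
    report.fp = len(pred_ids - matched_pred)
    return report


def evaluate_masks(pred_mask: np.ndarray, gt: GroundTruth,
                   include_uncertain: bool = True) -> Tuple[float, float]:
    """Pixelwise Dice and accuracy of the binary nucleus decision."""
    gt_mask = gt.nucleus_mask(include_uncertain)
    dc = dice(pred_mask, gt_mask)
    acc = float(np.count_nonzero(np.asarray(pred_mask, bool) == gt_mask)
                / gt_mask.size)
    return dc, acc


def default_sweep_grid() -> np.ndarray:
    """21 equidistant relative quality thresholds 0.900..1.000."""
    return np.round(np.linspace(0.900, 1.000, 21), 3)


def threshold_sweep(slices: Sequence[Tuple[object, GroundTruth]],
                    grid: Optional[Sequence[float]] = None) -> Tuple[pd.DataFrame, dict]:
    """Aggregate object counts and Dice over a grid of quality thresholds.

    ``slices`` holds ``(scored, gt)`` pairs where ``scored`` exposes
    ``nucleus_mask_at(t)`` and ``nucleus_objects_at(t)`` (see
    :class:`msmseg.pipeline.SliceResult`).  Returns the per-threshold table
    and a summary with the argmax-Dice threshold (ties -> larger threshold),
    both with and without uncertain objects.
    """
    grid = default_sweep_grid() if grid is None else np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("threshold grid must be nonempty")
    rows = []
    for t in grid:
        agg = dict(threshold=float(t), tp=0, tp_uncertain=0, fp=0,
                   fn=0, fn_uncertain=0)
        tp_px_i = fp_px_i = fn_px_i = 0
        tp_px_e = fp_px_e = fn_px_e = 0
        for scored, gt in slices:
            rep = match_nuclei(scored.nucleus_objects_at(t), gt)
            for k in ("tp", "tp_uncertain", "fp", "fn", "fn_uncertain"):
                agg[k] += getattr(rep, k)
            pred = scored.nucleus_mask_at(t)
            for include, acc in ((True, "i"), (False, "e")):
                gtm = gt.nucleus_mask(include)
                tp_px = int(np.count_nonzero(pred & gtm))
                fp_px = int(np.count_nonzero(pred & ~gtm))
                fn_px = int(np.count_nonzero(~pred & gtm))
                if acc == "i":
                    tp_px_i += tp_px; fp_px_i += fp_px; fn_px_i += fn_px
                else:
                    tp_px_e += tp_px; fp_px_e += fp_px; fn_px_e += fn_px
        denom_i = 2 * tp_px_i + fp_px_i + fn_px_i
        denom_e = 2 * tp_px_e + fp_px_e + fn_px_e
        agg["dice"] = 2 * tp_px_i / denom_i if denom_i else 1.0
        agg["dice_certain_only"] = 2 * tp_px_e / denom_e if denom_e else 1.0
        rows.append(agg)
    table = pd.DataFrame(rows)

    def argmax(col: str) -> float:
        best = table[col].max()
        return float(table.loc[table[col] >= best, "threshold"].max())

    summary = {
        "best_threshold": argmax("dice"),
        "best_threshold_certain_only": argmax("dice_certain_only"),
        "best_dice": float(table["dice"].max()),
        "best_dice_certain_only": float(table["dice_certain_only"].max()),
    }
    return table, summary


def register_segments(pred_labels: np.ndarray, gt_labels: np.ndarray,
                      min_dc: float = 0.75) -> List[Tuple[int, int, float]]:
    """Match each ground-truth object to the prediction segment with maximal
    shared area; drop pairs whose pairwise Dice is below ``min_dc``.

    Returns (gt_id, pred_id, pairwise_dc) triples, ties by lowest pred id.
    """
    pred = np.asarray(pred_labels)
    gt = np.asarray(gt_labels)
    if pred.shape != gt.shape:
        raise ValueError("label map shapes differ")
    triples = _overlap_pairs(pred, gt)
    best: Dict[int, Tuple[int, int]] = {}
    for c, g, p in triples:
        cur = best.get(g)
        if cur is None or (-c, p) < (-cur[0], cur[1]):
            best[g] = (c, p)
    pred_area = np.bincount(pred.ravel())
    gt_area = np.bincount(gt.ravel())
    out = []
    for g, (c, p) in sorted(best.items()):
        dc = 2.0 * c / (pred_area[p] + gt_area[g])
        if dc >= min_dc:
            out.append((g, p, float(dc)))
    return out


def add_noise_and_psnr(img, spec: NoiseSpec) -> Tuple[Slice, float]:
    """Add seeded Gaussian noise (round + clip to [0,255]) and report PSNR.

    PSNR is ``10*log10(255^2 / MSE)`` against the input; a zero-MSE result
    is reported as ``inf``.
    """
    s = as_slice(img)
    rng = np.random.default_rng(spec.seed)
    noisy = s.astype_float() + rng.normal(spec.mu, spec.sigma, size=s.shape)
    noisy = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    mse = float(np.mean((noisy.astype(np.float64) - s.astype_float()) ** 2))
    psnr = float("inf") if mse == 0 else 10.0 * np.log10(255.0 ** 2 / mse)
    return s.with_pixels(noisy), psnr
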