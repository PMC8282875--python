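"""End-to-end per-slice pipeline and the two batch experiments."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import evaluation as ev
from . import merging as mg
from . import oversegmentation as ov
from . import preprocess as pp
from . import semantic_assignment as sa
from .config import PipelineConfig
from .core import Slice, as_slice
from .evaluation import GroundTruth, NoiseSpec

log = logging.getLogger("msmseg")


@dataclass
class SliceResult:
    """Everything the pipeline derives from one slice."""

    input_slice: Slice
    diffused: Slice
    graph: ov.SuperpixelGraph
    msm: mg.MultiStageResult
    features: List[sa.SegmentFeatures]
    scores: List[sa.QualityScore]
    class_map: sa.ClassMap
    ocin: Dict[int, Tuple[str, int]]
    config: PipelineConfig
    timings: Dict[str, float] = field(default_factory=dict)

    @property
    def nucleus_mask(self) -> np.ndarray:
        return self.class_map.classes == sa.ClassMap.NUCLEUS

    def selected_labels(self) -> List[int]:
        return [s.label for s in self.scores if s.selected]

    def _selection_at(self, t_qual: float) -> List[int]:
        sel = sa.select_nuclei(self.scores, t_qual)
        return [s.label for s in sel if s.selected]

    def nucleus_objects_at(self, t_qual: float) -> np.ndarray:
        """Label map of nuclei selected at an alternative quality threshold."""
        chosen = self._selection_at(t_qual)
        n_seg = int(self.msm.final_labels.max()) + 1
        lut = np.zeros(n_seg, dtype=np.int64)
        for i, lab in enumerate(sorted(chosen), start=1):
            lut[lab] = i
        return lut[self.msm.final_labels]

    def nucleus_mask_at(self, t_qual: float) -> np.ndarray:
        return self.nucleus_objects_at(t_qual) > 0

    def feature_table(self) -> pd.DataFrame:
        d_of = {s.label: s.d for s in self.scores}
        sel = set(self.selected_labels())
        centroids = ndi.center_of_mass(
            np.ones_like(self.msm.final_labels), self.msm.final_labels,
            [f.label for f in self.features])
        rows = []
        for f, (cy, cx) in zip(self.features, centroids):
            rows.append(dict(label=f.label, centroid_y=cy, centroid_x=cx,
                             area=int((self.msm.final_labels == f.label).sum()),
                             S=f.S, C=f.C, grad=f.grad, H=f.H,
                             ocin_class=f.ocin_class,
                             d=d_of.get(f.label, np.nan),
                             selected=f.label in sel))
        return pd.DataFrame(rows)


def preprocess_slice(img, config: PipelineConfig) -> Slice:
    """Plateauing, CLAHE and anisotropic diffusion in sequence."""
    c = config.preprocess
    se = pp.make_disk_se(c.tophat_diameter)
    plateaued = pp.plateau_transform(img, se)
    enhanced = pp.clahe(plateaued, tile_px=c.clahe_tile, clip_limit=c.clahe_clip)
    params = pp.DiffusionParams(K=c.diffusion.K, lam=c.diffusion.lam,
                                iterations=c.diffusion.iterations)
    return pp.anisotropic_diffuse(enhanced, params)


def run_slice(img, config: Optional[PipelineConfig] = None) -> SliceResult:
    """Full pipeline on a single slice (deterministic)."""
    config = config or PipelineConfig()
    s = as_slice(img)
    timings: Dict[str, float] = {}

    t0 = time.perf_counter()
    diffused = preprocess_slice(s, config)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    grad = ov.sobel_gradient_magnitude(diffused)
    grad = ov.gaussian_smooth(
        grad, ov.GaussianParams(sigma=config.oversegmentation.gaussian_sigma))
    ws_labels = ov.watershed_partition(grad)
    intensity = (diffused if config.oversegmentation.intensity_source
                 == "diffused" else s)
    graph = ov.summarize_superpixels(ws_labels, intensity)
    timings["oversegmentation"] = time.perf_counter() - t0
    log.info("watershed produced %d superpixels", graph.n_segments)

    t0 = time.perf_counter()
    ladder = mg.MergeThresholdLadder(tuple(config.merging.thresholds))
    msm, _parts = mg.run_multistage(
        graph, ladder, intensity=intensity.astype_float(),
        order=config.merging.order,
        stability_aggregate=config.merging.stability_aggregate)
    timings["multistage_merging"] = time.perf_counter() - t0
    n_final = int(msm.final_labels.max()) + 1
    log.info("multi-stage merging kept %d segments", n_final)

    t0 = time.perf_counter()
    hierarchy = sa.build_enclosure_hierarchy(msm.final_labels)
    ocin = sa.ocin_assign(msm.final_labels, msm.mean_intensity,
                          hierarchy=hierarchy,
                          boundary_mode=config.semantics.boundary_mode,
                          intensity=intensity.astype_float())
    features = sa.compute_segment_features(
        msm.final_labels, msm.stability_seg, diffused, ocin,
        perimeter=config.semantics.perimeter)
    # the residual background segment (label 0) is never a nucleus candidate
    candidates = [f for f in features if f.label != 0]
    ocin_max = max(h for _, h in ocin.values())
    scores = sa.quality_scores(candidates, msm_max=config.semantics.msm_max,
                               i_max=config.semantics.i_max,
                               ocin_max=ocin_max)
    scores = sa.select_nuclei(scores, config.semantics.tqual)
    class_map = sa.assign_classes(
        msm.final_labels, [sc.label for sc in scores if sc.selected], ocin,
        background_label=0)
    timings["semantic_assignment"] = time.perf_counter() - t0
    log.info("selected %d nuclei out of %d candidates",
             sum(sc.selected for sc in scores), len(scores))

    return SliceResult(input_slice=s, diffused=diffused, graph=graph, msm=msm,
                       features=features, scores=scores, class_map=class_map,
                       ocin=ocin, config=config, timings=timings)


def run_sweep(slices: Sequence, gts: Sequence[GroundTruth],
              config: Optional[PipelineConfig] = None,
              grid: Optional[Sequence[float]] = None):
    """Threshold sweep over several slices with ground truth.

    Returns (per-threshold table, summary dict).  The summary also carries
    the per-slice argmax thresholds and their median.
    """
    config = config or PipelineConfig()
    if len(slices) != len(gts):
        raise ValueError("need one ground truth per slice")
    if grid is None:
        e = config.evaluation
        grid = np.round(np.linspace(e.sweep_start, e.sweep_stop,
                                    e.sweep_points), 6)
    results = [run_slice(s, config) for s in slices]
    for res, gt in zip(results, gts):
        if res.msm.final_labels.shape != gt.nucleus_labels.shape:
            raise ValueError("slice and ground-truth shapes differ")
    table, summary = ev.threshold_sweep(list(zip(results, gts)), grid)

    per_slice = []
    for res, gt in zip(results, gts):
        t_i, s_i = ev.threshold_sweep([(res, gt)], grid)
        per_slice.append(s_i["best_threshold"])
    summary["per_slice_best_thresholds"] = per_slice
    summary["median_per_slice_best_threshold"] = float(np.median(per_slice))
    return table, summary


def run_noise_experiment(img, gt: GroundTruth,
                         sigmas: Sequence[float],
                         seeds: Sequence[int],
                         config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Segment noisy copies of one slice end-to-end at the configured
    quality threshold; one row per (sigma, seed)."""
    config = config or PipelineConfig()
    s = as_slice(img)
    rows = []
    for sigma in sigmas:
        for seed in seeds:
            noisy, psnr = ev.add_noise_and_psnr(
                s, NoiseSpec(mu=0.0, sigma=float(sigma), seed=int(seed)))
            res = run_slice(noisy, config)
            rep = ev.match_nuclei(res.nucleus_objects_at(config.semantics.tqual),
                                  gt, min_overlap_px=config.evaluation.min_overlap_px)
            dc, acc = ev.evaluate_masks(res.nucleus_mask, gt,
                                        include_uncertain=True)
            rows.append(dict(sigma=float(sigma), seed=int(seed), psnr=psnr,
                             tp=rep.tp + rep.tp_uncertain, fp=rep.fp,
                             fn=rep.fn + rep.fn_uncertain, dice=dc,
                             pixel_accuracy=acc))
            if float(sigma) == 0.0:
                break  # noiseless runs are seed-independent
    return pd.DataFrame(rows)
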