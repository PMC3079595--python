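"""Generalized pattern search and the two-stage supervised learning scheme.

GPS is a derivative-free optimizer: from the current iterate it probes mesh
points x +/- m * Delta * s_i * e_i along the coordinate axes — long jumps
(the search step) first, then the unit poll.  The first strictly better
point is accepted and the mesh size Delta kept; when nothing improves,
Delta is halved, and the search stops after a fixed number of refinements.
It needs no gradients, which matters here because the segmentation-quality
energy is a piecewise-constant function of the segmentation parameters.

Learning is staged as in the underlying visual model: first the grouping
parameters (k, smoothing, minimum region size) are fitted by minimizing the
partition energy E = e_bl + e_ov + e_un against expert partitions, then the
four feature weights are fitted, with the segmentation frozen, by minimizing
the foreground-background quality of the thresholded RoI against the expert
RoI mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .conspicuity import PyramidConfig, all_conspicuity_maps
from .quality import DistanceWeighting, fg_quality, mask_partition, total_energy
from .saliency import CHANNELS, combine_saliency, extract_rois, region_feature_index
from .segmentation import SegmentationParams, felzenszwalb_segment, segmentation_channel


@dataclass(frozen=True)
class GPSConfig:
    """Pattern-search controls.

    ``search_multipliers`` are the integer mesh multiples probed by the
    search step before the unit poll: candidate points x +/- m*Delta*s_i*e_i
    on the mesh M(x0, Delta).  Long jumps let the search cross plateaus of a
    piecewise-constant objective that unit polls cannot escape; set it to
    ``()`` for pure coordinate polling.
    """

    initial_mesh: float = 1.0
    scales: Optional[Tuple[float, ...]] = None
    max_refinements: int = 6
    search_multipliers: Tuple[int, ...] = (16, 4)

    def validate(self) -> None:
        if self.initial_mesh <= 0:
            raise ValueError("initial_mesh must be > 0")
        if self.max_refinements < 1:
            raise ValueError("max_refinements must be >= 1")
        if self.scales is not None and any(s <= 0 for s in self.scales):
            raise ValueError("scales must be > 0")
        if any(int(m) != m or m < 2 for m in self.search_multipliers):
            raise ValueError("search_multipliers must be integers >= 2")


@dataclass
class TrainingSample:
    """One supervised example: an image, its expert partition, and the RoI mask."""

    image: np.ndarray
    partition: List[np.ndarray]
    roi: np.ndarray


def make_training_samples(images: Sequence[np.ndarray],
                          rois: Sequence[np.ndarray]) -> List[TrainingSample]:
    """Build samples from images and binary RoI masks.

    The expert partition is derived from the mask: each 8-connected
    foreground component is one region, the background another.
    """
    if len(images) != len(rois):
        raise ValueError("images and masks differ in length")
    samples = []
    for img, roi in zip(images, rois):
        roi = np.asarray(roi).astype(bool)
        samples.append(TrainingSample(image=img, partition=mask_partition(roi),
                                      roi=roi))
    return samples


def pattern_search(f: Callable[[np.ndarray], float],
                   x0: Sequence[float],
                   bounds: Sequence[Tuple[float, float]],
                   cfg: GPSConfig | None = None,
                   ) -> Tuple[np.ndarray, float, List[Tuple[Tuple[float, ...], float]]]:
    """Minimize ``f`` over a box by mesh search plus coordinate polling.

    Each iteration first tries the search step (long mesh jumps of
    ``search_multipliers`` times the step, largest first), then the unit
    poll, coordinates in declared order with + before -; the first strictly
    better point is accepted and the mesh size kept.  When neither step
    improves, the mesh is halved; the search terminates after
    ``max_refinements`` halvings.  Non-finite objective values are treated
    as +inf (the point is rejected).  Returns ``(x_best, f_best, trace)``
    where the trace records every distinct evaluation.
    """
    cfg = cfg or GPSConfig()
    cfg.validate()
    x = np.asarray(x0, dtype=np.float64).copy()
    lo = np.array([b[0] for b in bounds], dtype=np.float64)
    hi = np.array([b[1] for b in bounds], dtype=np.float64)
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("x0 outside bounds")
    n = len(x)
    scales = np.ones(n) if cfg.scales is None else np.asarray(cfg.scales, dtype=np.float64)
    if len(scales) != n:
        raise ValueError("scales length must match dimension")

    trace: List[Tuple[Tuple[float, ...], float]] = []
    cache: Dict[Tuple[float, ...], float] = {}

    def evaluate(point: np.ndarray) -> float:
        key = tuple(np.round(point, 12))
        if key in cache:
            return cache[key]
        value = f(point)
        value = float(value) if np.isfinite(value) else np.inf
        cache[key] = value
        trace.append((key, value))
        return value

    def try_step(step_multiplier: float, delta: float):
        """First strictly improving candidate at the given step length, or None."""
        for i in range(n):
            for sign in (1.0, -1.0):
                cand = x.copy()
                cand[i] = np.clip(cand[i] + sign * step_multiplier * delta * scales[i],
                                  lo[i], hi[i])
                if cand[i] == x[i]:
                    continue
                fc = evaluate(cand)
                if fc < fx:
                    return cand, fc
        return None

    fx = evaluate(x)
    delta = cfg.initial_mesh
    refinements = 0
    while refinements < cfg.max_refinements:
        hit = None
        for m in (*cfg.search_multipliers, 1):
            hit = try_step(float(m), delta)
            if hit is not None:
                break
        if hit is not None:
            x, fx = hit
        else:
            delta /= 2.0
            refinements += 1
    return x, fx, trace


# Default search box and start of the two-stage learner.
SEG_BOUNDS = ((10.0, 5000.0), (0.0, 2.0), (1.0, 500.0))  # k, smooth_sigma, min_size
SEG_X0 = (500.0, 0.8, 20.0)
SEG_SCALES = (128.0, 0.4, 32.0)
WEIGHT_BOUNDS = ((0.0, 1.0),) * 4
WEIGHT_X0 = (0.25, 0.25, 0.25, 0.25)
WEIGHT_SCALES = (0.25, 0.25, 0.25, 0.25)


def _seg_params_from_vector(x: Sequence[float],
                            template: SegmentationParams) -> SegmentationParams:
    return replace(template, k=float(x[0]), smooth_sigma=float(x[1]),
                   min_size=int(round(x[2])))


def learn_segmentation_params(samples: Sequence[TrainingSample],
                              cfg: GPSConfig | None = None,
                              weighting: DistanceWeighting | None = None,
                              template: SegmentationParams | None = None,
                              x0: Sequence[float] = SEG_X0,
                              bounds: Sequence[Tuple[float, float]] = SEG_BOUNDS,
                              ) -> Tuple[SegmentationParams, list]:
    """Stage 1: fit (k, smooth_sigma, min_size) by minimizing the summed partition energy."""
    if not samples:
        raise ValueError("at least one training sample is required")
    cfg = cfg or GPSConfig(scales=SEG_SCALES)
    if cfg.scales is None:
        cfg = replace(cfg, scales=SEG_SCALES)
    weighting = weighting or DistanceWeighting()
    template = template or SegmentationParams()
    channels = [segmentation_channel(s.image, template.color_edges) for s in samples]
    cache: Dict[Tuple[float, float, int], float] = {}

    def objective(x: np.ndarray) -> float:
        params = _seg_params_from_vector(x, template)
        key = (round(params.k, 9), round(params.smooth_sigma, 9), params.min_size)
        if key in cache:
            return cache[key]
        energy = 0.0
        for ch, sample in zip(channels, samples):
            labels = felzenszwalb_segment(ch, params)
            energy += total_energy(sample.partition, labels, weighting).energy
        cache[key] = energy
        return energy

    x_best, _, trace = pattern_search(objective, x0, bounds, cfg)
    return _seg_params_from_vector(x_best, template), trace


def learn_feature_weights(samples: Sequence[TrainingSample],
                          seg_params: SegmentationParams,
                          cfg: GPSConfig | None = None,
                          weighting: DistanceWeighting | None = None,
                          pyramid: PyramidConfig | None = None,
                          entropy_window: int = 9,
                          entropy_bins: int = 32,
                          normalize_entropy: bool = False,
                          x0: Sequence[float] = WEIGHT_X0,
                          ) -> Tuple[Dict[str, float], list]:
    """Stage 2: fit the four feature weights with the segmentation frozen.

    The objective is the summed normalized foreground-background quality of
    the thresholded RoI against the expert RoI.  An all-zero weight vector is
    evaluated with uniform weights instead (the combination is undefined at
    the origin).  The returned weights are renormalized to sum one.
    """
    if not samples:
        raise ValueError("at least one training sample is required")
    cfg = cfg or GPSConfig(scales=WEIGHT_SCALES)
    if cfg.scales is None:
        cfg = replace(cfg, scales=WEIGHT_SCALES)
    weighting = weighting or DistanceWeighting()
    # Conspicuity maps and region structure do not depend on the weights:
    # compute the per-region feature indices once per image.
    index_rows: List[np.ndarray] = []
    label_maps: List[np.ndarray] = []
    for s in samples:
        labels = felzenszwalb_segment(
            segmentation_channel(s.image, seg_params.color_edges), seg_params)
        maps = all_conspicuity_maps(s.image, cfg=pyramid,
                                    entropy_window=entropy_window,
                                    entropy_bins=entropy_bins,
                                    normalize_entropy=normalize_entropy)
        indices = np.column_stack([region_feature_index(labels, maps[ch])
                                   for ch in CHANNELS])
        index_rows.append(indices)
        label_maps.append(labels)

    def objective(wvec: np.ndarray) -> float:
        w = wvec if wvec.sum() > 0 else np.full(4, 0.25)
        cost = 0.0
        for indices, labels, sample in zip(index_rows, label_maps, samples):
            saliency = combine_saliency(indices, w)
            mask = extract_rois(labels, saliency)
            cost += fg_quality(sample.roi, mask, weighting).normalized
        return cost

    x_best, _, trace = pattern_search(objective, x0, WEIGHT_BOUNDS, cfg)
    if x_best.sum() <= 0:
        x_best = np.full(4, 0.25)
    x_best = x_best / x_best.sum()
    return dict(zip(CHANNELS, (float(v) for v in x_best))), trace


def fold_assignments(n: int, n_folds: int, seed: int = 0) -> List[List[int]]:
    """Deterministic seeded partition of ``range(n)`` into ``n_folds`` test folds."""
    if n < n_folds:
        raise ValueError("fewer samples than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [sorted(order[i::n_folds].tolist()) for i in range(n_folds)]


def crossvalidate(images: Sequence[np.ndarray], rois: Sequence[np.ndarray],
                  n_folds: int = 11, seed: int = 0,
                  seg_cfg: GPSConfig | None = None,
                  weight_cfg: GPSConfig | None = None,
                  weighting: DistanceWeighting | None = None) -> pd.DataFrame:
    """K-fold cross-validation of the full two-stage learner.

    Fold assignment is a seeded permutation, so every sample is held out
    exactly once.  Each row reports the held-out fold's mean energy, dB
    quality and pixel sensitivity/specificity.
    """
    from .detector import RoiDetector
    from .evaluation import pixel_confusion

    n = len(images)
    if n != len(rois):
        raise ValueError("images and masks differ in length")
    if n < n_folds:
        raise ValueError("fewer samples than folds")
    weighting = weighting or DistanceWeighting()
    folds = fold_assignments(n, n_folds, seed)
    rows = []
    for fold_id, test_idx in enumerate(folds):
        train_idx = [i for i in range(n) if i not in test_idx]
        det = RoiDetector(seg_gps=seg_cfg, weight_gps=weight_cfg)
        det.fit([images[i] for i in train_idx], [rois[i] for i in train_idx])
        sens, spec, dbs, energies = [], [], [], []
        for i in test_idx:
            mask = det.detect(images[i])[0]
            conf = pixel_confusion(mask, rois[i])
            sens.append(conf.sensitivity)
            spec.append(conf.specificity)
            q = fg_quality(rois[i], mask, weighting)
            dbs.append(q.db)
            energies.append(total_energy(mask_partition(rois[i]), mask_partition(mask),
                                         weighting).energy)
        rows.append({
            "fold": fold_id,
            "n_test": len(test_idx),
            "mean_sensitivity_pct": float(np.mean(sens)),
            "mean_specificity_pct": float(np.mean(spec)),
            "mean_quality_db": float(np.mean(dbs)),
            "mean_energy": float(np.mean(energies)),
            "k": det.segmentation_params_.k,
            "smooth_sigma": det.segmentation_params_.smooth_sigma,
            "min_size": det.segmentation_params_.min_size,
            "w_entropy": det.feature_weights_["entropy"],
        })
    return pd.DataFrame(rows)
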