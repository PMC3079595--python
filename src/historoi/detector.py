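"""Top-level estimator: supervised RoI detection with a fit/predict interface."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .conspicuity import PyramidConfig
from .learning import (
    GPSConfig,
    learn_feature_weights,
    learn_segmentation_params,
    make_training_samples,
)
from .quality import DistanceWeighting
from .saliency import detect as _detect
from .segmentation import SegmentationParams


class RoiDetector(BaseEstimator):
    """Supervised visual-attention detector of diagnostic regions.

    ``fit(X, y)`` takes a list of RGB images (H x W x 3 floats in [0, 1])
    and a list of binary expert RoI masks, and learns, by generalized
    pattern search, first the grouping parameters (k, smooth_sigma,
    min_size) against the expert partitions and then the four conspicuity
    weights against the expert RoIs.  ``predict(X)`` returns one binary mask
    per image.  Images may differ in size.

    Attributes set by ``fit`` carry the trailing underscore:
    ``segmentation_params_``, ``feature_weights_``, ``seg_trace_``,
    ``weight_trace_``.
    """

    def __init__(self,
                 k: float = 500.0,
                 smooth_sigma: float = 0.8,
                 min_size: int = 20,
                 connectivity: int = 4,
                 color_edges: bool = False,
                 w_intensity: float = 0.25,
                 w_color: float = 0.25,
                 w_orientation: float = 0.25,
                 w_entropy: float = 0.25,
                 entropy_window: int = 9,
                 entropy_bins: int = 32,
                 normalize_entropy: bool = False,
                 pyramid: Optional[PyramidConfig] = None,
                 weighting: Optional[DistanceWeighting] = None,
                 seg_gps: Optional[GPSConfig] = None,
                 weight_gps: Optional[GPSConfig] = None):
        self.k = k
        self.smooth_sigma = smooth_sigma
        self.min_size = min_size
        self.connectivity = connectivity
        self.color_edges = color_edges
        self.w_intensity = w_intensity
        self.w_color = w_color
        self.w_orientation = w_orientation
        self.w_entropy = w_entropy
        self.entropy_window = entropy_window
        self.entropy_bins = entropy_bins
        self.normalize_entropy = normalize_entropy
        self.pyramid = pyramid
        self.weighting = weighting
        self.seg_gps = seg_gps
        self.weight_gps = weight_gps

    # -- parameter views -------------------------------------------------
    def _initial_seg_params(self) -> SegmentationParams:
        return SegmentationParams(k=self.k, smooth_sigma=self.smooth_sigma,
                                  min_size=int(round(self.min_size)),
                                  connectivity=self.connectivity,
                                  color_edges=self.color_edges)

    def _initial_weights(self) -> Dict[str, float]:
        return {"intensity": self.w_intensity, "color": self.w_color,
                "orientation": self.w_orientation, "entropy": self.w_entropy}

    def _current_seg_params(self) -> SegmentationParams:
        return getattr(self, "segmentation_params_", self._initial_seg_params())

    def _current_weights(self) -> Dict[str, float]:
        return getattr(self, "feature_weights_", self._initial_weights())

    # -- estimator API ---------------------------------------------------
    def fit(self, X: Sequence[np.ndarray], y: Sequence[np.ndarray]) -> "RoiDetector":
        samples = make_training_samples(X, y)
        weighting = self.weighting or DistanceWeighting()
        seg_params, seg_trace = learn_segmentation_params(
            samples, cfg=self.seg_gps, weighting=weighting,
            template=self._initial_seg_params(),
            x0=(self.k, self.smooth_sigma, float(self.min_size)))
        weights, weight_trace = learn_feature_weights(
            samples, seg_params, cfg=self.weight_gps, weighting=weighting,
            pyramid=self.pyramid, entropy_window=self.entropy_window,
            entropy_bins=self.entropy_bins,
            normalize_entropy=self.normalize_entropy,
            x0=(self.w_intensity, self.w_color, self.w_orientation, self.w_entropy))
        self.segmentation_params_ = seg_params
        self.feature_weights_ = weights
        self.seg_trace_ = seg_trace
        self.weight_trace_ = weight_trace
        self.n_training_samples_ = len(samples)
        return self

    def detect(self, img: np.ndarray):
        """Run the pipeline on one image: returns (mask, region table, label map)."""
        return _detect(img,
                       seg_params=self._current_seg_params(),
                       weights=self._current_weights(),
                       pyramid=self.pyramid,
                       entropy_window=self.entropy_window,
                       entropy_bins=self.entropy_bins,
                       normalize_entropy=self.normalize_entropy)

    def predict(self, X: Sequence[np.ndarray]) -> List[np.ndarray]:
        return [self.detect(img)[0] for img in X]

    def score(self, X: Sequence[np.ndarray], y: Sequence[np.ndarray]) -> float:
        """Mean Dice coefficient between predicted and expert masks."""
        dices = []
        for img, gt in zip(X, y):
            pred = self.detect(img)[0].astype(bool)
            gt = np.asarray(gt).astype(bool)
            denom = pred.sum() + gt.sum()
            dices.append(1.0 if denom == 0 else 2.0 * (pred & gt).sum() / denom)
        return float(np.mean(dices))
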