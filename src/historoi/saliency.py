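"""Region-level saliency: feature averaging, linear combination, thresholding.

Each conspicuity map is averaged inside every segmented region ("a pixel
value average inside the region"), the four per-region indices are combined
with learned non-negative weights, the combined score is min-max normalized
across regions, and the regions whose saliency strictly exceeds the mean
region saliency form the predicted Region of Interest.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .conspicuity import CHANNELS, PyramidConfig, all_conspicuity_maps
from .segmentation import SegmentationParams, felzenszwalb_segment, segmentation_channel

DEFAULT_WEIGHTS: Dict[str, float] = {ch: 0.25 for ch in CHANNELS}


def region_feature_index(labels: np.ndarray, conspicuity_map: np.ndarray) -> np.ndarray:
    """Mean of a conspicuity map inside each region; entry r is region r's index."""
    labels = np.asarray(labels)
    conspicuity_map = np.asarray(conspicuity_map, dtype=np.float64)
    if labels.shape != conspicuity_map.shape:
        raise ValueError("label map and conspicuity map shapes differ")
    n = int(labels.max()) + 1
    sums = np.bincount(labels.ravel(), weights=conspicuity_map.ravel(), minlength=n)
    counts = np.bincount(labels.ravel(), minlength=n)
    return sums / counts


def combine_saliency(indices: np.ndarray, weights: Sequence[float]) -> np.ndarray:
    """Weighted mean of feature indices per region, min-max normalized.

    ``indices`` has shape (n_regions, n_features).  Weights must be
    non-negative and not all zero; they are normalized to sum one before the
    combination.  If all regions score equally the normalized saliency is
    0.5 everywhere (no region stands out).
    """
    indices = np.asarray(indices, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not be all zero")
    combined = indices @ (weights / total)
    lo, hi = combined.min(), combined.max()
    if hi - lo <= 0:
        return np.full_like(combined, 0.5)
    return (combined - lo) / (hi - lo)


def extract_rois(labels: np.ndarray, saliency: np.ndarray) -> np.ndarray:
    """Union of regions whose saliency strictly exceeds the mean region saliency.

    The mean is the unweighted average over regions.  With strict inequality
    an all-equal saliency vector yields an empty mask — the conservative
    behaviour for a detector.
    """
    saliency = np.asarray(saliency, dtype=np.float64)
    selected = saliency > saliency.mean()
    return selected[np.asarray(labels)].astype(np.uint8)


def region_table(labels: np.ndarray, maps: Mapping[str, np.ndarray],
                 weights: Mapping[str, float]) -> pd.DataFrame:
    """Per-region saliency table: feature indices, combined score, selection flag."""
    indices = np.column_stack([region_feature_index(labels, maps[ch]) for ch in CHANNELS])
    wvec = np.array([weights[ch] for ch in CHANNELS], dtype=np.float64)
    combined = combine_saliency(indices, wvec)
    selected = combined > combined.mean()
    table = pd.DataFrame(indices, columns=[f"mean_{ch}_consp" for ch in CHANNELS])
    table.insert(0, "region", np.arange(indices.shape[0]))
    table["combined_saliency"] = combined
    table["selected"] = selected
    return table


def detect(img: np.ndarray,
           seg_params: SegmentationParams | None = None,
           weights: Mapping[str, float] | None = None,
           pyramid: PyramidConfig | None = None,
           entropy_window: int = 9,
           entropy_bins: int = 32,
           normalize_entropy: bool = False,
           maps: Mapping[str, np.ndarray] | None = None,
           labels: np.ndarray | None = None,
           ) -> Tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Full pipeline: conspicuity x4 -> segmentation -> region saliency -> RoI mask.

    ``maps`` and ``labels`` allow callers (the learning loops) to reuse
    cached intermediates.  Returns ``(mask, table, labels)``.
    """
    seg_params = seg_params or SegmentationParams()
    weights = dict(weights) if weights is not None else dict(DEFAULT_WEIGHTS)
    if maps is None:
        maps = all_conspicuity_maps(img, cfg=pyramid, entropy_window=entropy_window,
                                    entropy_bins=entropy_bins,
                                    normalize_entropy=normalize_entropy)
    if labels is None:
        labels = felzenszwalb_segment(
            segmentation_channel(img, seg_params.color_edges), seg_params)
    table = region_table(labels, maps, weights)
    mask = extract_rois(labels, table["combined_saliency"].to_numpy())
    return mask, table, labels
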