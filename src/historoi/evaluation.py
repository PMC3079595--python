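"""Pixel- and region-level detection scores.

Pixel sensitivity/specificity treat every pixel as a binary classification.
Region scores operate on whole regions: a predicted connected component is
*meaningful* when at least a coverage fraction (default 70%) of its area
lies inside one single ground-truth region; a ground-truth region counts as
detected when a meaningful predicted component touches it.  Predicted
components failing the coverage rule are counted as meaningless — scattered
detections that a pathologist could not use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass(frozen=True)
class PixelConfusion:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float  # percent; nan when no positive ground truth
    specificity: float  # percent; nan when no negative ground truth


def pixel_confusion(pred: np.ndarray, gt: np.ndarray) -> PixelConfusion:
    """Pixelwise confusion counts and percent sensitivity/specificity."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    tn = int((~pred & ~gt).sum())
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return PixelConfusion(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec)


@dataclass(frozen=True)
class RegionHitReport:
    n_gt_regions: int
    n_pred_regions: int
    n_detected_gt: int
    n_meaningless_pred: int
    region_sensitivity: float  # percent; nan when no ground-truth regions


def _components(mask: np.ndarray) -> List[np.ndarray]:
    lab, n = ndimage.label(np.asarray(mask).astype(bool), structure=np.ones((3, 3)))
    return [lab == i for i in range(1, n + 1)]


def region_sensitivity(pred: np.ndarray | Sequence[np.ndarray],
                       gt: np.ndarray | Sequence[np.ndarray],
                       coverage_threshold: float = 0.70) -> RegionHitReport:
    """Region-level hit counting under the coverage rule.

    ``pred`` and ``gt`` may be binary masks (8-connected components become
    regions) or explicit lists of region masks.
    """
    if not (0 < coverage_threshold <= 1):
        raise ValueError("coverage_threshold must be in (0, 1]")
    pred_regions = _components(pred) if isinstance(pred, np.ndarray) else [
        np.asarray(m).astype(bool) for m in pred]
    gt_regions = _components(gt) if isinstance(gt, np.ndarray) else [
        np.asarray(m).astype(bool) for m in gt]
    meaningless = 0
    detected = np.zeros(len(gt_regions), dtype=bool)
    for region in pred_regions:
        area = region.sum()
        inside = np.array([int((region & g).sum()) for g in gt_regions]) \
            if gt_regions else np.zeros(0, dtype=int)
        if len(inside) and inside.max() >= coverage_threshold * area:
            detected |= inside > 0
        else:
            meaningless += 1
    n_gt = len(gt_regions)
    sens = 100.0 * detected.sum() / n_gt if n_gt else float("nan")
    return RegionHitReport(n_gt_regions=n_gt, n_pred_regions=len(pred_regions),
                           n_detected_gt=int(detected.sum()),
                           n_meaningless_pred=meaningless,
                           region_sensitivity=sens)


def evaluation_table(preds: Sequence[np.ndarray], gts: Sequence[np.ndarray],
                     groups: Optional[Sequence[str]] = None,
                     coverage_threshold: float = 0.70) -> pd.DataFrame:
    """One row per (prediction, ground truth) pair with pixel and region scores."""
    if len(preds) != len(gts):
        raise ValueError("predictions and ground truths differ in length")
    rows = []
    for i, (p, g) in enumerate(zip(preds, gts)):
        conf = pixel_confusion(p, g)
        hits = region_sensitivity(np.asarray(p), np.asarray(g), coverage_threshold)
        row = {
            "index": i,
            "sensitivity_pct": conf.sensitivity,
            "specificity_pct": conf.specificity,
            "tp": conf.tp, "fp": conf.fp, "tn": conf.tn, "fn": conf.fn,
            "n_gt_regions": hits.n_gt_regions,
            "n_pred_regions": hits.n_pred_regions,
            "n_detected_gt": hits.n_detected_gt,
            "n_meaningless_pred": hits.n_meaningless_pred,
            "region_sensitivity_pct": hits.region_sensitivity,
        }
        if groups is not None:
            row["group"] = groups[i]
        rows.append(row)
    return pd.DataFrame(rows)


def group_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean scores per group (e.g. per magnification) of an evaluation table."""
    if "group" not in table.columns:
        raise ValueError("table has no 'group' column")
    cols = ["sensitivity_pct", "specificity_pct", "region_sensitivity_pct"]
    return table.groupby("group")[cols].mean().reset_index()
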