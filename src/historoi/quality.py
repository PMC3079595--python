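"""Perceptual segmentation-quality energy (training objective and evaluation).

A predicted foreground is compared with an expert mask by two
distance-weighted pixel counts: missing foreground (expert pixels absent from
the prediction, each weighted by how far it lies from the predicted region)
and added background (predicted pixels outside the expert mask, weighted by
their distance to it).  Errors far from the relevant border are perceptually
worse than border jitter, hence the linearly growing weight capped at a
maximum distance.

For full partitions, ground-truth regions are matched one-to-one to
predicted regions by maximal overlap; the summed boundary inaccuracy of the
matched pairs plus over- and under-segmentation penalties for the unmatched
regions give a single energy E = e_bl + e_ov + e_un, zero exactly when the
partitions agree.  Normalized errors are also reported in decibels,
10*log10(error / (area * w_max) + 1e-7), the scale on which quality
differences of about 1 dB are visually meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

#: additive floor inside the dB logarithm; a perfect segmentation reports
#: 10*log10(1e-7) = -70 dB rather than -inf.
DB_EPSILON = 1e-7
DB_FLOOR = 10.0 * np.log10(DB_EPSILON)


@dataclass(frozen=True)
class DistanceWeighting:
    """Linear distance weight w(i) = offset + slope * min(i, d_max)."""

    slope: float = 1.0
    offset: float = 1.0
    d_max: float = 20.0

    def validate(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")

    def weight(self, distances: np.ndarray) -> np.ndarray:
        return self.offset + self.slope * np.minimum(distances, self.d_max)

    @property
    def max_weight(self) -> float:
        return self.offset + self.slope * self.d_max


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _distance_to(mask: np.ndarray, d_max: float) -> np.ndarray:
    """Euclidean distance of every pixel to the nearest mask pixel.

    An empty mask is, by convention, maximally far away: all distances are
    ``d_max``.  This keeps the errors well defined for empty predictions and
    makes the over/under-segmentation penalties (distances to a blank image)
    saturate at the maximum weight.
    """
    if not mask.any():
        return np.full(mask.shape, float(d_max))
    return ndimage.distance_transform_edt(~mask)


def missing_foreground(g: np.ndarray, c: np.ndarray,
                       w: DistanceWeighting | None = None) -> float:
    """Distance-weighted count of ground-truth pixels missing from ``c``."""
    w = w or DistanceWeighting()
    w.validate()
    g, c = _as_bool(g), _as_bool(c)
    if g.shape != c.shape:
        raise ValueError("mask shapes differ")
    missing = g & ~c
    if not missing.any():
        return 0.0
    dist = _distance_to(c, w.d_max)
    return float(w.weight(dist[missing]).sum())


def added_background(g: np.ndarray, c: np.ndarray,
                     w: DistanceWeighting | None = None) -> float:
    """Distance-weighted count of predicted pixels outside the ground truth."""
    w = w or DistanceWeighting()
    w.validate()
    g, c = _as_bool(g), _as_bool(c)
    if g.shape != c.shape:
        raise ValueError("mask shapes differ")
    added = c & ~g
    if not added.any():
        return 0.0
    dist = _distance_to(g, w.d_max)
    return float(w.weight(dist[added]).sum())


@dataclass(frozen=True)
class FgQuality:
    raw: float
    normalized: float
    db: float


def _to_db(raw: float, area: int, w: DistanceWeighting) -> Tuple[float, float]:
    normalized = raw / (area * w.max_weight)
    return normalized, float(10.0 * np.log10(normalized + DB_EPSILON))


def fg_quality(g: np.ndarray, c: np.ndarray,
               w_mf: DistanceWeighting | None = None,
               w_ab: DistanceWeighting | None = None) -> FgQuality:
    """Foreground-background quality: q_MF + q_AB, normalized, and in dB.

    Normalization divides by the worst possible weighted count, image area
    times the maximum weight, so the value lies in [0, 1].
    """
    w_mf = w_mf or DistanceWeighting()
    w_ab = w_ab or w_mf
    raw = missing_foreground(g, c, w_mf) + added_background(g, c, w_ab)
    area = int(np.asarray(g).size)
    normalized, db = _to_db(raw, area, w_mf)
    return FgQuality(raw=raw, normalized=normalized, db=db)


def partition_masks(labels: np.ndarray) -> List[np.ndarray]:
    """Region masks of a label map, ordered by label."""
    labels = np.asarray(labels)
    return [labels == r for r in range(int(labels.max()) + 1)]


def match_regions(G: Sequence[np.ndarray], C: np.ndarray | Sequence[np.ndarray]
                  ) -> Tuple[List[Tuple[int, int, int]], List[int], List[int]]:
    """Match ground-truth regions to predicted regions by maximal overlap.

    Each ground-truth region g is a candidate pair with the predicted region
    of largest overlap; candidates are granted greedily in descending overlap
    so every predicted region couples with at most one g.  Returns
    ``(pairs, uncoupled_pred, uncoupled_gt)`` where pairs are
    ``(gt_index, pred_index, overlap_pixels)``.
    """
    c_masks = partition_masks(C) if isinstance(C, np.ndarray) else [_as_bool(m) for m in C]
    g_masks = [_as_bool(m) for m in G]
    candidates = []
    for gi, g in enumerate(g_masks):
        overlaps = np.array([int((g & c).sum()) for c in c_masks])
        if len(overlaps) == 0 or overlaps.max() == 0:
            continue
        best = int(overlaps.argmax())  # ties: lowest predicted label
        candidates.append((int(overlaps[best]), gi, best))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    pairs: List[Tuple[int, int, int]] = []
    taken_c: set[int] = set()
    taken_g: set[int] = set()
    for overlap, gi, ci in candidates:
        if ci in taken_c or gi in taken_g:
            continue
        pairs.append((gi, ci, overlap))
        taken_c.add(ci)
        taken_g.add(gi)
    uncoupled_c = [i for i in range(len(c_masks)) if i not in taken_c]
    uncoupled_g = [i for i in range(len(g_masks)) if i not in taken_g]
    return pairs, uncoupled_c, uncoupled_g


def boundary_inaccuracy(pairs: Iterable[Tuple[np.ndarray, np.ndarray]],
                        w: DistanceWeighting | None = None) -> float:
    """Sum of raw fg_quality over matched (ground-truth, predicted) mask pairs."""
    w = w or DistanceWeighting()
    return float(sum(fg_quality(g, c, w).raw for g, c in pairs))


def _union(masks: Sequence[np.ndarray], shape) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for m in masks:
        out |= _as_bool(m)
    return out


def oversegmentation_error(uncoupled_pred: Sequence[np.ndarray], shape,
                           w: DistanceWeighting | None = None) -> float:
    """Penalty for predicted regions without a ground-truth partner.

    Their union is scored as added background against a blank image, so each
    pixel carries the maximum weight.
    """
    w = w or DistanceWeighting()
    if not uncoupled_pred:
        return 0.0
    blank = np.zeros(shape, dtype=bool)
    return added_background(blank, _union(uncoupled_pred, shape), w)


def undersegmentation_error(uncoupled_gt: Sequence[np.ndarray], shape,
                            w: DistanceWeighting | None = None) -> float:
    """Penalty for ground-truth regions without a predicted partner (mirror of e_ov)."""
    w = w or DistanceWeighting()
    if not uncoupled_gt:
        return 0.0
    blank = np.zeros(shape, dtype=bool)
    return missing_foreground(_union(uncoupled_gt, shape), blank, w)


@dataclass(frozen=True)
class QualityReport:
    """Full perceptual comparison of a predicted partition with ground truth."""

    q_mf: float
    q_ab: float
    e_bl: float
    e_ov: float
    e_un: float
    energy: float
    db_mf: float
    db_ab: float
    db_total: float

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("q_mf", "q_ab", "e_bl", "e_ov", "e_un", "energy",
                 "db_mf", "db_ab", "db_total")}


def total_energy(G: Sequence[np.ndarray], C: np.ndarray | Sequence[np.ndarray],
                 w: DistanceWeighting | None = None) -> QualityReport:
    """Energy E = e_bl + e_ov + e_un between a ground-truth partition and a prediction.

    ``G`` is a sequence of disjoint region masks; ``C`` either a label map or
    a sequence of region masks.  The dB fields report the missing-foreground
    side (matched pairs plus under-segmentation), the added-background side
    (matched pairs plus over-segmentation) and the total energy, each
    normalized by image area times the maximum distance weight.
    """
    w = w or DistanceWeighting()
    w.validate()
    c_masks = partition_masks(C) if isinstance(C, np.ndarray) else [_as_bool(m) for m in C]
    g_masks = [_as_bool(m) for m in G]
    if not g_masks:
        raise ValueError("ground-truth partition is empty")
    shape = g_masks[0].shape
    pairs, unc_c, unc_g = match_regions(g_masks, c_masks)
    mf = sum(missing_foreground(g_masks[gi], c_masks[ci], w) for gi, ci, _ in pairs)
    ab = sum(added_background(g_masks[gi], c_masks[ci], w) for gi, ci, _ in pairs)
    e_bl = mf + ab
    e_ov = oversegmentation_error([c_masks[i] for i in unc_c], shape, w)
    e_un = undersegmentation_error([g_masks[i] for i in unc_g], shape, w)
    energy = e_bl + e_ov + e_un
    area = int(np.prod(shape))
    q_mf = mf + e_un
    q_ab = ab + e_ov
    _, db_mf = _to_db(q_mf, area, w)
    _, db_ab = _to_db(q_ab, area, w)
    _, db_total = _to_db(energy, area, w)
    return QualityReport(q_mf=q_mf, q_ab=q_ab, e_bl=e_bl, e_ov=e_ov, e_un=e_un,
                         energy=energy, db_mf=db_mf, db_ab=db_ab, db_total=db_total)


def mask_partition(mask: np.ndarray, connectivity: int = 8) -> List[np.ndarray]:
    """Ground-truth partition implied by a binary RoI mask.

    Connected foreground components become regions; the background (if any)
    is one additional region, so the partition covers the image.
    """
    mask = _as_bool(mask)
    structure = np.ones((3, 3)) if connectivity == 8 else None
    lab, n = ndimage.label(mask, structure=structure)
    regions = [lab == i for i in range(1, n + 1)]
    background = ~mask
    if background.any():
        regions.append(background)
    return regions
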