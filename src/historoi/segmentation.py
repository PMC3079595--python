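"""Graph-based still-segmentation (the grouping stage of the pipeline).

Implements the Felzenszwalb-Huttenlocher merge rule: pixels are nodes, edges
between neighbours carry the absolute intensity difference, and two
components merge when the evidence for a boundary between them — the lightest
edge connecting them, examined in nondecreasing weight order — does not
exceed the internal difference of either component plus its size-dependent
tolerance tau(c) = k / |c|.  The scale parameter k (intensity units x pixels)
thereby sets a preference for component size and is learned from expert
segmentations rather than hand-tuned.

The union-find implementation is deterministic: equal-weight edges are
processed in row-major order of their first endpoint, so identical inputs
always give identical label maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the graph merge rule.

    ``k`` is the scale preference of the merge tolerance tau(c) = k/|c|;
    ``smooth_sigma`` an optional Gaussian pre-smoothing in pixels;
    ``min_size`` the minimum component size enforced by a final merging pass;
    ``color_edges`` switches edge weights from the intensity difference to
    the Euclidean RGB difference (off by default — stained tissue is grouped
    by brightness).
    """

    k: float = 500.0
    smooth_sigma: float = 0.8
    min_size: int = 20
    connectivity: int = 4
    color_edges: bool = False

    def validate(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def build_graph(channel: np.ndarray, connectivity: int = 4
                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edge list of the pixel grid.

    Returns arrays ``(a, b, w)`` of first endpoints, second endpoints (both
    row-major flat indices, a < b along the scan direction) and weights
    |I(a) - I(b)| (or the RGB norm for colour images).  Edges are emitted in
    row-major order of ``a``, direction right, down (and the two diagonals
    for 8-connectivity).
    """
    channel = np.asarray(channel, dtype=np.float64)
    h, w = channel.shape[:2]
    idx = np.arange(h * w).reshape(h, w)

    def diff(sl_a, sl_b):
        if channel.ndim == 3:
            return np.sqrt(((channel[sl_a] - channel[sl_b]) ** 2).sum(axis=-1))
        return np.abs(channel[sl_a] - channel[sl_b])

    pieces = [
        (idx[:, :-1], idx[:, 1:], diff(np.s_[:, :-1], np.s_[:, 1:])),   # right
        (idx[:-1, :], idx[1:, :], diff(np.s_[:-1, :], np.s_[1:, :])),   # down
    ]
    if connectivity == 8:
        pieces.append((idx[:-1, :-1], idx[1:, 1:], diff(np.s_[:-1, :-1], np.s_[1:, 1:])))
        pieces.append((idx[:-1, 1:], idx[1:, :-1], diff(np.s_[:-1, 1:], np.s_[1:, :-1])))
    elif connectivity != 4:
        raise ValueError("connectivity must be 4 or 8")
    a = np.concatenate([p[0].ravel() for p in pieces])
    b = np.concatenate([p[1].ravel() for p in pieces])
    wts = np.concatenate([p[2].ravel() for p in pieces])
    return a, b, wts


# plain Python lists: scalar access in the union-find inner loop is several
# times faster than numpy element indexing
class _UnionFind:
    __slots__ = ("parent", "size", "internal")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n
        self.internal = [0.0] * n  # max merged-edge weight

    def find(self, i: int) -> int:
        parent = self.parent
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    def union(self, ra: int, rb: int, weight: float) -> int:
        size = self.size
        if size[ra] < size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        size[ra] += size[rb]
        internal = self.internal
        internal[ra] = max(internal[ra], internal[rb], weight)
        return ra


def _sorted_edge_order(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> np.ndarray:
    # total order: weight, then row-major first endpoint, then second endpoint
    return np.lexsort((b, a, w))


def felzenszwalb_segment(channel: np.ndarray, params: SegmentationParams | None = None
                         ) -> np.ndarray:
    """Segment a scalar (or RGB, with ``color_edges``) image into regions.

    Edges are processed in nondecreasing weight; components c1, c2 merge iff
    ``w <= min(Int(c1) + k/|c1|, Int(c2) + k/|c2|)`` where Int is the largest
    weight among edges already merged inside the component.  A final pass
    merges every component smaller than ``min_size`` into its lowest-weight
    neighbour.  Returns an int label map with consecutive labels ordered by
    first row-major occurrence.
    """
    params = params or SegmentationParams()
    params.validate()
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim == 3 and not params.color_edges:
        channel = channel.mean(axis=2)
    if channel.shape[0] < 2 or channel.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    if params.smooth_sigma > 0:
        if channel.ndim == 3:
            channel = np.stack([ndimage.gaussian_filter(channel[..., c], params.smooth_sigma,
                                                        mode="reflect") for c in range(3)],
                               axis=-1)
        else:
            channel = ndimage.gaussian_filter(channel, params.smooth_sigma, mode="reflect")
    h, w = channel.shape[:2]
    a, b, wts = build_graph(channel, params.connectivity)
    order = _sorted_edge_order(a, b, wts)
    ea = a[order].tolist()
    eb = b[order].tolist()
    ew = wts[order].tolist()
    uf = _UnionFind(h * w)
    k = float(params.k)
    find, union = uf.find, uf.union
    size, internal = uf.size, uf.internal
    for pa, pb, weight in zip(ea, eb, ew):
        ra, rb = find(pa), find(pb)
        if ra == rb:
            continue
        if weight <= min(internal[ra] + k / size[ra], internal[rb] + k / size[rb]):
            union(ra, rb, weight)
    if params.min_size > 1:
        min_size = params.min_size
        for pa, pb, weight in zip(ea, eb, ew):
            ra, rb = find(pa), find(pb)
            if ra != rb and (size[ra] < min_size or size[rb] < min_size):
                union(ra, rb, weight)
    roots = np.fromiter((find(i) for i in range(h * w)), dtype=np.int64, count=h * w)
    _, labels = np.unique(roots, return_inverse=True)
    # renumber by first row-major occurrence
    n_lab = int(labels.max()) + 1
    first = np.full(n_lab, h * w, dtype=np.int64)
    np.minimum.at(first, labels, np.arange(h * w))
    remap = np.empty(n_lab, dtype=np.int64)
    remap[np.argsort(first, kind="stable")] = np.arange(n_lab)
    return remap[labels].reshape(h, w)


def n_regions(labels: np.ndarray) -> int:
    return int(labels.max()) + 1


def segmentation_channel(img: np.ndarray, color_edges: bool = False) -> np.ndarray:
    """Channel on which the merge rule runs, in 0-255 intensity units.

    RGB images normalized to [0, 1] at load time are rescaled so that the
    scale parameter k keeps its conventional intensity x pixels units.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        arr = img if color_edges else img.mean(axis=2)
        if img.max() <= 1.0 + 1e-9:
            arr = arr * 255.0
        return arr
    return img


class GraphSegmenter(BaseEstimator):
    """Scikit-learn style wrapper around :func:`felzenszwalb_segment`.

    ``fit(X, y)`` learns (k, smooth_sigma, min_size) by generalized pattern
    search against ground-truth partitions when ``y`` is given (see
    :mod:`historoi.learning`); with ``y=None`` the current parameters are
    kept.  ``predict`` maps a list of images to a list of label maps.
    """

    def __init__(self, k: float = 500.0, smooth_sigma: float = 0.8,
                 min_size: int = 20, connectivity: int = 4,
                 color_edges: bool = False, gps_config=None):
        self.k = k
        self.smooth_sigma = smooth_sigma
        self.min_size = min_size
        self.connectivity = connectivity
        self.color_edges = color_edges
        self.gps_config = gps_config

    def _params(self) -> SegmentationParams:
        return SegmentationParams(k=self.k, smooth_sigma=self.smooth_sigma,
                                  min_size=int(round(self.min_size)),
                                  connectivity=self.connectivity,
                                  color_edges=self.color_edges)

    def fit(self, X, y=None):
        base = self._params()
        if y is None:
            self.params_ = base
            return self
        from .learning import learn_segmentation_params, make_training_samples

        samples = make_training_samples(X, y)
        learned, trace = learn_segmentation_params(
            samples, cfg=self.gps_config,
            template=replace(base, connectivity=self.connectivity,
                             color_edges=self.color_edges))
        self.params_ = learned
        self.trace_ = trace
        return self

    def predict(self, X) -> List[np.ndarray]:
        params = getattr(self, "params_", self._params())
        return [felzenszwalb_segment(segmentation_channel(img, params.color_edges), params)
                for img in X]

    transform = predict

    def segment(self, img: np.ndarray) -> np.ndarray:
        return self.predict([img])[0]
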