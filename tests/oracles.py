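"""Independent brute-force references used as oracles by the test suite.

Everything here recomputes quantities by the most literal method available —
explicit set scanning, nested-loop convolution, exhaustive distance search —
and deliberately shares no code with the implementation it checks.
"""

from __future__ import annotations

import math
from typing import List, Set, Tuple

import numpy as np


def reference_segment(img: np.ndarray, k: float, min_size: int = 1,
                      connectivity: int = 4) -> List[Set[int]]:
    """Set-based re-evaluation of the graph merge rule.

    Components are plain Python sets; the within-component difference is
    recomputed at every step by scanning the list of accepted merge edges,
    and the merge predicate is applied to edges in nondecreasing weight with
    ties broken by the row-major index of the first endpoint.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    flat = img.ravel()

    edges = []
    for y in range(h):
        for x in range(w):
            p = y * w + x
            if x + 1 < w:
                edges.append((p, p + 1))
            if y + 1 < h:
                edges.append((p, p + w))
            if connectivity == 8:
                if x + 1 < w and y + 1 < h:
                    edges.append((p, p + w + 1))
                if x - 1 >= 0 and y + 1 < h:
                    edges.append((p, p + w - 1))
    weighted = [(abs(flat[a] - flat[b]), a, b) for a, b in edges]
    weighted.sort(key=lambda t: (t[0], t[1], t[2]))

    comps: List[Set[int]] = [{i} for i in range(h * w)]
    accepted: List[Tuple[int, int, float]] = []

    def comp_of(p: int) -> Set[int]:
        for c in comps:
            if p in c:
                return c
        raise AssertionError

    def internal_diff(c: Set[int]) -> float:
        best = 0.0
        for a, b, weight in accepted:
            if a in c and b in c:
                best = max(best, weight)
        return best

    for weight, a, b in weighted:
        ca, cb = comp_of(a), comp_of(b)
        if ca is cb:
            continue
        if weight <= min(internal_diff(ca) + k / len(ca),
                         internal_diff(cb) + k / len(cb)):
            comps.remove(ca)
            comps.remove(cb)
            comps.append(ca | cb)
            accepted.append((a, b, weight))
    if min_size > 1:
        for weight, a, b in weighted:
            ca, cb = comp_of(a), comp_of(b)
            if ca is not cb and (len(ca) < min_size or len(cb) < min_size):
                comps.remove(ca)
                comps.remove(cb)
                comps.append(ca | cb)
    return comps


def labels_to_partition(labels: np.ndarray) -> Set[frozenset]:
    labels = np.asarray(labels).ravel()
    return {frozenset(np.flatnonzero(labels == r).tolist())
            for r in range(labels.max() + 1)}


def partition_of_sets(comps: List[Set[int]]) -> Set[frozenset]:
    return {frozenset(c) for c in comps}


def brute_force_entropy(channel: np.ndarray, window: int, n_bins: int) -> np.ndarray:
    """Per-pixel histogram entropy by explicit window extraction (reflect padding)."""
    q = np.clip((np.asarray(channel, dtype=np.float64) * n_bins).astype(int),
                0, n_bins - 1)
    before = window // 2
    after = window - 1 - before
    padded = np.pad(q, ((before, after), (before, after)), mode="symmetric")
    h, w = q.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            patch = padded[y:y + window, x:x + window].ravel()
            counts = np.bincount(patch, minlength=n_bins)
            p = counts[counts > 0] / patch.size
            out[y, x] = -(p * np.log2(p)).sum()
    return out


def brute_force_convolve(channel: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Nested-loop 2-D convolution with reflective edge padding."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(channel, ((ph, kh - 1 - ph), (pw, kw - 1 - pw)), mode="symmetric")
    flipped = kernel[::-1, ::-1]
    h, w = channel.shape
    out = np.zeros((h, w), dtype=kernel.dtype)
    for y in range(h):
        for x in range(w):
            out[y, x] = (padded[y:y + kh, x:x + kw] * flipped).sum()
    return out


def gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    xs = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (xs / sigma) ** 2)
    return k / k.sum()


def brute_force_distance(mask: np.ndarray, y: int, x: int) -> float:
    """Euclidean distance from (y, x) to the nearest True pixel by exhaustive search."""
    mask = np.asarray(mask).astype(bool)
    best = math.inf
    for yy in range(mask.shape[0]):
        for xx in range(mask.shape[1]):
            if mask[yy, xx]:
                best = min(best, math.hypot(yy - y, xx - x))
    return best


def local_maxima_naive(m: np.ndarray) -> List[float]:
    """Values of 3x3 local maxima by explicit neighbourhood scanning.

    A connected plateau of equal maximal value is counted once.
    """
    h, w = m.shape
    is_max = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            if m[y, x] <= 0:
                continue
            neighbourhood = m[max(0, y - 1):y + 2, max(0, x - 1):x + 2]
            if m[y, x] >= neighbourhood.max():
                is_max[y, x] = True
    # merge 8-connected plateaus
    seen = np.zeros((h, w), dtype=bool)
    values = []
    for y in range(h):
        for x in range(w):
            if is_max[y, x] and not seen[y, x]:
                stack = [(y, x)]
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = cy + dy, cx + dx
                            if (0 <= ny < h and 0 <= nx < w and is_max[ny, nx]
                                    and not seen[ny, nx]):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                values.append(float(m[y, x]))
    return values
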