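"""Per-pixel conspicuity maps: intensity, colour opponency, orientation, entropy.

The three low-level channels follow the classic multiscale centre-surround
architecture of Itti-Koch saliency: a dyadic Gaussian pyramid, absolute
differences between a fine "centre" level and an upsampled coarse "surround"
level, the peak-promoting normalization N(.) that multiplies each map by
(global max - mean of other local maxima)^2, and an across-scale sum.  The
fourth channel measures texture clutter as the Shannon entropy of the local
intensity histogram; in tumour tissue this channel is the discriminative one
because hue and brightness of stained tissue are often very alike.

All maps are returned at input resolution with values in [0, 1]; a constant
input yields an identically zero map on every channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import gabor_kernel

CHANNELS = ("intensity", "color", "orientation", "entropy")


@dataclass(frozen=True)
class PyramidConfig:
    """Dyadic-pyramid layout for the centre-surround channels.

    ``center_levels`` are the fine scales c, ``surround_deltas`` the offsets
    d such that the surround is level c + d.  The canonical configuration
    (9 levels, c in {2,3,4}, d in {3,4}, 4 orientations) is used for large
    images; images smaller than 256 px fall back to a 5-level layout so that
    the coarsest level keeps a few pixels.
    """

    n_levels: int = 9
    center_levels: Tuple[int, ...] = (2, 3, 4)
    surround_deltas: Tuple[int, ...] = (3, 4)
    n_orientations: int = 4

    def validate(self) -> None:
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")
        if max(self.center_levels) + max(self.surround_deltas) >= self.n_levels:
            raise ValueError("max(center) + max(delta) must be < n_levels")

    @staticmethod
    def for_image(shape: Sequence[int]) -> "PyramidConfig":
        if min(shape[0], shape[1]) < 256:
            return SMALL_PYRAMID
        return DEFAULT_PYRAMID


DEFAULT_PYRAMID = PyramidConfig()
SMALL_PYRAMID = PyramidConfig(n_levels=5, center_levels=(1, 2), surround_deltas=(2,))


def _as_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def intensity_channel(img: np.ndarray) -> np.ndarray:
    """Mean of the three colour planes: I = (R + G + B) / 3."""
    img = _as_float(img)
    if img.ndim == 2:
        return img
    return img.mean(axis=2)


def color_opponency(img: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Broadly tuned red-green and blue-yellow opponency planes.

    Follows the Itti broadly tuned channels r' = r - (g+b)/2 etc., with
    RG = R' - G' and BY = B' - Y'; centre-surround differencing of these
    planes implements double colour opponency.
    """
    img = _as_float(img)
    if img.ndim != 3:
        raise ValueError("color opponency requires an RGB image")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    R = np.clip(r - (g + b) / 2.0, 0, None)
    G = np.clip(g - (r + b) / 2.0, 0, None)
    B = np.clip(b - (r + g) / 2.0, 0, None)
    Y = np.clip((r + g) / 2.0 - np.abs(r - g) / 2.0 - b, 0, None)
    return R - G, B - Y


def gaussian_pyramid(channel: np.ndarray, n_levels: int, sigma: float = 1.0) -> List[np.ndarray]:
    """Dyadic Gaussian pyramid: smooth with ``sigma`` then keep every 2nd pixel."""
    levels = [np.asarray(channel, dtype=np.float64)]
    for _ in range(n_levels - 1):
        prev = levels[-1]
        if min(prev.shape) < 2:
            raise ValueError("image too small for the requested pyramid depth")
        smoothed = ndimage.gaussian_filter(prev, sigma, mode="reflect")
        levels.append(smoothed[::2, ::2])
    return levels


def _upsample_to(m: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsampling by repetition, cropped to ``shape``."""
    out = m
    while out.shape[0] < shape[0] or out.shape[1] < shape[1]:
        out = np.repeat(np.repeat(out, 2, axis=0), 2, axis=1)
    return out[: shape[0], : shape[1]]


def center_surround_maps(channel: np.ndarray, cfg: PyramidConfig) -> List[np.ndarray]:
    """|centre - upsampled surround| feature maps, one per (c, d) pair.

    Maps are returned at the resolution of their centre level.
    """
    cfg.validate()
    pyr = gaussian_pyramid(channel, cfg.n_levels)
    maps = []
    for c in cfg.center_levels:
        for d in cfg.surround_deltas:
            surround = _upsample_to(pyr[c + d], pyr[c].shape)
            maps.append(np.abs(pyr[c] - surround))
    return maps


def _local_maxima_values(m: np.ndarray) -> np.ndarray:
    """Values of the strict-or-plateau local maxima of ``m`` on a 3x3 neighbourhood.

    A connected plateau of equal maximal value counts as a single maximum.
    Zero-valued pixels are never maxima.
    """
    peak = (m >= ndimage.maximum_filter(m, size=3, mode="reflect")) & (m > 0)
    if not peak.any():
        return np.empty(0)
    lab, n = ndimage.label(peak)
    return np.asarray(ndimage.labeled_comprehension(m, lab, np.arange(1, n + 1),
                                                    np.max, np.float64, 0.0))


def normalize_map(m: np.ndarray) -> np.ndarray:
    """Itti's N(.): rescale to [0, 1], then multiply by (M - mbar)^2.

    M is the global maximum (1 after rescaling) and mbar the mean of all
    *other* local maxima, so maps with a single dominant peak are preserved
    while maps with many comparable peaks are suppressed.  An all-zero map is
    returned unchanged.
    """
    m = np.asarray(m, dtype=np.float64)
    top = m.max()
    if top <= 0:
        return np.zeros_like(m)
    scaled = m / top
    values = np.sort(_local_maxima_values(scaled))[::-1]
    if len(values) <= 1:
        mbar = 0.0
    else:
        # one occurrence of the global maximum is "the" peak, the rest compete
        mbar = float(values[1:].mean())
    return scaled * (1.0 - mbar) ** 2


def _accumulate(maps: List[np.ndarray], shape: Tuple[int, int]) -> np.ndarray:
    total = np.zeros(shape, dtype=np.float64)
    for m in maps:
        total += _upsample_to(normalize_map(m), shape)
    top = total.max()
    if top > 0:
        total /= top
    return total


def _gabor_bank(n_orientations: int, frequency: float = 0.25):
    kernels = []
    for i in range(n_orientations):
        # channel angle = orientation of the stripes the filter responds to;
        # the kernel's wave vector is normal to the stripes
        theta = np.pi / 2 - np.pi * i / n_orientations
        kernels.append(gabor_kernel(frequency, theta=theta))
    return kernels


def orientation_angles(n_orientations: int) -> List[float]:
    """Stripe angles (degrees, 0 = horizontal, 90 = vertical) of the Gabor bank."""
    return [180.0 * i / n_orientations for i in range(n_orientations)]


def gabor_magnitude(channel: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Energy (modulus) of the complex Gabor response."""
    re = ndimage.convolve(channel, np.real(kernel), mode="reflect")
    im = ndimage.convolve(channel, np.imag(kernel), mode="reflect")
    return np.hypot(re, im)


def conspicuity(img: np.ndarray, channel: str, cfg: PyramidConfig | None = None) -> np.ndarray:
    """One conspicuity map: across-scale sum of normalized centre-surround maps.

    ``channel`` is one of ``intensity``, ``color`` or ``orientation``; use
    :func:`entropy_conspicuity` for the texture channel.  The result has the
    input shape and values in [0, 1].
    """
    img = _as_float(img)
    shape = img.shape[:2]
    if cfg is None:
        cfg = PyramidConfig.for_image(shape)
    cfg.validate()
    if channel == "intensity":
        maps = center_surround_maps(intensity_channel(img), cfg)
    elif channel == "color":
        rg, by = color_opponency(img)
        maps = center_surround_maps(rg, cfg) + center_surround_maps(by, cfg)
    elif channel == "orientation":
        intensity = intensity_channel(img)
        pyr = gaussian_pyramid(intensity, cfg.n_levels)
        maps = []
        for kernel in _gabor_bank(cfg.n_orientations):
            responses = [gabor_magnitude(level, kernel) for level in pyr]
            for c in cfg.center_levels:
                for d in cfg.surround_deltas:
                    surround = _upsample_to(responses[c + d], responses[c].shape)
                    maps.append(np.abs(responses[c] - surround))
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return _accumulate(maps, shape)


def local_entropy(channel: np.ndarray, window: int = 9, n_bins: int = 32) -> np.ndarray:
    """Shannon entropy (bits) of the local intensity histogram.

    ``channel`` must be scalar with values in [0, 1]; pixels are quantized
    into ``n_bins`` equal bins and counted in a ``window`` x ``window``
    neighbourhood with reflective edge padding.  Odd windows are centred;
    even windows (useful for analytic half-and-half tests) cover
    ``[i - w//2, i + w - w//2)``.
    """
    channel = _as_float(channel)
    if channel.ndim != 2:
        raise ValueError("local_entropy expects a scalar image")
    if window < 2:
        raise ValueError("window must be >= 2")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if channel.min() < -1e-9 or channel.max() > 1 + 1e-9:
        raise ValueError("intensity values must lie in [0, 1]")
    q = np.clip((channel * n_bins).astype(np.int64), 0, n_bins - 1)
    area = float(window * window)
    entropy = np.zeros_like(channel, dtype=np.float64)
    for b in range(n_bins):
        counts = ndimage.uniform_filter((q == b).astype(np.float64), size=window,
                                        mode="reflect") * area
        # counts are integers up to float round-off; make them exact
        p = np.rint(counts) / area
        nz = p > 0
        entropy[nz] -= p[nz] * np.log2(p[nz])
    return entropy


def entropy_conspicuity(img: np.ndarray, window: int = 9, n_bins: int = 32) -> np.ndarray:
    """Texture conspicuity: local intensity entropy rescaled to [0, 1].

    Computed single-scale on the intensity channel and divided by
    ``log2(n_bins)``, the maximal achievable entropy.
    """
    intensity = intensity_channel(_as_float(img))
    return local_entropy(intensity, window=window, n_bins=n_bins) / np.log2(n_bins)


def all_conspicuity_maps(img: np.ndarray, cfg: PyramidConfig | None = None,
                         entropy_window: int = 9, entropy_bins: int = 32,
                         normalize_entropy: bool = False) -> Dict[str, np.ndarray]:
    """The four channel maps used by the detection pipeline, keyed by name."""
    maps = {ch: conspicuity(img, ch, cfg) for ch in ("intensity", "color", "orientation")}
    ent = entropy_conspicuity(img, window=entropy_window, n_bins=entropy_bins)
    if normalize_entropy:
        ent = normalize_map(ent)
    maps["entropy"] = ent
    return maps
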