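"""Synthetic histology-like fixtures and tiny analytic micro-images.

Real H&E fields of basal-cell carcinoma show pale, smooth eosin-stained
stroma surrounding darker haematoxylin-dense tumour "islets" whose interior
is visibly more cluttered (higher local intensity entropy) than the
background.  :func:`generate_fixture` emulates exactly those two properties
— a colour/intensity offset and a texture (speckle) offset — with smooth
closed contours, so the full detection pipeline can be exercised and scored
against an exact ground-truth mask without any external corpus.

:func:`micro_image` provides a catalogue of hand-specified images (at most
8x8) whose segmentations and masks are known analytically; tests use them as
oracle inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy import ndimage


class PlacementError(RuntimeError):
    """Raised when non-overlapping islets cannot be placed."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic histology field.

    Colours are 8-bit RGB triples; noise standard deviations are in 0-255
    intensity units.  The defaults emulate a pale pink stroma background with
    two darker violet, heavily speckled carcinoma islets.
    """

    width: int = 128
    height: int = 128
    n_islets: int = 2
    islet_radius_range: Tuple[float, float] = (14.0, 24.0)
    background_color: Tuple[int, int, int] = (230, 200, 210)
    islet_color: Tuple[int, int, int] = (120, 90, 160)
    islet_texture_noise_sd: float = 45.0
    background_noise_sd: float = 5.0
    blur_sigma: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValueError("fixture must be at least 16x16")
        if self.n_islets < 0:
            raise ValueError("n_islets must be >= 0")
        lo, hi = self.islet_radius_range
        if not (0 < lo <= hi):
            raise ValueError("islet_radius_range must satisfy 0 < min <= max")
        if hi >= min(self.width, self.height) / 2:
            raise ValueError("islet radii must be < min(width, height)/2")
        if self.islet_texture_noise_sd < 0 or self.background_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


# Radial contour perturbation: low angular frequencies only, so contours stay
# smooth and closed; total relative amplitude capped at 0.25.
_PERTURB_MODES = (2, 3, 4)
_PERTURB_AMPLITUDE = 0.20


def _islet_mask(shape: Tuple[int, int], center: Tuple[float, float], radius: float,
                rng: np.random.Generator) -> np.ndarray:
    """Binary support of one islet: a disc deformed by low-frequency radial modes."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - center[0]
    dx = xx - center[1]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    amps = rng.uniform(-1.0, 1.0, size=len(_PERTURB_MODES))
    norm = np.sum(np.abs(amps))
    if norm > 0:
        amps = amps / norm * _PERTURB_AMPLITUDE * rng.uniform(0.5, 1.0)
    phases = rng.uniform(0, 2 * np.pi, size=len(_PERTURB_MODES))
    modulation = np.ones_like(theta)
    for m, a, p in zip(_PERTURB_MODES, amps, phases):
        modulation = modulation + a * np.cos(m * theta + p)
    return rho <= radius * modulation


def generate_fixture(spec: FixtureSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Generate one synthetic field and its ground-truth mask.

    Returns
    -------
    image : (H, W, 3) float64 in [0, 1]
    mask : (H, W) uint8 in {0, 1}; 1 marks islet (RoI) pixels.

    Identical specs (including seed) give byte-identical output.  Raises
    :class:`PlacementError` when ``n_islets`` non-overlapping islets cannot
    be placed within 1000 rejection-sampling attempts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    placed: list[Tuple[float, float, float]] = []
    # Contour can bulge up to (1 + amplitude) * radius; keep a safety margin.
    bulge = 1.0 + _PERTURB_AMPLITUDE + 0.05
    attempts = 0
    while len(placed) < spec.n_islets:
        if attempts >= 1000:
            raise PlacementError(
                f"could not place {spec.n_islets} non-overlapping islets "
                f"in a {w}x{h} image after 1000 attempts"
            )
        attempts += 1
        radius = rng.uniform(*spec.islet_radius_range)
        margin = radius * bulge + 2
        if 2 * margin >= min(h, w):
            continue
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if any(np.hypot(cy - py, cx - px) < (radius + pr) * bulge + 2
               for py, px, pr in placed):
            continue
        placed.append((cy, cx, radius))
        mask |= _islet_mask((h, w), (cy, cx), radius, rng)

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(spec.background_color, dtype=np.float64)
    img[mask] = np.asarray(spec.islet_color, dtype=np.float64)
    # Shared-luminance speckle keeps the intensity channel textured, which is
    # what drives the local-entropy contrast between islet and stroma.
    noise = rng.normal(0.0, 1.0, size=(h, w))
    sd = np.where(mask, spec.islet_texture_noise_sd, spec.background_noise_sd)
    img += (noise * sd)[..., None]
    if spec.blur_sigma > 0:
        for ch in range(3):
            img[..., ch] = ndimage.gaussian_filter(img[..., ch], spec.blur_sigma,
                                                   mode="reflect")
    np.clip(img, 0.0, 255.0, out=img)
    return img / 255.0, mask.astype(np.uint8)


def fixture_suite(n: int, seed: int, spec: FixtureSpec | None = None):
    """A list of ``n`` (image, mask) fixtures with seeds derived from ``seed``."""
    base = spec if spec is not None else FixtureSpec()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [generate_fixture(replace(base, seed=int(s))) for s in seeds]


def channel_discriminative_fixture(channel: str, seed: int,
                                   width: int = 128, height: int = 128,
                                   radius: float = 18.0
                                   ) -> Tuple[np.ndarray, np.ndarray]:
    """A field where only one feature channel identifies the true RoI.

    Two blobs are planted: a *target* (the ground-truth RoI) that stands out
    only in the requested ``channel``, and a *distractor* that is conspicuous
    in the complementary channels but is not part of the ground truth.  For
    ``channel='entropy'`` the target shares the background colour and differs
    only by heavy speckle, while the distractor is a dark, smooth islet; for
    ``channel='color'`` the target is hue-shifted at equal mean intensity and
    the distractor is a speckled background-coloured blob.  A weight learner
    must favour the named channel to select the target and reject the
    distractor.
    """
    background = (230, 200, 210)
    if channel == "entropy":
        target_color, target_sd = background, 50.0
        distractor_color, distractor_sd = (120, 90, 160), 3.0
    elif channel == "color":
        # same mean intensity as the background (213.3), different hue
        target_color, target_sd = (180, 230, 230), 3.0
        distractor_color, distractor_sd = background, 50.0
    else:
        raise ValueError("channel must be 'entropy' or 'color'")
    rng = np.random.default_rng(seed)
    h, w = height, width
    bulge = 1.0 + _PERTURB_AMPLITUDE + 0.05
    margin = radius * bulge + 2
    blobs = []
    attempts = 0
    while len(blobs) < 2:
        if attempts >= 1000:
            raise PlacementError("could not place target and distractor blobs")
        attempts += 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if any(np.hypot(cy - py, cx - px) < 2 * radius * bulge + 2 for py, px in blobs):
            continue
        blobs.append((cy, cx))
    target = _islet_mask((h, w), blobs[0], radius, rng)
    distractor = _islet_mask((h, w), blobs[1], radius, rng)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(background, dtype=np.float64)
    img[target] = np.asarray(target_color, dtype=np.float64)
    img[distractor] = np.asarray(distractor_color, dtype=np.float64)
    sd = np.full((h, w), 3.0)
    sd[target] = target_sd
    sd[distractor] = distractor_sd
    img += (rng.normal(0.0, 1.0, size=(h, w)) * sd)[..., None]
    for ch in range(3):
        img[..., ch] = ndimage.gaussian_filter(img[..., ch], 0.5, mode="reflect")
    np.clip(img, 0.0, 255.0, out=img)
    return img / 255.0, target.astype(np.uint8)


def _uniform4():
    img = np.full((4, 4), 128.0)
    labels = np.zeros((4, 4), dtype=np.int64)
    return img, labels


def _halves4():
    img = np.zeros((4, 4))
    img[:, 2:] = 255.0
    labels = np.zeros((4, 4), dtype=np.int64)
    labels[:, 2:] = 1
    return img, labels


def _checker4():
    img = np.indices((4, 4)).sum(axis=0) % 2 * 255.0
    # every 4-neighbour differs, so the natural partition is one region per pixel
    labels = np.arange(16, dtype=np.int64).reshape(4, 4)
    return img, labels


def _quadrants4():
    img = np.zeros((4, 4))
    img[:2, 2:] = 85.0
    img[2:, :2] = 170.0
    img[2:, 2:] = 255.0
    labels = np.zeros((4, 4), dtype=np.int64)
    labels[:2, 2:] = 1
    labels[2:, :2] = 2
    labels[2:, 2:] = 3
    return img, labels


def _square3in8():
    img = np.zeros((8, 8))
    img[2:5, 2:5] = 255.0
    mask = (img > 0).astype(np.uint8)
    return img, mask


_CATALOGUE = {
    "uniform4": _uniform4,
    "halves4": _halves4,
    "checker4": _checker4,
    "quadrants4": _quadrants4,
    "square3in8": _square3in8,
}

MICRO_IMAGE_NAMES = tuple(sorted(_CATALOGUE))


def micro_image(name: str) -> Tuple[np.ndarray, np.ndarray]:
    """Return a hand-specified micro-image and its known partition or mask.

    Images are scalar arrays in 0-255 intensity units (the scale on which
    segmentation edge weights and the merge threshold ``k/|c|`` are defined).
    ``square3in8`` returns a binary mask; the others return label maps.
    """
    try:
        builder = _CATALOGUE[name]
    except KeyError:
        raise KeyError(f"unknown micro-image {name!r}; known: {MICRO_IMAGE_NAMES}")
    return builder()
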