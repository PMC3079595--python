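"""Image, mask and label-map I/O.

Conventions: images are read as 8-bit RGB and normalized to [0, 1] floats;
binary masks are single-channel PNGs with values {0, 255} on disk and
{0, 1} in memory; label maps are 16-bit PNGs with a JSON sidecar recording
the region count and the parameters that produced them.  Pixel coordinates
are 0-based row-major throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB image (PNG/JPEG) as (H, W, 3) float64 in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return arr / 255.0


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] float RGB image as 8-bit PNG."""
    arr = np.clip(np.asarray(img) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG; any nonzero pixel counts as foreground."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask).astype(bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)


def write_labelmap(path: str | Path, labels: np.ndarray,
                   params: Optional[dict] = None) -> None:
    """Write a label map as 16-bit PNG plus a `.json` sidecar."""
    labels = np.asarray(labels)
    if labels.max() > 65534:
        raise ValueError("label map has more than 65535 regions")
    Image.fromarray(labels.astype(np.uint16)).save(path)
    sidecar = {"n_regions": int(labels.max()) + 1, "params": params or {}}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_labelmap(path: str | Path) -> Tuple[np.ndarray, dict]:
    with Image.open(path) as im:
        labels = np.asarray(im, dtype=np.int64)
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return labels, sidecar
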