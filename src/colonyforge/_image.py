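"""Shared raster helpers: grayscale conversion and PNG I/O.

Plate images are uint8 arrays of shape (height, width, 3), indexed
``image[y, x, channel]`` with channels in RGB order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

# ITU-R BT.601 luma weights (the convention of cv2.cvtColor BGR2GRAY /
# PIL "L" mode), applied to RGB.
_LUMA = np.array([0.299, 0.587, 0.114])


def as_plate_image(image: np.ndarray) -> np.ndarray:
    """Validate and return an 8-bit 3-channel plate image."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected uint8 image, got dtype {arr.dtype}")
    return arr


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luma grayscale of an RGB image as float64 in [0, 255]."""
    return as_plate_image(image) @ _LUMA


def read_png(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_png(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(as_plate_image(image), mode="RGB").save(path, format="PNG")
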