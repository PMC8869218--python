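"""Geometric augmentation: lossless rotation and quarter-cutting.

Rotations are restricted to 90/180/270 degrees so they are pure axis
transpositions/flips — no interpolation, the pixel multiset is preserved
exactly. Boxes are rotated with the centre-anchored transform

    xR =  (xo - w/2) cos(t) + (yo - h/2) sin(t) + W/2
    yR = -(xo - w/2) sin(t) + (yo - h/2) cos(t) + H/2

where (w, h) are the source dimensions and (W, H) the rotated ones
((h, w) for 90/270). The direction convention is pinned to
``numpy.rot90``: under a 90-degree rotation the pixel (0, 0) of a w x h
image lands at (0, w - 1).

Quarter-cutting divides a plate image into four equal quadrants. It does
not change a colony's absolute pixel size, but halves the image side, so
the colony's size *relative to the image* doubles — for a division into D
parts the relative linear size grows by sqrt(D) and the relative area by
D (see :func:`relative_scale`). Boxes straddling a cut line are clipped
to each quadrant and kept only when enough of their area survives.
"""

from __future__ import annotations

import numpy as np

from ._image import as_plate_image
from .annotations import BoxAnnotation

_ANGLES = {90: 1, 180: 2, 270: 3}

# exact (cos, sin) for the supported angles
_TRIG = {90: (0, 1), 180: (-1, 0), 270: (0, -1)}


def rotated_dims(w: int, h: int, theta: int) -> tuple[int, int]:
    """(W, H) of the rotated image."""
    if theta not in _ANGLES:
        raise ValueError(f"unsupported angle {theta}; use 90, 180 or 270")
    return (h, w) if theta in (90, 270) else (w, h)


def rotate_image(image: np.ndarray, theta: int) -> np.ndarray:
    """Lossless rotation by 90/180/270 degrees."""
    if theta not in _ANGLES:
        raise ValueError(f"unsupported angle {theta}; use 90, 180 or 270")
    return np.ascontiguousarray(np.rot90(as_plate_image(image),
                                         _ANGLES[theta]))


def rotate_box(box: BoxAnnotation, theta: int, w: int, h: int
               ) -> BoxAnnotation:
    """Rotate a box with the image; exact for the three supported angles.

    All four corners are mapped with the centre-anchored transform (in
    continuous coordinates, where the image occupies [0, w] x [0, h]) and
    the axis-aligned box of the images is returned, valid in the rotated
    W x H frame.
    """
    if theta not in _TRIG:
        raise ValueError(f"unsupported angle {theta}; use 90, 180 or 270")
    cos_t, sin_t = _TRIG[theta]
    W, H = rotated_dims(w, h, theta)
    xs, ys = [], []
    for xo, yo in ((box.x1, box.y1), (box.x2, box.y1),
                   (box.x1, box.y2), (box.x2, box.y2)):
        dx, dy = xo - 0.5 * w, yo - 0.5 * h
        xs.append(dx * cos_t + dy * sin_t + 0.5 * W)
        ys.append(-dx * sin_t + dy * cos_t + 0.5 * H)
    return BoxAnnotation(box.class_id, min(xs), min(ys), max(xs), max(ys))


def quarter_cut(image: np.ndarray, annotations: list[BoxAnnotation],
                min_kept_fraction: float = 0.3
                ) -> list[tuple[np.ndarray, list[BoxAnnotation]]]:
    """Split into four quadrants with clipped, translated annotations.

    Quadrants come back in reading order (top-left, top-right,
    bottom-left, bottom-right), each ``floor(w/2) x floor(h/2)`` (odd
    dimensions lose the final row/column). A box is clipped to every
    quadrant it intersects, translated to quadrant-local coordinates, and
    kept iff the clipped area is at least ``min_kept_fraction`` of the
    original area — slivers left by a cut line would be unlearnable
    labels.
    """
    img = as_plate_image(image)
    h, w = img.shape[:2]
    hw, hh = w // 2, h // 2
    quads = []
    for qy, qx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        ox, oy = qx * hw, qy * hh
        sub = img[oy:oy + hh, ox:ox + hw]
        kept = []
        for box in annotations:
            x1 = max(box.x1, ox) - ox
            y1 = max(box.y1, oy) - oy
            x2 = min(box.x2, ox + hw) - ox
            y2 = min(box.y2, oy + hh) - oy
            if x2 <= x1 or y2 <= y1:
                continue
            if (x2 - x1) * (y2 - y1) >= min_kept_fraction * box.area:
                kept.append(BoxAnnotation(box.class_id, x1, y1, x2, y2))
        quads.append((sub, kept))
    return quads


def relative_scale(d: int) -> tuple[float, float]:
    """Relative-size growth factors for a division into ``d`` parts.

    Cutting an image into ``d`` equal parts (d = 4, 9, 16, ...) leaves
    each colony's absolute length unchanged while the image width shrinks
    by sqrt(d); a colony's length relative to the image width therefore
    grows by sqrt(d) and its relative area by d. Returns
    ``(sqrt(d), d)``. (The relation is sometimes written with a bare
    factor of d on the linear ratio; the geometry — and the doubling for
    d = 4 — give sqrt(d), so both factors are exposed.)
    """
    if d < 4:
        raise ValueError("d must be a perfect square >= 4")
    root = int(round(np.sqrt(d)))
    if root * root != d:
        raise ValueError(f"d={d} is not a perfect square")
    return (float(root), float(d))
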