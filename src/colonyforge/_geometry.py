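"""Exact minimum enclosing circle of a 2-D point set.

Randomized incremental (Welzl-style) algorithm, expected O(n). The circle
is unique, so the internal shuffle does not affect the result. Points are
reduced to their convex hull first when possible, which keeps the expected
cost negligible for colony-sized components.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import ConvexHull, QhullError

_EPS = 1e-9


def _circle_two(a, b):
    cx = 0.5 * (a[0] + b[0])
    cy = 0.5 * (a[1] + b[1])
    r = math.dist(a, (cx, cy))
    return (cx, cy, r)


def _circle_three(a, b, c):
    # circumcircle; returns None for (near-)collinear triples
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < _EPS:
        return None
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    return (ux, uy, math.dist(a, (ux, uy)))


def _in_circle(circle, p) -> bool:
    cx, cy, r = circle
    return math.dist(p, (cx, cy)) <= r + _EPS


def _mec_one_boundary(points, p):
    circle = (p[0], p[1], 0.0)
    for i, q in enumerate(points):
        if not _in_circle(circle, q):
            circle = _mec_two_boundary(points[:i], p, q)
    return circle


def _mec_two_boundary(points, p, q):
    circ = _circle_two(p, q)
    left = None
    right = None
    px, py = p
    qx, qy = q
    for r in points:
        if _in_circle(circ, r):
            continue
        cross = (qx - px) * (r[1] - py) - (qy - py) * (r[0] - px)
        c = _circle_three(p, q, r)
        if c is None:
            continue
        if cross > 0 and (left is None or
                          (qx - px) * (c[1] - py) - (qy - py) * (c[0] - px)
                          > (qx - px) * (left[1] - py) - (qy - py) * (left[0] - px)):
            left = c
        elif cross < 0 and (right is None or
                            (qx - px) * (c[1] - py) - (qy - py) * (c[0] - px)
                            < (qx - px) * (right[1] - py) - (qy - py) * (right[0] - px)):
            right = c
    if left is None and right is None:
        return circ
    if left is None:
        return right
    if right is None:
        return left
    return left if left[2] <= right[2] else right


def minimum_enclosing_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Smallest circle covering every point; returns (cx, cy, radius).

    ``points`` is an (n, 2) array of (x, y) coordinates, n >= 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    if len(pts) > 8:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear/degenerate sets: fall through with all points
    order = np.random.default_rng(0).permutation(len(pts))
    shuffled = [tuple(pts[i]) for i in order]
    circle = None
    for i, p in enumerate(shuffled):
        if circle is None or not _in_circle(circle, p):
            circle = _mec_one_boundary(shuffled[:i], p)
    return circle
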