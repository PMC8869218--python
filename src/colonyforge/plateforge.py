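"""Synthetic colony-plate generator with exact ground truth.

Emulates the imaging regime of low-cost colony photography in a shaded
enclosure: a near-black background (gray values typically below 20),
low-contrast bright colonies rendered as radially shaded discs, optional
overlapping/adherent colony pairs, and a bright dish rim near the image
border. Every colony comes with a tight ground-truth bounding box, so the
augmentation and counting modules can be tested without any real data.

Coordinates follow the toolkit convention: 0-based, x rightward, y
downward; ground-truth boxes are half-open ``[x1, x2) x [y1, y2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotations import BoxAnnotation


class LayoutInfeasibleError(RuntimeError):
    """Raised when colonies cannot be placed after bounded retries."""


@dataclass(frozen=True)
class PlateSpec:
    """Parameters of one synthetic plate.

    Defaults mirror the low-contrast regime the toolkit targets: mean
    background gray 12 (so that virtually all background pixels sit below
    the gray-20 band), colony peak brightness 90-150, and colony radii
    6-28 px so that pixel areas fall inside the effective (60, 3500) px**2
    band used for candidate filtering.
    """

    width: int = 640
    height: int = 648
    n_colonies: int = 40
    radius_range: tuple[float, float] = (6.0, 28.0)
    background_level: float = 12.0
    background_noise: float = 2.0
    colony_intensity_range: tuple[float, float] = (90.0, 150.0)
    overlap_fraction: float = 0.15
    rim: bool = True
    rim_brightness: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.n_colonies < 0:
            raise ValueError("n_colonies must be >= 0")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (min, max)")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.background_level >= self.colony_intensity_range[0]:
            raise ValueError("colonies must be brighter than the background")

    @property
    def rim_radius(self) -> float:
        return 0.98 * min(self.width, self.height) / 2.0

    @property
    def rim_width(self) -> int:
        return 4


@dataclass
class GroundTruth:
    """Exact layout of one plate: per-colony center, radius and box."""

    boxes: list[BoxAnnotation] = field(default_factory=list)
    centers: list[tuple[float, float]] = field(default_factory=list)
    radii: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.boxes)


def _box_for(cx: float, cy: float, r: float) -> BoxAnnotation:
    # tight integer box: side in [2r, 2r + 2]
    return BoxAnnotation(0, math.floor(cx - r), math.floor(cy - r),
                         math.ceil(cx + r), math.ceil(cy + r))


def sample_layout(spec: PlateSpec, max_tries: int = 2000) -> GroundTruth:
    """Place ``spec.n_colonies`` discs inside the dish, seeded by the spec.

    Approximately ``overlap_fraction`` of colonies get an overlapping
    neighbour: overlap is created in pairs, so ``round(f * n / 2)``
    colonies are attached to a distinct isolated anchor at a
    centre-to-centre distance below the radius sum. All other colonies
    are mutually separated. Raises :class:`LayoutInfeasibleError` when a
    position cannot be found within ``max_tries`` attempts.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_colonies
    gt = GroundTruth()
    if n == 0:
        return gt

    n_attached = int(round(spec.overlap_fraction * n / 2.0))
    n_free = n - n_attached
    cx0, cy0 = spec.width / 2.0, spec.height / 2.0
    # discs must stay inside the dish interior (inside the rim when drawn)
    if spec.rim:
        dish_r = spec.rim_radius - spec.rim_width - 1
    else:
        dish_r = min(spec.width, spec.height) / 2.0 - 1

    centers: list[tuple[float, float]] = []
    radii: list[float] = []

    def fits_dish(x: float, y: float, r: float) -> bool:
        return math.hypot(x - cx0, y - cy0) <= dish_r - r

    # placement of mutually separated "free" colonies
    for _ in range(n_free):
        r = rng.uniform(*spec.radius_range)
        for _ in range(max_tries):
            x = rng.uniform(cx0 - dish_r, cx0 + dish_r)
            y = rng.uniform(cy0 - dish_r, cy0 + dish_r)
            if not fits_dish(x, y, r):
                continue
            if all(math.hypot(x - px, y - py) > r + pr + 2.0
                   for (px, py), pr in zip(centers, radii)):
                centers.append((x, y))
                radii.append(r)
                break
        else:
            raise LayoutInfeasibleError(
                f"could not place colony {len(centers) + 1}/{n} "
                f"after {max_tries} tries")

    # attached colonies: each overlaps one distinct free anchor
    anchor_ids = rng.permutation(n_free)[:n_attached] if n_free else []
    for a in anchor_ids:
        ax, ay = centers[a]
        ar = radii[a]
        r = rng.uniform(*spec.radius_range)
        for _ in range(max_tries):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            d = rng.uniform(0.55, 0.9) * (ar + r)
            x, y = ax + d * math.cos(theta), ay + d * math.sin(theta)
            if not fits_dish(x, y, r):
                continue
            # overlap only the chosen anchor, stay clear of everyone else
            ok = all(i == a or math.hypot(x - px, y - py) > r + pr + 2.0
                     for i, ((px, py), pr) in enumerate(zip(centers, radii)))
            if ok:
                centers.append((x, y))
                radii.append(r)
                break
        else:
            raise LayoutInfeasibleError(
                f"could not attach overlapping colony to anchor {a}")

    gt.centers = centers
    gt.radii = radii
    gt.boxes = [_box_for(x, y, r) for (x, y), r in zip(centers, radii)]
    return gt


def render_plate(spec: PlateSpec, layout: GroundTruth) -> np.ndarray:
    """Render the plate raster for a layout; (spec, layout) -> uint8 RGB.

    Background pixels are Gaussian noise around ``background_level``
    (clipped at 0), colonies are discs with a cosine falloff from a
    per-colony peak down to background at the disc edge, and the optional
    rim is a bright ring. The grayscale field is replicated to three
    channels with independent integer jitter in [-2, 2] so the channels
    are distinguishable but near-identical.
    """
    rng = np.random.default_rng(spec.seed + 1)
    h, w = spec.height, spec.width
    # truncate the noise tail so background + channel jitter stays < 20
    field_ = np.clip(
        rng.normal(spec.background_level, spec.background_noise, (h, w)),
        0.0, 17.0)

    for (cx, cy), r, peak in zip(
            layout.centers, layout.radii,
            rng.uniform(*spec.colony_intensity_range, size=len(layout))):
        x0, x1 = max(0, math.floor(cx - r)), min(w, math.ceil(cx + r) + 1)
        y0, y1 = max(0, math.floor(cy - r)), min(h, math.ceil(cy + r) + 1)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xs - cx, ys - cy)
        inside = d <= r
        # cosine falloff over [0, pi/2]: peak at centre, background at edge
        profile = spec.background_level + (peak - spec.background_level) \
            * np.cos(0.5 * math.pi * np.clip(d / max(r, 1e-9), 0.0, 1.0))
        patch = field_[y0:y1, x0:x1]
        patch[inside] = np.maximum(patch[inside], profile[inside])

    if spec.rim:
        cx0, cy0 = w / 2.0, h / 2.0
        ys, xs = np.mgrid[0:h, 0:w]
        d = np.hypot(xs - cx0, ys - cy0)
        ring = (d >= spec.rim_radius - spec.rim_width) & (d < spec.rim_radius)
        field_[ring] = spec.rim_brightness

    gray = np.clip(field_, 0, 255)
    jitter = rng.integers(-2, 3, size=(h, w, 3))
    rgb = np.clip(gray[:, :, None] + jitter, 0, 255).astype(np.uint8)
    return rgb


def generate_plate(spec: PlateSpec) -> tuple[np.ndarray, GroundTruth]:
    """Convenience wrapper: sample a layout and render it."""
    layout = sample_layout(spec)
    return render_plate(spec, layout), layout


def make_source_plates(n_sources: int = 5, seed: int = 0,
                       width: int = 2560, height: int = 2590,
                       n_colonies: int = 300
                       ) -> list[tuple[np.ndarray, list[BoxAnnotation]]]:
    """Emulate a small hand-collected set of annotated plate photographs.

    Defaults reproduce the few-shot regime the toolkit targets: five
    full-resolution 2560 x 2590 plates, each a few hundred colonies, from
    which the augmentation pipeline builds the whole training dataset.
    Returns ``(image, boxes)`` pairs.
    """
    sources = []
    for i in range(n_sources):
        spec = PlateSpec(width=width, height=height, n_colonies=n_colonies,
                         seed=seed * 1000 + i)
        image, layout = generate_plate(spec)
        sources.append((image, layout.boxes))
    return sources
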