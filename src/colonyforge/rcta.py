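"""Random Cover Targets Algorithm: annotation-preserving colony erasure.

The algorithm augments an annotated plate photograph by erasing randomly
chosen colonies: candidate colonies are found by threshold segmentation,
filtered to an effective pixel-area band and to the central region of the
image, and each selected candidate is overwritten with a disc of the local
background colour. Because the image structure changes while the remaining
colonies stay put, the source image's annotation file carries over — only
the boxes of erased colonies have to be dropped, which this module does
automatically (a box is dropped iff its centre lies inside a covered disc).

The cover colour is the per-channel mean of near-black background pixels
(grayscale below ``background_cutoff``, default 20) inside an s x s window
anchored at the target centre:

    Rmean = sum(R(x, y)) / N   over (x, y) in [xr, xr+s) x [yr, yr+s)
                               with gray(x, y) < cutoff,

and likewise for G and B. The window extends to the bottom-right of the
centre; colony pixels inside it are excluded by the cutoff mask. When the
window holds no background pixel at all, the global mean of all sub-cutoff
pixels is used and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from ._geometry import minimum_enclosing_circle
from ._image import as_plate_image, to_gray
from .annotations import BoxAnnotation


class NoBackgroundError(RuntimeError):
    """No pixel below the background cutoff anywhere in the image."""


@dataclass(frozen=True)
class RCTAConfig:
    """Tunable parameters of the cover algorithm.

    seg_threshold
        Gray value separating background from candidate targets. There is
        no universal value — it depends on exposure — so it is explicit;
        40 suits the synthetic plates (background band < 20, colony peaks
        well above 40).
    area_range
        Open interval of candidate pixel areas treated as genuine
        colonies; (60, 3500) px**2 by default.
    margin_fraction
        Border fraction (per side) excluded from coverage, keeping the
        dish rim and edge artefacts out of the candidate pool.
    window_size
        Side s of the background sampling window anchored at the target
        centre.
    background_cutoff
        Gray value below which a pixel counts as background.
    """

    seg_threshold: float = 40.0
    area_range: tuple[float, float] = (60.0, 3500.0)
    margin_fraction: float = 0.10
    window_size: int = 20
    background_cutoff: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.seg_threshold < 255):
            raise ValueError("seg_threshold must be in (0, 255)")
        a_min, a_max = self.area_range
        if not (0 <= a_min < a_max):
            raise ValueError("area_range must satisfy 0 <= a_min < a_max")
        if not (0 <= self.margin_fraction < 0.5):
            raise ValueError("margin_fraction must be in [0, 0.5)")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0 < self.background_cutoff <= 255):
            raise ValueError("background_cutoff must be in (0, 255]")


@dataclass(frozen=True)
class TargetRegion:
    """A segmented candidate colony: centre, enclosing radius, pixel area."""

    xr: float
    yr: float
    radius: float
    area: float


@dataclass(frozen=True)
class CoverColor:
    """Per-channel background mean used to overwrite one target."""

    r_mean: float
    g_mean: float
    b_mean: float
    n: int
    fallback: bool = False  # True when the global background mean was used

    def as_rgb8(self) -> tuple[int, int, int]:
        return tuple(int(np.clip(round(c), 0, 255))
                     for c in (self.r_mean, self.g_mean, self.b_mean))


def find_target_regions(image: np.ndarray, seg_threshold: float
                        ) -> list[TargetRegion]:
    """Threshold-segment the image and return one region per component.

    The image is converted to grayscale (BT.601 luma), binarized at
    ``seg_threshold`` (strictly greater -> foreground), and each
    8-connected foreground component yields a :class:`TargetRegion`
    carrying its minimum-enclosing-circle centre/radius and its pixel
    area. Regions come back in raster-scan (label) order.
    """
    gray = to_gray(image)
    labels = label(gray > seg_threshold, connectivity=2)
    regions = []
    for prop in regionprops(labels):
        ys, xs = prop.coords[:, 0], prop.coords[:, 1]
        cx, cy, radius = minimum_enclosing_circle(
            np.column_stack([xs, ys]))
        regions.append(TargetRegion(xr=cx, yr=cy, radius=radius,
                                    area=float(prop.area)))
    return regions


def filter_regions(regions: list[TargetRegion], config: RCTAConfig,
                   width: int, height: int) -> list[TargetRegion]:
    """Keep regions in the effective area band and the central rectangle.

    The area band is the open interval ``a_min < area < a_max``; the
    central rectangle excludes a ``margin_fraction`` border per side
    (half-open, consistent with the box convention). Order is preserved.
    """
    a_min, a_max = config.area_range
    m = config.margin_fraction
    x_lo, x_hi = m * width, (1.0 - m) * width
    y_lo, y_hi = m * height, (1.0 - m) * height
    return [r for r in regions
            if a_min < r.area < a_max
            and x_lo <= r.xr < x_hi and y_lo <= r.yr < y_hi]


def compute_cover_color(image: np.ndarray, region: TargetRegion,
                        config: RCTAConfig) -> CoverColor:
    """Mean background colour in the window anchored at the region centre.

    The window is ``[xr, xr+s) x [yr, yr+s)`` clipped to the image; only
    pixels whose grayscale value is strictly below ``background_cutoff``
    contribute. With no qualifying pixel in the window, the mean over all
    sub-cutoff pixels of the whole image is returned with ``fallback``
    set; if even that set is empty, :class:`NoBackgroundError` is raised.
    """
    img = as_plate_image(image)
    h, w = img.shape[:2]
    s = config.window_size
    x0 = int(np.clip(round(region.xr), 0, w))
    y0 = int(np.clip(round(region.yr), 0, h))
    x1, y1 = min(x0 + s, w), min(y0 + s, h)

    window = img[y0:y1, x0:x1].astype(np.float64)
    if window.size:
        mask = (window @ np.array([0.299, 0.587, 0.114])
                ) < config.background_cutoff
    else:
        mask = np.zeros((0, 0), dtype=bool)
    n = int(mask.sum())
    if n > 0:
        means = window[mask].mean(axis=0)
        return CoverColor(*means, n=n)

    gray = to_gray(img)
    global_mask = gray < config.background_cutoff
    n_global = int(global_mask.sum())
    if n_global == 0:
        raise NoBackgroundError(
            f"no pixel with gray < {config.background_cutoff} in the image")
    means = img[global_mask].astype(np.float64).mean(axis=0)
    return CoverColor(*means, n=n_global, fallback=True)


def cover_target(image: np.ndarray, region: TargetRegion,
                 color: CoverColor) -> np.ndarray:
    """Return a copy with the region's disc filled with the cover colour.

    Every pixel whose centre lies within ``region.radius`` of
    ``(xr, yr)`` is set to the 8-bit rounded cover colour; all other
    pixels are bit-identical to the input.
    """
    img = as_plate_image(image).copy()
    h, w = img.shape[:2]
    r = region.radius
    x0, x1 = max(0, int(np.floor(region.xr - r))), min(w, int(np.ceil(region.xr + r)) + 1)
    y0, y1 = max(0, int(np.floor(region.yr - r))), min(h, int(np.ceil(region.yr + r)) + 1)
    if x0 >= x1 or y0 >= y1:
        return img
    ys, xs = np.mgrid[y0:y1, x0:x1]
    # tolerance absorbs rounding at support points lying exactly on the circle
    disc = (xs - region.xr) ** 2 + (ys - region.yr) ** 2 <= r * r + 1e-6
    patch = img[y0:y1, x0:x1]
    patch[disc] = color.as_rgb8()
    return img


def rcta_augment(image: np.ndarray, annotations: list[BoxAnnotation],
                 config: RCTAConfig, iteration: int
                 ) -> tuple[np.ndarray, list[BoxAnnotation],
                            list[TargetRegion]]:
    """Erase ``iteration`` randomly chosen eligible targets.

    Segments once at ``config.seg_threshold``, filters to eligible
    regions, draws a seeded random permutation and covers its first
    ``min(iteration, n_eligible)`` regions one at a time — each cover
    colour is computed on the image as already modified by the earlier
    covers. Returns ``(augmented_image, surviving_annotations,
    covered_regions)``; an annotation survives unless its box centre lies
    inside a covered disc. Deterministic given ``(config.seed,
    iteration)``; for the same seed the covered set at a smaller
    iteration is a prefix of the covered set at a larger one.
    """
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    img = as_plate_image(image)
    h, w = img.shape[:2]
    eligible = filter_regions(
        find_target_regions(img, config.seg_threshold), config, w, h)
    if iteration > len(eligible):
        warnings.warn(
            f"requested {iteration} covers but only {len(eligible)} "
            "eligible regions; covering all of them", stacklevel=2)
    order = np.random.default_rng(config.seed).permutation(len(eligible))
    chosen = [eligible[i] for i in order[:min(iteration, len(eligible))]]

    out = img
    for region in chosen:
        color = compute_cover_color(out, region, config)
        out = cover_target(out, region, color)

    def erased(box: BoxAnnotation) -> bool:
        bx, by = box.center
        return any((bx - t.xr) ** 2 + (by - t.yr) ** 2 <= t.radius ** 2
                   for t in chosen)

    survivors = [b for b in annotations if not erased(b)]
    return out, survivors, chosen
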