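"""Traditional threshold-segmentation colony counters.

Two baselines commonly used for colony counting. The *simple* counter
binarizes the grayscale image at a user-chosen threshold and reports
every 8-connected foreground component as one colony — trivially fooled
by noise specks, since every above-threshold pixel group counts. The
*comprehensive* counter adds a pixel-area band filter on top, which
removes small noise but still merges adherent colonies into single
detections and drops fused clumps that exceed the band.

There is no sensible default threshold: it depends entirely on exposure
and contrast, so callers must choose it per image set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from skimage.measure import label, regionprops

from ._image import to_gray
from .annotations import BoxAnnotation


@dataclass(frozen=True)
class Detection:
    """One counted object: bounding box, centroid and pixel area."""

    box: BoxAnnotation
    centroid: tuple[float, float]
    area: float


def simple_threshold_count(image, threshold: float) -> list[Detection]:
    """One detection per 8-connected component above ``threshold``.

    Pixels with grayscale value strictly above the threshold are
    foreground; no filtering of any kind is applied.
    """
    if not (0 < threshold < 255):
        raise ValueError("threshold must be in (0, 255)")
    labels = label(to_gray(image) > threshold, connectivity=2)
    detections = []
    for prop in regionprops(labels):
        y1, x1, y2, x2 = prop.bbox
        cy, cx = prop.centroid
        detections.append(Detection(
            box=BoxAnnotation(0, x1, y1, x2, y2),
            centroid=(cx, cy),
            area=float(prop.area)))
    return detections


def comprehensive_threshold_count(image, threshold: float,
                                  min_area: float = 60.0,
                                  max_area: float = 3500.0
                                  ) -> list[Detection]:
    """Simple threshold counting plus an open pixel-area band filter.

    Only components with ``min_area < area < max_area`` (strict bounds)
    are kept — the same convention the cover algorithm uses for its
    effective range.
    """
    if not (0 <= min_area < max_area):
        raise ValueError("need 0 <= min_area < max_area")
    return [d for d in simple_threshold_count(image, threshold)
            if min_area < d.area < max_area]
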