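"""Score the two threshold-segmentation baselines against ground truth.

The simple counter reports every above-threshold component — so a few
hundred single-pixel noise specks become a few hundred false positives
and the accuracy collapses. The comprehensive counter filters components
to the (60, 3500) px^2 band, which removes the specks but still merges
adherent colony pairs into single detections.
"""

import numpy as np

from colonyforge import (PlateSpec, compute_metrics,
                         comprehensive_threshold_count, generate_plate,
                         match_detections, simple_threshold_count)
from colonyforge._image import to_gray

image, layout = generate_plate(
    PlateSpec(width=500, height=500, n_colonies=25,
              overlap_fraction=0.0, rim=False, seed=30))

# scatter isolated single-pixel bright specks over the background
rng = np.random.default_rng(31)
noisy = image.copy()
placed = 0
while placed < 150:
    x, y = rng.integers(1, 499, size=2)
    if (to_gray(noisy[y - 1:y + 2, x - 1:x + 2]) < 40).all():
        noisy[y, x] = 120
        placed += 1

for name, dets in (
        ("simple", simple_threshold_count(noisy, threshold=40)),
        ("comprehensive", comprehensive_threshold_count(
            noisy, threshold=40, min_area=60, max_area=3500))):
    counts = match_detections(dets, layout.boxes, rule="center-in-box")
    acc, tpr, fnr = compute_metrics(counts).as_percentages()
    print(f"{name:>13}: {len(dets):>3} detections  "
          f"TP={counts.tp} FP={counts.fp} FN={counts.fn}  "
          f"ACC={acc}% TPR={tpr}% FNR={fnr}%")

# ACC penalizes false positives; the area filter is what separates the
# two methods on noisy plates.
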