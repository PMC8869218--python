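"""Erase random colonies and watch the annotations follow.

The random-cover augmentation segments candidate colonies, filters them
to the effective area band (60, 3500) px^2 away from the border, and
overwrites k randomly chosen ones with the local background colour. Only
the boxes of erased colonies are dropped — the rest of the label file
carries over unchanged, which is what makes the augmentation cheap to
annotate.
"""

from colonyforge import (PlateSpec, RCTAConfig, find_target_regions,
                         generate_plate, rcta_augment)

image, layout = generate_plate(
    PlateSpec(width=640, height=648, n_colonies=40, seed=7))
config = RCTAConfig(seg_threshold=40, seed=7)

print(f"source plate: {len(layout)} colonies, "
      f"{len(find_target_regions(image, 40))} segmentable targets")
for k in (1, 3, 6, 10):
    augmented, kept, covered = rcta_augment(image, layout.boxes, config, k)
    n_regions = len(find_target_regions(augmented, 40))
    print(f"k={k:>2}: covered {len(covered)} targets, "
          f"{len(layout.boxes)} -> {len(kept)} boxes, "
          f"{n_regions} targets remain segmentable")

# The covered sets for growing k share a prefix (same seed), so the
# variants form a nested family of progressively emptier plates.
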