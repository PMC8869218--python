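"""Build a complete few-shot training dataset from two source plates.

Per source: the original plus cover variants with a growing number of
erased colonies; each variant quarter-cut; each quadrant kept at
identity plus three rotations. The pool is then split 90/10 into
training and validation and exported in darknet layout (images/,
labels/, train.txt, valid.txt, colony.names).

At full scale — five 2560 x 2590 sources, 12 variants — the same calls
yield 960 items and an 864/96 split.
"""

import tempfile
from pathlib import Path

from colonyforge import (PlateSpec, RCTAConfig, build_augmented_pool,
                         export_darknet, generate_plate, split_dataset)

sources = []
for seed in (1, 2):
    image, layout = generate_plate(
        PlateSpec(width=400, height=400, n_colonies=20, seed=seed))
    sources.append((image, layout.boxes))

pool = build_augmented_pool(sources, variants_per_source=4,
                            rcta_config=RCTAConfig(seed=0))
print(f"{len(sources)} sources x 4 variants x 4 quadrants x 4 rotations "
      f"= {len(pool)} items")

split = split_dataset(pool, train_fraction=0.9, seed=0)
print(f"90/10 split: {len(split.train)} train, "
      f"{len(split.validation)} validation")

with tempfile.TemporaryDirectory() as tmp:
    manifest = export_darknet(split, Path(tmp) / "dataset")
    n_images = len(list((Path(tmp) / "dataset" / "images").glob("*.png")))
    print(f"exported {n_images} images + labels; "
          f"train list {manifest['n_train']} lines, "
          f"valid list {manifest['n_validation']} lines")
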