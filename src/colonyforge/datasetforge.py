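"""Few-shot dataset assembly and YOLO-darknet label I/O.

Builds the full augmented training pool from a handful of annotated
source plates: per source, the original plus RCTA variants with a
growing number of covered colonies, each pool image quarter-cut into
four quadrants, each quadrant kept at identity plus the three lossless
rotations. Five sources with 12 variants each therefore yield
5 x 12 x 4 x 4 = 960 items, which a seeded 90/10 shuffle splits into
864 training and 96 validation items.

Labels use the YOLO-darknet plain-text format: one line per box,
``class cx cy w h``, centre and size normalized to the image dimensions,
six decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._image import write_png
from .annotations import BoxAnnotation
from .geomaug import quarter_cut, rotate_box, rotate_image
from .rcta import RCTAConfig, rcta_augment

_QUADRANT_NAMES = ("tl", "tr", "bl", "br")


@dataclass
class DatasetItem:
    """One augmented image with its annotations and provenance.

    ``provenance`` is ``(source_id, rcta_variant_index, quadrant,
    rotation)`` and uniquely identifies the item. The raster is held in
    ``image`` (in-memory pools), referenced by ``image_path`` (on-disk
    pools), or dropped entirely when only annotations are needed.
    """

    annotations: list[BoxAnnotation]
    provenance: tuple[int, int, int, int]
    width: int
    height: int
    image: np.ndarray | None = None
    image_path: Path | None = None

    @property
    def stem(self) -> str:
        s, v, q, r = self.provenance
        return f"src{s}_v{v}_{_QUADRANT_NAMES[q]}_r{r}"


@dataclass
class SplitResult:
    train: list[DatasetItem]
    validation: list[DatasetItem]
    train_fraction: float
    seed: int

    pool_size: int = field(init=False)

    def __post_init__(self) -> None:
        self.pool_size = len(self.train) + len(self.validation)


def build_augmented_pool(
    sources: list[tuple[np.ndarray, list[BoxAnnotation]]],
    variants_per_source: int,
    rcta_config: RCTAConfig = RCTAConfig(),
    min_kept_fraction: float = 0.3,
    out_dir: str | Path | None = None,
    keep_images: bool = True,
) -> list[DatasetItem]:
    """Expand annotated source plates into the full augmented pool.

    Per source: variant 0 is the original; variant v >= 1 is an RCTA
    augmentation with v covered colonies (the cover count grows with the
    variant index, so successive variants differ more and more from the
    source). Each variant is quarter-cut, and each quadrant is emitted at
    rotations 0, 90, 180 and 270. Pool size is always
    ``len(sources) * variants_per_source * 16``.

    With ``out_dir`` set, every item raster is written as a PNG there and
    items carry paths; otherwise rasters are kept in memory when
    ``keep_images`` (suitable for small plates) or dropped (annotation
    bookkeeping only, e.g. auditing pool composition at full scale).
    """
    if variants_per_source < 1:
        raise ValueError("variants_per_source must be >= 1")
    out = Path(out_dir) if out_dir is not None else None
    items: list[DatasetItem] = []
    for s_idx, (image, annotations) in enumerate(sources):
        for v in range(variants_per_source):
            if v == 0:
                var_img, var_ann = image, list(annotations)
            else:
                seed = np.random.default_rng(
                    [rcta_config.seed, s_idx, v]).integers(2 ** 31)
                cfg = replace(rcta_config, seed=int(seed))
                with warnings.catch_warnings():
                    warnings.simplefilter("always")
                    var_img, var_ann, _ = rcta_augment(
                        image, annotations, cfg, iteration=v)
            for q, (quad, q_ann) in enumerate(
                    quarter_cut(var_img, var_ann, min_kept_fraction)):
                qh, qw = quad.shape[:2]
                for rot in (0, 90, 180, 270):
                    if rot == 0:
                        r_img, r_ann = quad, q_ann
                        rw, rh = qw, qh
                    else:
                        r_img = rotate_image(quad, rot)
                        r_ann = [rotate_box(b, rot, qw, qh) for b in q_ann]
                        rh, rw = r_img.shape[:2]
                    item = DatasetItem(annotations=r_ann,
                                       provenance=(s_idx, v, q, rot),
                                       width=rw, height=rh)
                    if out is not None:
                        item.image_path = out / f"{item.stem}.png"
                        write_png(r_img, item.image_path)
                    elif keep_images:
                        item.image = np.ascontiguousarray(r_img)
                    items.append(item)
    return items


def split_dataset(pool: list[DatasetItem], train_fraction: float,
                  seed: int) -> SplitResult:
    """Seeded uniform shuffle; first ``round(frac * n)`` items train."""
    if not pool:
        raise ValueError("cannot split an empty pool")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(len(pool))
    n_train = int(round(train_fraction * len(pool)))
    return SplitResult(train=[pool[i] for i in order[:n_train]],
                       validation=[pool[i] for i in order[n_train:]],
                       train_fraction=train_fraction, seed=seed)


def read_yolo_labels(path: str | Path, image_width: int, image_height: int
                     ) -> list[BoxAnnotation]:
    """Parse a YOLO-darknet label file into pixel-space boxes."""
    boxes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 'class cx cy w h', "
                    f"got {line!r}")
            try:
                class_id = int(parts[0])
                cx, cy, w, h = map(float, parts[1:])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if not all(0.0 <= v <= 1.0 for v in (cx, cy, w, h)):
                raise ValueError(
                    f"{path}:{lineno}: normalized values out of [0, 1]")
            boxes.append(BoxAnnotation(
                class_id,
                (cx - w / 2) * image_width, (cy - h / 2) * image_height,
                (cx + w / 2) * image_width, (cy + h / 2) * image_height))
    return boxes


def write_yolo_labels(boxes: list[BoxAnnotation], path: str | Path,
                      image_width: int, image_height: int) -> None:
    """Write boxes as normalized ``class cx cy w h`` lines, 6 decimals."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for b in boxes:
            cx, cy = b.center
            fh.write(f"{b.class_id} "
                     f"{cx / image_width:.6f} {cy / image_height:.6f} "
                     f"{b.width / image_width:.6f} "
                     f"{b.height / image_height:.6f}\n")


def export_darknet(split: SplitResult, out_dir: str | Path) -> dict:
    """Write a darknet-style dataset directory and return its manifest.

    Layout: ``images/<stem>.png``, ``labels/<stem>.txt``, ``train.txt``
    and ``valid.txt`` path lists, and a single-class ``colony.names``.
    Items must carry a raster (``image``) or reference one
    (``image_path``).
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)

    def export_items(items: list[DatasetItem], list_name: str) -> list[str]:
        lines = []
        for item in items:
            img_path = out / "images" / f"{item.stem}.png"
            if item.image is not None:
                write_png(item.image, img_path)
            elif item.image_path is not None:
                img_path.write_bytes(Path(item.image_path).read_bytes())
            else:
                raise ValueError(f"item {item.stem} has no image data")
            write_yolo_labels(item.annotations,
                              out / "labels" / f"{item.stem}.txt",
                              item.width, item.height)
            lines.append(str(img_path))
        (out / list_name).write_text("".join(f"{p}\n" for p in lines))
        return lines

    train_lines = export_items(split.train, "train.txt")
    valid_lines = export_items(split.validation, "valid.txt")
    (out / "colony.names").write_text("colony\n")
    return {
        "out_dir": str(out),
        "n_train": len(train_lines),
        "n_validation": len(valid_lines),
        "train_list": str(out / "train.txt"),
        "valid_list": str(out / "valid.txt"),
        "names": str(out / "colony.names"),
    }
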