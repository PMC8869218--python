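# Methods

## The problem and the pipeline

Training an object detector to count bacterial colonies needs boxed
training images, and plate photographs are slow to collect (a culture
takes one to two days) and slow to annotate (hundreds of boxes per
plate). The pipeline implemented here multiplies a handful of annotated
source plates into a full dataset through three annotation-preserving
stages:

1. **Random cover augmentation** — erase k randomly chosen colonies by
   overwriting each with a disc of locally estimated background colour;
   drop exactly the boxes whose centres fall in covered discs.
2. **Quarter-cutting** — split each image into four equal quadrants,
   clipping boxes at the cut lines.
3. **Lossless rotation** — emit each quadrant at 0°/90°/180°/270°.

With 5 sources and 12 cover variants per source this yields
5 × 12 × 4 × 4 = 960 items; a seeded 90/10 shuffle gives 864/96
training/validation items.

## Random cover augmentation

**Candidate segmentation.** The RGB image is reduced to grayscale with
BT.601 luma weights (0.299 R + 0.587 G + 0.114 B) and binarized at a
user-set threshold τ (default 40 for the synthetic plates); each
8-connected foreground component becomes a candidate with its pixel
count as area and its exact minimum enclosing circle (Welzl's
algorithm over the component's convex-hull points) as centre/radius.
Segmentation at a fixed gray threshold finds only the
cleanly separated colonies — that is sufficient, because the candidates
only serve as erasure targets, not as a counting result.

**Filtering.** Candidates are kept when their area lies strictly inside
(a_min, a_max) — default (60, 3500) px², open interval — and their
centre lies in the central rectangle obtained by removing a 10 % margin
per side. The margin keeps the bright dish rim and border artefacts out
of the candidate pool. The same strict-open area convention is used by
the comprehensive threshold counter.

**Cover colour.** For a target centred at (x_r, y_r) the cover colour is
the per-channel mean over pixels in the window
[x_r, x_r+s) × [y_r, y_r+s), s = 20, whose grayscale value is below the
background cutoff (20). The window deliberately extends to the
bottom-right of the centre — it therefore overlaps the colony, and the
cutoff mask is what excludes colony pixels. The anchor is rounded to the
nearest integer pixel; windows are clipped at the image border. If no
window pixel qualifies (N = 0), the mean over all sub-cutoff pixels of
the image is used and flagged (`CoverColor.fallback`); an image with no
sub-cutoff pixel at all raises `NoBackgroundError`. This fallback is a
fail-safe of this toolkit's design: mid-pipeline exceptions would be
worse than a slightly less local colour.

**Covering and box pruning.** Covers are applied one at a time: each
cover's colour is computed on the image as already modified by the
earlier covers. A pixel is covered when its centre is within the
region's radius of the region centre (with a 10⁻⁶ tolerance on the
squared distance, absorbing rounding at circle support points).
Selection is a seeded uniform permutation of the eligible candidates,
truncated at k, so for a fixed seed the covered set at k₁ ≤ k₂ is a
prefix of the set at k₂ — variants form a nested family. A box is
pruned iff its centre lies in a covered disc; this is the automated
counterpart of removing redundant boxes by hand, and it makes
annotation bookkeeping exact: |boxes_in| = |boxes_out| + |boxes centred
in covered discs|.

## Geometric augmentation

**Rotation.** Only 90°/180°/270° are supported, implemented as
`numpy.rot90`, so rotation is exact (the per-value pixel histogram is
preserved). Boxes are rotated by mapping all four corners with the
centre-anchored transform and taking their axis-aligned hull; the
convention (under 90°, pixel (0, 0) of a w × h image lands at
(0, w − 1)) is pinned by a mask-rotation oracle in the tests. The
transform as commonly printed with a row-vector translation of
(−w/2·sin θ + h/2·cos θ + H/2) in y is inconsistent with a
centre-anchored rotation (it maps the image centre off-centre for 90°);
the corrected form above is used, and its x-translation term agrees
with the printed one.

**Quarter-cutting.** Quadrants are emitted in reading order, each
⌊w/2⌋ × ⌊h/2⌋ (odd trailing row/column dropped); for even dimensions
reassembling the quadrants reproduces the raster bit-exactly. A clipped
box is kept when its surviving area is at least `min_kept_fraction`
(default 0.3) of the original — slivers at cut lines would be
unlearnable labels. The scaling relation is exposed by
`relative_scale(D) = (√D, D)`: cutting into D parts grows a colony's
linear size relative to image width by √D and its relative area by D.
(The relation is sometimes printed with a bare factor D on the linear
ratio; the geometry, and the 2× doubling for D = 4, give √D. Both
factors are returned rather than silently picking one.)

## Dataset assembly

Variant v = 0 of each source is the original; variant v ≥ 1 applies
v covers (cover count grows with variant index, mirroring the
iteration-controlled behaviour of the cover algorithm at small scale).
Whether "12 variants" should include the original is a genuine
ambiguity; including it reproduces the 60-image pool from 5 sources
while keeping fully annotated originals in the pool, so that reading is
used. Per-variant RNG seeds are derived from (base seed, source index,
variant index) via `numpy.random.SeedSequence`, so pools are
reproducible and sources independent. The split shuffles at the
augmented-item level, as the pipeline is specified; note this leaks
source content across train/validation (quadrants of one source can end
up on both sides) — acceptable for augmentation bookkeeping, but a
source-level split would be needed for honest generalization estimates.

YOLO label I/O writes `class cx cy w h` normalized to six decimals;
round-tripping is bounded by 0.5 px at any plate-photograph scale.

## Threshold baselines and metrics

Both counters binarize BT.601 grayscale at a user-supplied threshold
(there is no defensible default — it depends on exposure, so the CLI
requires `--threshold`) and label 8-connected components. The simple
counter returns every component; the comprehensive counter keeps
components with area strictly inside (min_area, max_area). Their known
failure modes are reproduced by construction: single-pixel noise
inflates the simple count, and fused colony pairs exceed the band and
vanish from the comprehensive count.

Matching predictions to truth is not uniquely defined for counting;
two rules are provided. `iou-greedy` (default) accepts candidate pairs
in descending IoU order, one-to-one, at IoU ≥ 0.5 — greedy matching can
in principle be below the optimal assignment in cardinality; the test
suite compares it against an exhaustive oracle on small instances and
records discrepancies rather than hiding them. `center-in-box` matches
a prediction to an unmatched truth box containing its centroid, for
centroid-quality baselines. With TN ≡ 0 (background is not a countable
object), ACC = TP/(TP+FP+FN), TPR = TP/(TP+FN), FNR = FN/(TP+FN); hence
TPR + FNR = 1 and ACC ≤ TPR with equality iff FP = 0. Reported
percentages are rounded to one decimal.

Of the published per-method confusion tables used as reference inputs,
two rows print percentages inconsistent with their own counts: the
simple-threshold row prints TPR 73.8 %/FNR 26.2 % where TP = 3605,
FN = 1293 give 73.6 %/26.4 %, and the tiny-YOLOv3 row prints ACC 85.9 %
where the counts give 86.0 %. The formulas are implemented as defined;
those two printed values are documented as discrepant and excluded from
the arithmetic checks.

## Synthetic plate generator

The generator is the test bed for everything above. It emulates the
imaging regime the pipeline targets, not plate photography in general:

* **Background**: Gaussian noise, mean gray 12, σ = 2, truncated at 17
  so background plus channel jitter stays strictly below gray 20 — the
  band the cover-colour estimator relies on.
* **Colonies**: discs with a cosine falloff, intensity
  b + (p − b)·cos(π d / 2r) at distance d from the centre, peak p drawn
  uniformly from (90, 150). This gives the soft, low-contrast edges of
  real colonies; the default radius range (6, 28) px keeps thresholded
  component areas inside the effective (60, 3500) px² band.
* **Overlap**: a fraction f of colonies get an overlapping partner;
  overlap is created in pairs (round(f·n/2) attached colonies placed at
  0.55–0.9 of the radius sum from a distinct isolated anchor), so about
  f·n colonies end up with an overlapping neighbour.
* **Rim**: a 4 px bright ring at radius 0.98·min(w, h)/2, exercising
  the border-exclusion rule.
* **Channels**: the gray field replicated to RGB with independent
  integer jitter in [−2, 2], so the per-channel cover-colour means are
  genuinely distinguishable in tests.
* **Ground truth**: boxes are the integer hull of each disc (side
  within ±2 px of the diameter); layout placement is rejection sampling
  with bounded retries (`LayoutInfeasibleError` on failure), fully
  determined by the spec's seed.

Full-scale source plates (`make_source_plates`) default to five
2560 × 2590 images with 300 colonies each — a realistic density for the
30–300 CFU dilution regime plates are prepared in, and enough eligible
candidates for 11 cover variants.

What the generator does **not** model: agar texture, lighting gradients,
lens distortion, colony colour variation, condensation, or writing on
the dish. Tests passing on synthetic plates therefore validate the
pipeline's geometry, bookkeeping and determinism — not detector
performance on real photographs, which additionally depends on the
trained network and the imaging conditions.

## Numerical choices and problem sizes

* Strict-open interval bounds for all area bands; half-open pixel/box
  membership everywhere ([x1, x2) × [y1, y2)).
* Cover discs use exact pixel-centre-in-circle rasterization (plus the
  10⁻⁶ tolerance above), not a polygonal circle approximation.
* Minimum enclosing circles are exact (Welzl), deterministic, and
  reduced via convex hull for speed.
* `round()` decides split sizes (exact at 0.9 × 960 = 864).
* The test suite and the acceptance script run the full-scale pipeline
  (five 2560 × 2590 sources, 960 items) once each — about 40 s on one
  CPU; all other tests use plates of 200–800 px, where every oracle
  (per-pixel cover-colour reference, connected-component labelling,
  exhaustive matching on ≤ 5 × 5 instances, mask-rotation) is cheap.
* Pool building can drop rasters (`keep_images=False`) because 960
  full-scale arrays would need ~5 GB; with an `out_dir` it streams
  images to disk instead.
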