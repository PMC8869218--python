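# colonyforge

Few-shot dataset construction and evaluation for bacterial colony
counting images.

Counting colony-forming units on agar plates is a standard task in food
testing, water monitoring and clinical microbiology, but plate
photographs are expensive to annotate: a single plate can hold hundreds
of low-contrast, overlapping colonies, and training an object detector
the usual way needs hundreds of such images. `colonyforge` implements an
augmentation pipeline that turns a handful of annotated plates into a
full detection dataset, the two classical threshold-segmentation
counters used as baselines, counting-specific evaluation metrics, and a
synthetic plate generator so everything is testable end to end without
any real photographs.

## What it does

**Random cover augmentation.** The central idea is that erasing colonies
makes a structurally new training image whose labels need pruning, not
redrawing. Candidate colonies are found by threshold segmentation,
filtered to an effective pixel-area band (default the open interval
(60, 3500) px²) and to the central region of the image, and k randomly
chosen candidates are each overwritten with a disc of the local
background colour. The cover colour for a target centred at (x_r, y_r)
is the per-channel mean of the near-black background pixels in the
window [x_r, x_r+s) × [y_r, y_r+s), s = 20:

    R_mean = Σ R(x, y) / N   over window pixels with gray(x, y) < 20,

and likewise G_mean, B_mean; N is the number of qualifying pixels.
Annotation boxes whose centre falls inside a covered disc are dropped
automatically; all other boxes carry over unchanged.

**Geometric augmentation.** Quarter-cutting divides a plate image into
four equal quadrants — a colony's absolute size is unchanged, but its
size relative to the image grows by √D for a division into D parts (2×
for quadrants), which makes small targets learnable. Boxes are clipped
at the cut lines and kept when ≥ 30 % of their area survives. Rotations
by 90°/180°/270° are lossless; boxes are rotated with the
centre-anchored transform

    x_R =  (x_o − w/2)·cos θ + (y_o − h/2)·sin θ + W/2
    y_R = −(x_o − w/2)·sin θ + (y_o − h/2)·cos θ + H/2.

**Dataset assembly.** Per source: the original plus RCTA-style variants
with a growing cover count, quarter-cut, identity + three rotations —
5 sources × 12 variants × 4 quadrants × 4 orientations = 960 items,
split 90/10 into 864 training and 96 validation items, exported in
darknet layout with YOLO labels (`class cx cy w h`, normalized).

**Baselines and metrics.** `simple_threshold_count` reports every
8-connected component above a gray threshold; `comprehensive_threshold_count`
adds the area-band filter. Counters are scored with TN fixed at 0:

    ACC = TP/(TP+FP+FN),  TPR = TP/(TP+FN),  FNR = FN/(TP+FN).

## Worked example

```bash
python examples/05_threshold_baselines.py
```

```
       simple: 175 detections  TP=25 FP=150 FN=0  ACC=14.3% TPR=100.0% FNR=0.0%
comprehensive:  25 detections  TP=25 FP=0 FN=0  ACC=100.0% TPR=100.0% FNR=0.0%
```

On a synthetic plate with 25 colonies and 150 single-pixel noise specks,
the simple counter reports every speck as a colony (150 false positives,
ACC 14.3 %); the area-band filter removes all of them and recovers every
true colony. `examples/` contains one such narrative script per
capability (generation, cover augmentation, cut/rotate, dataset build,
baselines); a thin CLI (`colonyforge generate|augment|cut|rotate|build|
count|evaluate|analyze`) wraps the same calls for shell use.

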