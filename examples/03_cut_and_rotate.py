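"""Quarter-cut and rotate a plate, carrying boxes along exactly.

Cutting a W x H image into four quadrants leaves each colony's absolute
size unchanged but halves the image side, so the colony's size relative
to the image doubles — which is what makes small targets learnable.
Rotations by 90/180/270 degrees are lossless array moves.
"""

from colonyforge import (PlateSpec, generate_plate, quarter_cut,
                         relative_scale, rotate_box, rotate_image)

image, layout = generate_plate(
    PlateSpec(width=640, height=648, n_colonies=30, seed=3))
h, w = image.shape[:2]
print(f"source: {w} x {h}, {len(layout.boxes)} boxes")

for name, (quad, boxes) in zip(("top-left", "top-right",
                                "bottom-left", "bottom-right"),
                               quarter_cut(image, layout.boxes)):
    print(f"  {name}: {quad.shape[1]} x {quad.shape[0]}, "
          f"{len(boxes)} boxes survive clipping")

linear, area = relative_scale(4)
print(f"dividing into 4 parts grows relative colony size "
      f"x{linear:.0f} (linear), x{area:.0f} (area)")

quad, boxes = quarter_cut(image, layout.boxes)[0]
rot = rotate_image(quad, 90)
rot_boxes = [rotate_box(b, 90, quad.shape[1], quad.shape[0]) for b in boxes]
print(f"rotated quadrant: {rot.shape[1]} x {rot.shape[0]}, "
      f"{len(rot_boxes)} boxes, areas preserved: "
      f"{all(a.area == b.area for a, b in zip(boxes, rot_boxes))}")
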