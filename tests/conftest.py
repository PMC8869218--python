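import numpy as np
import pytest

from colonyforge import PlateSpec, generate_plate


@pytest.fixture(scope="session")
def plate400():
    """A 400x400 plate with 20 colonies, some overlapping, with rim."""
    spec = PlateSpec(width=400, height=400, n_colonies=20, seed=3)
    image, layout = generate_plate(spec)
    return spec, image, layout


@pytest.fixture(scope="session")
def plate_isolated():
    """A plate whose colonies are all isolated (no overlap), no rim."""
    spec = PlateSpec(width=420, height=420, n_colonies=15,
                     overlap_fraction=0.0, rim=False, seed=11)
    image, layout = generate_plate(spec)
    return spec, image, layout


def make_disc_image(width, height, discs, background=10, peak=120):
    """Hard-edged bright discs on a constant background (uint8 RGB).

    ``discs`` is a list of (cx, cy, r). Unlike the generator's soft
    colonies these have exact pixel areas, handy for area arithmetic.
    """
    img = np.full((height, width, 3), background, dtype=np.uint8)
    ys, xs = np.mgrid[0:height, 0:width]
    for cx, cy, r in discs:
        mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
        img[mask] = peak
    return img
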