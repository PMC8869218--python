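import math
import warnings

import numpy as np
import pytest
from scipy import ndimage

from colonyforge import (BoxAnnotation, NoBackgroundError, PlateSpec,
                         RCTAConfig, TargetRegion, compute_cover_color,
                         cover_target, filter_regions, find_target_regions,
                         generate_plate, rcta_augment)
from colonyforge._image import to_gray

from conftest import make_disc_image


def brute_force_cover_color(image, xr, yr, s, cutoff):
    """Exhaustive per-pixel reference for the windowed background mean."""
    h, w = image.shape[:2]
    sums = np.zeros(3)
    n = 0
    for y in range(int(round(yr)), min(int(round(yr)) + s, h)):
        for x in range(int(round(xr)), min(int(round(xr)) + s, w)):
            r, g, b = (float(v) for v in image[y, x])
            if 0.299 * r + 0.587 * g + 0.114 * b < cutoff:
                sums += (r, g, b)
                n += 1
    return (sums / n if n else None), n


class TestFindTargetRegions:
    def test_uniform_image_has_no_targets(self):
        img = np.full((50, 50, 3), 10, dtype=np.uint8)
        assert find_target_regions(img, 40) == []

    def test_single_disc_found_at_center(self):
        img = make_disc_image(120, 120, [(60, 55, 20)])
        regions = find_target_regions(img, 40)
        assert len(regions) == 1
        r = regions[0]
        assert math.hypot(r.xr - 60, r.yr - 55) <= 2
        assert 19 <= r.radius <= 21

    def test_component_count_matches_ndimage_oracle(self, plate400):
        _, img, _ = plate400
        regions = find_target_regions(img, 40)
        _, n = ndimage.label(to_gray(img) > 40,
                             structure=np.ones((3, 3)))
        assert len(regions) == n

    def test_separate_vs_fused_discs(self):
        separate = make_disc_image(200, 100, [(50, 50, 15), (150, 50, 15)])
        fused = make_disc_image(200, 100, [(80, 50, 15), (100, 50, 15)])
        assert len(find_target_regions(separate, 40)) == 2
        assert len(find_target_regions(fused, 40)) == 1

    def test_region_areas_are_pixel_counts(self):
        img = make_disc_image(100, 100, [(50, 50, 10)])
        region = find_target_regions(img, 40)[0]
        assert region.area == (to_gray(img) > 40).sum()


class TestFilterRegions:
    CFG = RCTAConfig(area_range=(60, 3500), margin_fraction=0.10)

    def region(self, x=500, y=500, area=100):
        return TargetRegion(xr=x, yr=y, radius=10, area=area)

    @pytest.mark.parametrize("area,kept", [
        (60, False), (61, True), (3499, True), (3500, False), (59, False),
    ])
    def test_area_band_is_strict_open(self, area, kept):
        out = filter_regions([self.region(area=area)], self.CFG, 1000, 1000)
        assert (len(out) == 1) is kept

    def test_border_region_excluded_regardless_of_area(self):
        assert filter_regions([self.region(x=5, y=5)],
                              self.CFG, 1000, 1000) == []

    @pytest.mark.parametrize("x,kept", [
        (99.9, False), (100.0, True), (899.9, True), (900.0, False),
    ])
    def test_central_rectangle_is_half_open(self, x, kept):
        out = filter_regions([self.region(x=x)], self.CFG, 1000, 1000)
        assert (len(out) == 1) is kept

    def test_order_preserved(self):
        regions = [self.region(area=a) for a in (100, 200, 300)]
        assert filter_regions(regions, self.CFG, 1000, 1000) == regions


class TestComputeCoverColor:
    def test_constant_background_window(self):
        img = np.full((100, 100, 3), 10, dtype=np.uint8)
        cfg = RCTAConfig()
        color = compute_cover_color(
            img, TargetRegion(30, 30, 5, 100), cfg)
        assert (color.r_mean, color.g_mean, color.b_mean) == (10, 10, 10)
        assert color.n == cfg.window_size ** 2
        assert not color.fallback

    def test_bright_pixels_excluded_from_mean(self):
        img = np.full((60, 60, 3), 10, dtype=np.uint8)
        img[20:25, 20:40] = 200  # 100 bright pixels inside the window
        color = compute_cover_color(
            img, TargetRegion(20, 20, 5, 100), RCTAConfig())
        expected, n = brute_force_cover_color(img, 20, 20, 20, 20)
        assert n == 300
        assert color.n == n
        np.testing.assert_allclose(
            (color.r_mean, color.g_mean, color.b_mean), expected)

    def test_corner_window_is_clipped(self, plate400):
        _, img, _ = plate400
        cfg = RCTAConfig()
        region = TargetRegion(395, 392, 3, 50)
        color = compute_cover_color(img, region, cfg)
        expected, n = brute_force_cover_color(img, 395, 392,
                                              cfg.window_size, 20)
        assert 0 < n < cfg.window_size ** 2
        assert color.n == n
        np.testing.assert_allclose(
            (color.r_mean, color.g_mean, color.b_mean), expected)

    def test_random_windows_match_oracle(self, plate400):
        _, img, _ = plate400
        cfg = RCTAConfig()
        rng = np.random.default_rng(42)
        for _ in range(60):
            xr = float(rng.uniform(-5, 405))
            yr = float(rng.uniform(-5, 405))
            region = TargetRegion(max(xr, 0), max(yr, 0), 3, 50)
            expected, n = brute_force_cover_color(
                img, region.xr, region.yr, cfg.window_size, 20)
            color = compute_cover_color(img, region, cfg)
            assert color.n == n or color.fallback
            if n:
                np.testing.assert_allclose(
                    (color.r_mean, color.g_mean, color.b_mean), expected)

    def test_fallback_to_global_mean(self):
        img = np.full((100, 100, 3), 10, dtype=np.uint8)
        img[40:80, 40:80] = 200  # window fully bright
        color = compute_cover_color(
            img, TargetRegion(50, 50, 5, 100), RCTAConfig())
        assert color.fallback
        assert color.r_mean == 10
        assert color.n == 100 * 100 - 40 * 40

    def test_no_background_anywhere_raises(self):
        img = np.full((30, 30, 3), 100, dtype=np.uint8)
        with pytest.raises(NoBackgroundError):
            compute_cover_color(img, TargetRegion(5, 5, 2, 10), RCTAConfig())


class TestCoverTarget:
    def test_zero_radius_changes_at_most_center_pixel(self):
        img = make_disc_image(50, 50, [(25, 25, 10)])
        from colonyforge import CoverColor
        out = cover_target(img, TargetRegion(25, 25, 0, 1),
                           CoverColor(10, 10, 10, 5))
        assert (out != img).any(axis=2).sum() <= 1

    def test_interior_disc_pixel_diff(self):
        img = make_disc_image(100, 100, [(50, 50, 12)])
        from colonyforge import CoverColor
        region = TargetRegion(50, 50, 12, 400)
        out = cover_target(img, region, CoverColor(7, 8, 9, 5))
        changed = (out != img).any(axis=2)
        ys, xs = np.mgrid[0:100, 0:100]
        disc = (xs - 50) ** 2 + (ys - 50) ** 2 <= 144 + 1e-6
        # every pixel in the disc is the cover colour, nothing else moved
        assert (out[disc] == (7, 8, 9)).all()
        assert not changed[~disc].any()

    def test_covered_component_disappears_on_resegmentation(self):
        img = make_disc_image(150, 150, [(60, 60, 15), (110, 110, 10)])
        regions = find_target_regions(img, 40)
        assert len(regions) == 2
        cfg = RCTAConfig()
        target = regions[0]
        out = cover_target(img, target,
                           compute_cover_color(img, target, cfg))
        remaining = find_target_regions(out, 40)
        assert len(remaining) == 1
        assert math.hypot(remaining[0].xr - 110, remaining[0].yr - 110) < 2


class TestRctaAugment:
    def test_zero_iterations_is_identity(self, plate400):
        _, img, layout = plate400
        out, kept, covered = rcta_augment(img, layout.boxes,
                                          RCTAConfig(seed=0), 0)
        assert np.array_equal(out, img)
        assert kept == layout.boxes
        assert covered == []

    def test_exactly_k_boxes_removed(self, plate_isolated):
        _, img, layout = plate_isolated
        out, kept, covered = rcta_augment(img, layout.boxes,
                                          RCTAConfig(seed=2), 3)
        assert len(covered) == 3
        assert len(kept) == len(layout.boxes) - 3
        # removed boxes are exactly those with centres in covered discs
        for box in layout.boxes:
            bx, by = box.center
            inside = any((bx - t.xr) ** 2 + (by - t.yr) ** 2
                         <= t.radius ** 2 for t in covered)
            assert (box not in kept) == inside

    def test_full_coverage_empties_annotations(self):
        spec = PlateSpec(width=400, height=400, n_colonies=10,
                         overlap_fraction=0.0, rim=False, seed=13)
        img, layout = generate_plate(spec)
        cfg = RCTAConfig(margin_fraction=0.0, seed=0)
        eligible = filter_regions(find_target_regions(img, 40), cfg,
                                  400, 400)
        assert len(eligible) == 10
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, kept, covered = rcta_augment(img, layout.boxes, cfg, 10)
        assert len(covered) == 10
        assert kept == []

    def test_locality_outside_covered_discs(self, plate400):
        _, img, layout = plate400
        for seed in range(5):
            out, _, covered = rcta_augment(img, layout.boxes,
                                           RCTAConfig(seed=seed), 4)
            ys, xs = np.mgrid[0:400, 0:400]
            union = np.zeros((400, 400), dtype=bool)
            for t in covered:
                union |= ((xs - t.xr) ** 2 + (ys - t.yr) ** 2
                          <= t.radius ** 2 + 1e-6)
            assert np.array_equal(out[~union], img[~union])

    def test_monotone_erasure_prefix(self, plate400):
        _, img, layout = plate400
        cfg = RCTAConfig(seed=7)
        prev_covered, prev_kept = [], layout.boxes
        for k in range(0, 8):
            _, kept, covered = rcta_augment(img, layout.boxes, cfg, k)
            assert covered[:len(prev_covered)] == prev_covered
            assert len(kept) <= len(prev_kept)
            prev_covered, prev_kept = covered, kept

    def test_annotation_conservation(self, plate400):
        _, img, layout = plate400
        _, kept, covered = rcta_augment(img, layout.boxes,
                                        RCTAConfig(seed=3), 5)
        erased = [b for b in layout.boxes
                  if any((b.center[0] - t.xr) ** 2
                         + (b.center[1] - t.yr) ** 2 <= t.radius ** 2
                         for t in covered)]
        assert len(layout.boxes) == len(kept) + len(erased)

    def test_requesting_too_many_covers_warns_and_caps(self):
        img = make_disc_image(200, 200, [(100, 100, 15)])
        with pytest.warns(UserWarning, match="eligible"):
            _, _, covered = rcta_augment(img, [], RCTAConfig(seed=0), 99)
        assert len(covered) == 1

    def test_deterministic_given_seed(self, plate400):
        _, img, layout = plate400
        a = rcta_augment(img, layout.boxes, RCTAConfig(seed=5), 4)
        b = rcta_augment(img, layout.boxes, RCTAConfig(seed=5), 4)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1] and a[2] == b[2]
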