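"""Cavity segmentation: brute-force oracle equivalence and the
noise-removal / surface-exclusion rules."""

import numpy as np
import pytest

from lumiphantom.extraction import (CavityMask, apply_surface_exclusion,
                                    detect_bright_regions,
                                    remove_baseline_noise, to_grayscale)

PIXEL = 0.01  # mm; detection radius 0.1 mm -> 10 px


def naive_local_mean_mask(img, radius_px, threshold):
    """Reference O(N r^2) implementation: per-pixel circular-neighborhood
    mean over the intersection with the image, center pixel included."""
    h, w = img.shape
    n = int(np.floor(radius_px))
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            total = 0.0
            count = 0
            for di in range(-n, n + 1):
                for dj in range(-n, n + 1):
                    if di * di + dj * dj > radius_px * radius_px:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        total += float(img[ii, jj])
                        count += 1
            out[i, j] = img[i, j] - total / count >= threshold
    return out


def disk_image(shape, center, radius_px, background, value):
    img = np.full(shape, background, dtype=np.uint8)
    ii, jj = np.mgrid[:shape[0], :shape[1]]
    img[(ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius_px ** 2] = value
    return img


class TestDetectBrightRegions:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        got = detect_bright_regions(img, PIXEL).mask
        want = naive_local_mean_mask(img, 10.0, 10.0)
        np.testing.assert_array_equal(got, want)

    def test_uniform_image_empty(self):
        img = np.full((50, 50), 120, dtype=np.uint8)
        assert detect_bright_regions(img, PIXEL).mask.sum() == 0

    def test_disk_above_threshold_detected(self):
        img = disk_image((64, 64), (32, 32), 5, 100, 120)
        mask = detect_bright_regions(img, PIXEL).mask
        ii, jj = np.mgrid[:64, :64]
        disk = (ii - 32) ** 2 + (jj - 32) ** 2 <= 25
        assert mask[disk].all()
        np.testing.assert_array_equal(mask, naive_local_mean_mask(img, 10.0, 10.0))

    def test_nine_level_disk_not_detected(self):
        """The rule is 'by 10 or more': a +9 disk stays below it because
        the local mean never drops 1 full level below the disk value."""
        img = disk_image((64, 64), (32, 32), 5, 100, 109)
        assert detect_bright_regions(img, PIXEL).mask.sum() == 0

    def test_plus_ten_boundary_matches_oracle(self):
        """Rule boundary arithmetic: a +10 feature inflates its own local
        mean, so its excess is 10(1 - area fraction) < 10 and it is never
        marked — the increment must strictly exceed the threshold. The
        production path must agree bit-for-bit with the brute-force rule
        in this boundary regime."""
        small = disk_image((64, 64), (16, 16), 3, 100, 110)
        got = detect_bright_regions(small, PIXEL).mask
        np.testing.assert_array_equal(got,
                                      naive_local_mean_mask(small, 10.0, 10.0))
        assert got.sum() == 0
        plateau = np.full((64, 64), 100, dtype=np.uint8)
        plateau[10:54, 10:54] = 110
        got2 = detect_bright_regions(plateau, PIXEL).mask
        np.testing.assert_array_equal(got2,
                                      naive_local_mean_mask(plateau, 10.0, 10.0))
        assert not got2[32, 32]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        img = rng.integers(0, 256, size=(48, 48), dtype=np.uint8)
        prev = detect_bright_regions(img, PIXEL, threshold=5.0).mask
        for thr in (8.0, 10.0, 15.0, 30.0):
            cur = detect_bright_regions(img, PIXEL, threshold=thr).mask
            assert not (cur & ~prev).any()
            prev = cur

    def test_threshold_monotonicity_property(self):
        """For arbitrary images, raising the threshold never adds pixels
        and the strict rule boundary holds exactly."""
        from hypothesis import given, settings
        from hypothesis.extra import numpy as hnp

        @settings(max_examples=25, deadline=None, derandomize=True)
        @given(hnp.arrays(np.uint8, (16, 16)))
        def check(img):
            lo = detect_bright_regions(img, 0.033, threshold=9.0).mask
            hi = detect_bright_regions(img, 0.033, threshold=10.0).mask
            assert not (hi & ~lo).any()
            np.testing.assert_array_equal(
                hi, naive_local_mean_mask(img, 0.1 / 0.033, 10.0))

        check()

    def test_radius_below_pixel_rejected(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(ValueError, match="radius"):
            detect_bright_regions(img, pixel_size=0.2, radius=0.1)


class TestToGrayscale:
    def test_identity_for_grayscale(self):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        assert to_grayscale(img) is img

    def test_equal_channels(self):
        rgb = np.full((5, 5, 3), 77, dtype=np.uint8)
        np.testing.assert_array_equal(to_grayscale(rgb),
                                      np.full((5, 5), 77, np.uint8))

    def test_pure_red_luminance(self):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        rgb[..., 0] = 255
        expected = int(round(0.2125 * 255))
        assert (to_grayscale(rgb) == expected).all()

    def test_unsupported_depth(self):
        with pytest.raises(ValueError, match="bit depth"):
            to_grayscale(np.zeros((5, 5), dtype=np.uint16))


class TestBaselineRemoval:
    @staticmethod
    def mask_from(px_lists, shape=(20, 20)):
        m = np.zeros(shape, dtype=bool)
        for pixels in px_lists:
            for r, c in pixels:
                m[r, c] = True
        return CavityMask(mask=m, pixel_size=PIXEL)

    def test_smaller_than_pre_mean_removed(self):
        """Pre components of 2 and 4 px (mean 3): a 2-px post component is
        removed, a 5-px one survives."""
        pre = self.mask_from([[(1, 1), (1, 2)],
                              [(10, 10), (10, 11), (11, 10), (11, 11)]])
        post = self.mask_from([[(3, 3), (3, 4)],
                               [(15, 1), (15, 2), (15, 3), (16, 1), (16, 2)]])
        cleaned = remove_baseline_noise(post, pre)
        assert cleaned.mask.sum() == 5
        assert cleaned.mask[15, 1] and not cleaned.mask[3, 3]

    def test_equal_to_mean_retained(self):
        pre = self.mask_from([[(1, 1), (1, 2), (2, 1)]])  # mean area 3
        post = self.mask_from([[(8, 8), (8, 9), (9, 8)]])  # exactly 3
        assert remove_baseline_noise(post, pre).mask.sum() == 3

    def test_empty_pre_is_identity(self):
        pre = self.mask_from([])
        post = self.mask_from([[(3, 3)]])
        np.testing.assert_array_equal(remove_baseline_noise(post, pre).mask,
                                      post.mask)

    def test_diagonal_components_are_connected(self):
        pre = self.mask_from([[(0, 0), (1, 1)]])  # 8-connected: one 2-px blob
        post = self.mask_from([[(5, 5)]])          # 1 px < mean 2 -> removed
        assert remove_baseline_noise(post, pre).mask.sum() == 0

    def test_incongruent_masks_rejected(self):
        with pytest.raises(ValueError, match="congruent"):
            remove_baseline_noise(
                CavityMask(np.zeros((5, 5), bool), PIXEL),
                CavityMask(np.zeros((6, 5), bool), PIXEL))


class TestSurfaceExclusion:
    def make(self, depth_mm):
        m = np.zeros((60, 30), dtype=bool)
        m[int(depth_mm / PIXEL), 10] = True
        return CavityMask(mask=m, pixel_size=PIXEL, surface_row=0)

    def test_shallow_cavity_removed(self):
        assert apply_surface_exclusion(self.make(0.10)).mask.sum() == 0

    def test_deep_cavity_retained(self):
        assert apply_surface_exclusion(self.make(0.25)).mask.sum() == 1

    def test_zero_depth_identity(self):
        m = self.make(0.10)
        np.testing.assert_array_equal(apply_surface_exclusion(m, 0.0).mask,
                                      m.mask)

    def test_idempotent(self):
        m = CavityMask(np.random.default_rng(1).random((60, 30)) > 0.7,
                       pixel_size=PIXEL)
        once = apply_surface_exclusion(m)
        twice = apply_surface_exclusion(once)
        np.testing.assert_array_equal(once.mask, twice.mask)


def test_component_stats_areas_and_depths():
    m = np.zeros((30, 30), dtype=bool)
    m[20:22, 5:7] = True  # 4 px at depth ~0.2 mm
    stats = CavityMask(mask=m, pixel_size=PIXEL,
                       surface_row=0).component_stats()
    assert len(stats) == 1
    assert stats.loc[0, "area_mm2"] == pytest.approx(4 * PIXEL ** 2)
    assert stats.loc[0, "depth_mm"] == pytest.approx(0.205, abs=0.01)
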