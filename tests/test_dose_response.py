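"""Registration, fluence binning, range pooling and sigmoid fitting."""

import numpy as np
import pytest

from lumiphantom.dose_response import (DEFAULT_FIT_RANGES, CavitationCurve,
                                       FitRange, align_by_centroid,
                                       average_curves, cavitation_curve,
                                       fit_sigmoid, pool_curves,
                                       resample_axial_slice, sigmoid)
from lumiphantom.extraction import CavityMask

PAPER = (0.24, 1.37, 2.0, -0.005)


class TestAlignment:
    voxel = 0.05
    pixel = 0.01

    def make_mask(self, shift_px=0):
        m = np.zeros((200, 301), dtype=bool)
        m[60:80, 140 + shift_px:160 + shift_px] = True
        return CavityMask(mask=m, pixel_size=self.pixel, surface_row=0)

    def gradient_slice(self):
        # lateral-by-depth field, smooth in both axes
        lat = np.linspace(0, 1, 61)[:, None]
        dep = np.linspace(1, 2, 100)[None, :]
        return lat * dep

    def test_centered_mask_zero_shift(self):
        fl, shift = align_by_centroid(self.make_mask(0),
                                      self.gradient_slice(), self.voxel)
        assert abs(shift) < self.pixel

    def test_translated_mask_recovers_shift(self):
        """Translating the cavity field +0.5 mm moves the reported centroid
        offset by +0.5 mm (the fluence axis follows the cavities)."""
        _, s0 = align_by_centroid(self.make_mask(0), self.gradient_slice(),
                                  self.voxel)
        _, s1 = align_by_centroid(self.make_mask(50), self.gradient_slice(),
                                  self.voxel)
        assert s1 - s0 == pytest.approx(0.5, abs=self.pixel)

    def test_uniform_field_resamples_exactly(self):
        uniform = np.full((61, 100), 3.7)
        fl, _ = align_by_centroid(self.make_mask(0), uniform, self.voxel)
        np.testing.assert_allclose(fl, 3.7)

    def test_empty_mask_warns_and_centers(self):
        empty = CavityMask(mask=np.zeros((50, 61), bool),
                           pixel_size=self.pixel)
        with pytest.warns(UserWarning, match="empty mask"):
            _, shift = align_by_centroid(empty, self.gradient_slice(),
                                         self.voxel)
        assert shift == 0.0

    def test_resample_is_bilinear_in_depth(self):
        """A linear-in-depth field stays linear after resampling."""
        sl = np.tile(np.linspace(0.0, 2.0, 100)[None, :], (61, 1))
        img = resample_axial_slice(sl, self.voxel, (150, 61), self.pixel)
        col = img[:, 30]
        diffs = np.diff(col[5:140])
        assert np.allclose(diffs, diffs[0], atol=1e-9)


class TestCavitationCurve:
    def test_all_true_mask(self, rng):
        fl = rng.uniform(0, 3, size=(50, 60))
        c = cavitation_curve(np.ones((50, 60), bool), fl)
        assert np.all(c.ratio[c.n_pixels > 0] == 1.0)

    def test_empty_mask(self, rng):
        fl = rng.uniform(0, 3, size=(50, 60))
        c = cavitation_curve(np.zeros((50, 60), bool), fl)
        assert np.all(c.ratio[c.n_pixels > 0] == 0.0)
        assert np.isnan(c.ratio[c.n_pixels == 0]).all()

    def test_independent_bernoulli_mask(self, rng):
        """A Bernoulli(0.2) mask independent of fluence gives ratio 0.2 in
        every well-populated bin (3 sigma binomial)."""
        fl = rng.uniform(0, 0.5, size=(400, 500))  # 5 bins, ~40k px each
        m = rng.random((400, 500)) < 0.2
        c = cavitation_curve(m, fl)
        for r, n in zip(c.ratio, c.n_pixels):
            if n >= 10_000:
                assert abs(r - 0.2) <= 3 * np.sqrt(0.2 * 0.8 / n)

    def test_surface_band_excluded_from_both_sides(self):
        fl = np.full((30, 10), 0.25)
        m = np.zeros((30, 10), bool)
        m[:5, :] = True  # cavities only inside the excluded band
        c = cavitation_curve(m, fl, exclude_rows=5)
        assert np.all(c.ratio[c.n_pixels > 0] == 0.0)
        assert c.n_pixels.sum() == 25 * 10

    def test_numerator_never_exceeds_denominator(self, rng):
        for _ in range(5):
            fl = rng.uniform(0, 2, size=(40, 40))
            m = rng.random((40, 40)) < rng.uniform(0, 1)
            c = cavitation_curve(m, fl)
            n_cav = np.nan_to_num(c.ratio) * c.n_pixels
            assert np.all(n_cav <= c.n_pixels + 1e-9)


def make_curve(edges, ratio, n=1000):
    ratio = np.asarray(ratio, dtype=float)
    return CavitationCurve(bin_edges=np.asarray(edges, float), ratio=ratio,
                           n_pixels=np.full(ratio.size, n))


class TestPooling:
    def test_range_assignment(self):
        curves = {
            2.0: make_curve(np.arange(0, 2.11, 0.1), np.full(21, 0.1)),
            3.0: make_curve(np.arange(0, 3.11, 0.1), np.full(31, 0.2)),
        }
        ranges = (FitRange(2.0, 0.0, 2.0), FitRange(3.0, 2.0, 3.0))
        x, y, n = pool_curves(curves, ranges)
        assert x.min() == pytest.approx(0.05)
        assert x.max() == pytest.approx(2.95)
        # the F0=3 curve contributes no bin below 2
        assert np.all(y[x < 2.0] == 0.1) and np.all(y[x > 2.0] == 0.2)

    def test_default_ranges_cover_zero_to_five(self):
        ivals = sorted((fr.lo, fr.hi) for fr in DEFAULT_FIT_RANGES)
        assert ivals[0][0] == 0.0 and ivals[-1][1] == 5.0
        for (_, hi1), (lo2, _) in zip(ivals, ivals[1:]):
            assert hi1 == lo2

    def test_single_curve_identity(self):
        c = make_curve(np.arange(0, 1.01, 0.1), np.linspace(0, 1, 10))
        x, y, n = pool_curves({2.0: c}, (FitRange(2.0, 0.0, 1.0),))
        np.testing.assert_allclose(y, c.ratio)

    def test_overlapping_ranges_rejected(self):
        c = make_curve(np.arange(0, 1.01, 0.1), np.zeros(10))
        with pytest.raises(ValueError, match="overlap"):
            pool_curves({2.0: c, 3.0: c},
                        (FitRange(2.0, 0.0, 1.0), FitRange(3.0, 0.5, 1.5)))


class TestAverageCurves:
    def test_mean_and_sd(self):
        a = make_curve([0, 0.1, 0.2], [0.1, 0.3])
        b = make_curve([0, 0.1, 0.2], [0.3, 0.5])
        avg = average_curves([a, b])
        np.testing.assert_allclose(avg.ratio, [0.2, 0.4])
        np.testing.assert_allclose(avg.sd, np.std([[0.1, 0.3], [0.3, 0.5]],
                                                  axis=0, ddof=1))
        assert avg.n_pixels.tolist() == [2000, 2000]


class TestFitSigmoid:
    def test_noise_free_recovery(self):
        """Exact samples of the dose-response on a 0.1-spaced grid recover
        the generating parameters to machine-level accuracy."""
        x = np.arange(0.05, 5.0, 0.1)
        y = sigmoid(x, *PAPER)
        params, diag = fit_sigmoid(x, y)
        assert params.L == pytest.approx(PAPER[0], abs=1e-6)
        assert params.x0 == pytest.approx(PAPER[1], abs=1e-6)
        assert params.k == pytest.approx(PAPER[2], abs=1e-6)
        assert params.b == pytest.approx(PAPER[3], abs=1e-6)
        assert diag["converged"]

    def test_weighted_recovery_matches(self):
        x = np.arange(0.05, 5.0, 0.1)
        y = sigmoid(x, *PAPER)
        n = np.full(x.size, 5000.0)
        params, _ = fit_sigmoid(x, y, n_pixels=n, cluster_area=10.0)
        assert params.x0 == pytest.approx(PAPER[1], abs=1e-5)

    def test_value_at_inflection(self):
        x = np.arange(0.05, 5.0, 0.1)
        params, _ = fit_sigmoid(x, sigmoid(x, *PAPER))
        assert params(params.x0) == pytest.approx(params.L / 2 + params.b)

    def test_constant_data_flagged(self):
        x = np.arange(0.05, 2.0, 0.1)
        params, diag = fit_sigmoid(x, np.full(x.size, 0.3))
        assert "degenerate_constant_data" in diag["flags"]
        assert not diag["converged"]
        assert np.isnan(params.k)
        assert params.b == pytest.approx(0.3)

    def test_x0_outside_range_flagged(self):
        x = np.arange(3.0, 5.0, 0.1)   # only the upper plateau sampled
        y = sigmoid(x, *PAPER) + np.random.default_rng(0).normal(0, 1e-4, x.size)
        params, diag = fit_sigmoid(x, y)
        if not (x.min() <= params.x0 <= x.max()):
            assert "x0_outside_data_range" in diag["flags"]
            assert not diag["converged"]
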