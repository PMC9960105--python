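"""Preprocessing operations against independent oracles and their
mathematical invariants (anti-extensivity of the opening, SG polynomial
reproduction, TIC contract, recalibration recovery)."""

import numpy as np
import pytest

from maldi_profiler import (PreprocessConfig, Spectrum, normalize_tic,
                            preprocess_spectrum, recalibrate, restrict_range,
                            sg_smooth, tophat_baseline)
from maldi_profiler.core_io import SpectrumError


def flat_spectrum(lo=2000.0, hi=4000.0, step=1.0, value=5.0):
    mz = np.arange(lo, hi + step / 2, step)
    return Spectrum(mz=mz, intensity=np.full(len(mz), value))


def brute_force_opening(mz, y, width):
    """O(n^2) sliding min-then-max with windows on the m/z axis."""
    hw = width / 2.0
    eroded = np.array([y[(mz >= m - hw) & (mz <= m + hw)].min() for m in mz])
    return np.array([eroded[(mz >= m - hw) & (mz <= m + hw)].max() for m in mz])


class TestRestrictRange:
    def test_endpoints_inside_bounds(self):
        mz = np.arange(1500.0, 21000.0, 1.0)
        s = Spectrum(mz=mz, intensity=np.ones(len(mz)))
        r = restrict_range(s, 2000.0, 20000.0)
        assert r.mz[0] >= 2000.0 and r.mz[-1] <= 20000.0

    def test_identity_when_range_covers(self):
        s = flat_spectrum()
        r = restrict_range(s, 1000.0, 30000.0)
        np.testing.assert_array_equal(r.mz, s.mz)

    def test_empty_restriction_errors(self):
        s = flat_spectrum()
        with pytest.raises(SpectrumError):
            restrict_range(s, 5000.0, 6000.0)


class TestTophatBaseline:
    def test_constant_spectrum_maps_to_zero(self):
        s = flat_spectrum(value=7.0)
        out = tophat_baseline(s, 10.0)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_anti_extensive_and_nonnegative(self):
        rng = np.random.default_rng(0)
        mz = np.arange(2000.0, 5000.0, 1.0)
        y = rng.uniform(0, 10, len(mz)) + 5 * np.exp(-(mz - 2000) / 800)
        s = Spectrum(mz=mz, intensity=y)
        out = tophat_baseline(s, 10.0)
        assert np.all(out.intensity <= s.intensity + 1e-12)
        assert np.all(out.intensity >= 0.0)

    def test_narrow_triangle_on_ramp_recovered(self):
        # peak support 20 Da, window 1800 Da: opening removes the ramp only
        mz = np.arange(2000.0, 20000.0, 10.0)
        ramp = 1.0 + (mz - 2000.0) / 18000.0
        tri = np.clip(1.0 - np.abs(mz - 9000.0) / 10.0, 0.0, None) * 5.0
        s = Spectrum(mz=mz, intensity=ramp + tri)
        out = tophat_baseline(s, 10.0)  # 10% of 18000 = 1800 Da window
        width = 0.10 * (mz[-1] - mz[0])
        oracle = (ramp + tri) - brute_force_opening(mz, ramp + tri, width)
        np.testing.assert_allclose(out.intensity, oracle, atol=1e-9)
        # the triangle itself comes back up to the support x slope floor
        # that morphology on a sloped baseline cannot beat
        interior = (mz >= 2000.0 + width) & (mz <= 20000.0 - width)
        np.testing.assert_allclose(out.intensity[interior], tri[interior],
                                   atol=20.0 / 18000.0 + 1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        mz = np.sort(rng.uniform(2000.0, 2500.0, 300))
        mz += np.arange(300) * 1e-6  # ensure strictly increasing
        y = rng.uniform(0, 10, 300)
        s = Spectrum(mz=mz, intensity=y)
        out = tophat_baseline(s, 10.0)
        width = 0.10 * (mz[-1] - mz[0])
        expected = y - brute_force_opening(mz, y, width)
        np.testing.assert_allclose(out.intensity, expected, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        mz = np.arange(2000.0, 4000.0, 1.0)
        s = Spectrum(mz=mz, intensity=rng.uniform(0, 10, len(mz)))
        once = tophat_baseline(s, 10.0)
        twice = tophat_baseline(once, 10.0)
        np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-9)


class TestSgSmooth:
    def test_constant_reproduced(self):
        s = flat_spectrum(value=3.5)
        out = sg_smooth(s, 5.0, cycles=10, polyorder=2)
        np.testing.assert_allclose(out.intensity, 3.5, atol=1e-10)

    def test_linear_ramp_reproduced(self):
        mz = np.arange(2000.0, 2200.0, 1.0)
        y = 0.01 * (mz - 2000.0) + 1.0
        out = sg_smooth(Spectrum(mz=mz, intensity=y), 5.0, 10, 2)
        np.testing.assert_allclose(out.intensity, y, atol=1e-9)

    def test_noise_variance_reduced_and_matches_convolution_oracle(self):
        from scipy.signal import savgol_coeffs
        rng = np.random.default_rng(3)
        mz = np.arange(2000.0, 3000.0, 1.0)
        y = rng.normal(50.0, 5.0, len(mz))
        out = sg_smooth(Spectrum(mz=mz, intensity=y), 5.0, 10, 2)
        assert out.intensity.var() < y.var()
        # oracle: explicit convolution with SG coefficients, 10 times
        c = savgol_coeffs(5, 2)
        expect = y.copy()
        for _ in range(10):
            expect = np.convolve(expect, c[::-1], mode="same")
        interior = slice(30, -30)  # oracle edges differ by construction
        np.testing.assert_allclose(out.intensity[interior],
                                   np.clip(expect, 0, None)[interior],
                                   rtol=1e-9, atol=1e-12)

    def test_too_sparse_grid_errors(self):
        mz = np.arange(2000.0, 2100.0, 10.0)  # width 5 covers 1 point
        s = Spectrum(mz=mz, intensity=np.ones(len(mz)))
        with pytest.raises(SpectrumError):
            sg_smooth(s, 5.0, 1, 2)

    def test_nonuniform_grid_polynomial_reproduction(self):
        rng = np.random.default_rng(4)
        mz = np.sort(rng.uniform(2000.0, 2050.0, 200))
        y = 2.0 + 0.3 * (mz - 2000.0)  # linear, reproduced exactly
        out = sg_smooth(Spectrum(mz=mz, intensity=y), 5.0, 2, 2)
        np.testing.assert_allclose(out.intensity, y, rtol=1e-8)


class TestNormalizeTic:
    def test_integral_is_one(self):
        rng = np.random.default_rng(5)
        mz = np.arange(2000.0, 4000.0, 1.0)
        s = Spectrum(mz=mz, intensity=rng.uniform(0.1, 9.0, len(mz)))
        out = normalize_tic(s)
        assert np.trapezoid(out.intensity, out.mz) == pytest.approx(1.0,
                                                                    abs=1e-9)

    def test_idempotent(self):
        s = normalize_tic(flat_spectrum())
        again = normalize_tic(s)
        np.testing.assert_allclose(again.intensity, s.intensity, rtol=1e-12)

    def test_null_spectrum_errors(self):
        s = Spectrum(mz=[2000.0, 2001.0], intensity=[0.0, 0.0])
        with pytest.raises(SpectrumError, match="null"):
            normalize_tic(s)


def gaussian_comb(mz, centers, fwhm=8.0, amp=10.0):
    sd = fwhm / (2 * np.sqrt(2 * np.log(2)))
    y = np.zeros(len(mz))
    for c in centers:
        y += amp * np.exp(-0.5 * ((mz - c) / sd) ** 2)
    return y


class TestRecalibrate:
    centers = [2500.0, 3000.0, 3500.0, 4000.0, 4500.0]

    def _spectrum(self, stretch=1.0):
        mz = np.arange(2000.0, 5000.0, 0.25)
        y = gaussian_comb(mz, [c * stretch for c in self.centers])
        return Spectrum(mz=mz, intensity=y)

    def test_aligned_spectrum_identity(self):
        s = self._spectrum()
        out, frac, excluded = recalibrate(s, self.centers)
        assert not excluded
        assert frac == 1.0
        np.testing.assert_allclose(out.mz, s.mz, rtol=1e-9)

    def test_500ppm_shift_recovered(self):
        s = self._spectrum(stretch=1 + 500e-6)
        out, frac, excluded = recalibrate(s, self.centers, 1000.0, 0.10)
        assert not excluded
        # recovered multiplicative shift within 50 ppm of the injected one
        factor = out.mz[0] / s.mz[0]
        recovered_ppm = (1.0 / factor - 1.0) * 1e6
        assert recovered_ppm == pytest.approx(500.0, abs=50.0)

    def test_2000ppm_shift_excluded(self):
        s = self._spectrum(stretch=1 + 2000e-6)
        out, frac, excluded = recalibrate(s, self.centers, 1000.0, 0.10)
        assert excluded
        assert frac == 0.0
        np.testing.assert_array_equal(out.mz, s.mz)  # returned unshifted

    def test_empty_reference_list_errors(self):
        with pytest.raises(ValueError):
            recalibrate(self._spectrum(), [])


class TestPipelineProperties:
    def test_no_negative_intensities_and_sorted_mz(self):
        rng = np.random.default_rng(6)
        mz = np.arange(1500.0, 21000.0, 1.0)
        y = (20 * np.exp(-(mz - 1500) / 2000)
             + gaussian_comb(mz, [3000, 8000, 15000], amp=50)
             + rng.normal(0, 1, len(mz)))
        s = Spectrum(mz=mz, intensity=np.clip(y, 0, None))
        out = preprocess_spectrum(s, PreprocessConfig())
        assert np.all(out.intensity >= 0)
        assert np.all(np.diff(out.mz) > 0)
        assert out.mz[0] >= 2000.0 and out.mz[-1] <= 20000.0

    def test_noise_free_apex_shift_below_one_step(self):
        mz = np.arange(2000.0, 6000.0, 1.0)
        centers = [3000.0, 4500.0]
        s = Spectrum(mz=mz, intensity=gaussian_comb(mz, centers, amp=100.0))
        out = preprocess_spectrum(s, PreprocessConfig())
        for c in centers:
            m = np.abs(out.mz - c) < 20
            apex = out.mz[m][np.argmax(out.intensity[m])]
            assert abs(apex - c) <= 1.0
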