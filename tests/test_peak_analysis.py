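"""Average-spectrum computation, noise estimation, S/N peak picking and
matrix construction against generator-manifest and closed-form oracles."""

import numpy as np
import pytest

from maldi_profiler import (NoiseProfile, PeakDefinition, QuantityMode,
                            Spectrum, SpectrumSet, build_peak_matrix,
                            estimate_noise, integrate_peaks, pick_peaks,
                            total_average_spectrum)
from maldi_profiler.core_io import SpectrumError


def gaussian(mz, c, fwhm, amp):
    sd = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return amp * np.exp(-0.5 * ((mz - c) / sd) ** 2)


class TestTotalAverageSpectrum:
    def test_single_spectrum_is_itself(self):
        mz = np.arange(2000.0, 2100.0)
        s = Spectrum(mz=mz, intensity=np.random.default_rng(0).uniform(
            0, 5, len(mz)))
        avg = total_average_spectrum(SpectrumSet([s], s.fluid))
        np.testing.assert_array_equal(avg.intensity, s.intensity)

    def test_two_identical_spectra(self):
        mz = np.arange(2000.0, 2100.0)
        y = np.random.default_rng(1).uniform(0, 5, len(mz))
        ss = SpectrumSet([Spectrum(mz=mz, intensity=y, sample_id=f"s{i}")
                          for i in range(2)], "saliva")
        avg = total_average_spectrum(ss)
        np.testing.assert_allclose(avg.intensity, y, rtol=1e-12)

    def test_shifted_grids_match_interpolation_oracle(self):
        rng = np.random.default_rng(2)
        mz1 = np.arange(2000.0, 2100.0, 1.0)
        mz2 = mz1 + 0.25
        y1, y2 = rng.uniform(0, 5, len(mz1)), rng.uniform(0, 5, len(mz2))
        ss = SpectrumSet([Spectrum(mz=mz1, intensity=y1, sample_id="a"),
                          Spectrum(mz=mz2, intensity=y2, sample_id="b")],
                         "saliva")
        avg = total_average_spectrum(ss)
        union = np.union1d(mz1, mz2)
        oracle = (np.interp(union, mz1, y1) + np.interp(union, mz2, y2)) / 2
        np.testing.assert_allclose(avg.intensity, oracle, atol=1e-9)

    def test_empty_set_errors(self):
        with pytest.raises(SpectrumError):
            total_average_spectrum(SpectrumSet([], "saliva"))


class TestEstimateNoise:
    def test_recovers_known_sigma(self):
        rng = np.random.default_rng(3)
        mz = np.arange(2000.0, 6000.0)
        sigma = 2.5
        s = Spectrum(mz=mz, intensity=np.abs(rng.normal(50.0, sigma, len(mz))))
        est = estimate_noise(s, 200.0)
        assert np.median(est.sd) == pytest.approx(sigma, rel=0.10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        mz = np.arange(2000.0, 6000.0)
        base = rng.normal(0.0, 1.0, len(mz))
        s1 = Spectrum(mz=mz, intensity=np.abs(50 + base))
        s2 = Spectrum(mz=mz, intensity=np.abs(50 + 2 * base))
        r = np.median(estimate_noise(s2).sd) / np.median(estimate_noise(s1).sd)
        assert r == pytest.approx(2.0, rel=0.10)

    def test_noise_free_trace_near_zero(self):
        mz = np.arange(2000.0, 6000.0)
        y = 10.0 + 0.001 * (mz - 2000.0) + gaussian(mz, 4000.0, 12.0, 100.0)
        est = estimate_noise(Spectrum(mz=mz, intensity=y))
        assert est.sd.max() < 1e-6 * y.max()

    def test_window_too_small_errors(self):
        mz = np.arange(2000.0, 2006.0)
        s = Spectrum(mz=mz, intensity=np.ones(len(mz)))
        with pytest.raises(SpectrumError):
            estimate_noise(s, window_mz=2.0)


class TestPickPeaks:
    def _flat_noise(self, mz, sd=1.0):
        return NoiseProfile(mz=mz, sd=np.full(len(mz), sd))

    def test_zero_spectrum_empty_list(self):
        mz = np.arange(2000.0, 3000.0)
        s = Spectrum(mz=mz, intensity=np.zeros(len(mz)))
        assert pick_peaks(s, self._flat_noise(mz), 4.0, 300.0) == []

    def test_snr_threshold_selects_expected_subset(self):
        # apexes at S/N 10, 5 and 2 against unit noise; threshold 4 keeps 2
        mz = np.arange(2000.0, 5000.0)
        y = (gaussian(mz, 2500.0, 2500 / 300, 10.0)
             + gaussian(mz, 3500.0, 3500 / 300, 5.0)
             + gaussian(mz, 4500.0, 4500 / 300, 2.0))
        peaks = pick_peaks(Spectrum(mz=mz, intensity=y),
                           self._flat_noise(mz), 4.0, 300.0)
        assert len(peaks) == 2
        got = sorted(p.centroid_mz for p in peaks)
        assert got[0] == pytest.approx(2500.0, abs=1.0)
        assert got[1] == pytest.approx(3500.0, abs=1.0)

    def test_snr_exactly_at_threshold_included(self):
        mz = np.arange(2000.0, 3000.0)
        y = np.zeros(len(mz))
        y[500] = 4.0  # apex exactly at S/N 4 over unit noise, zero floor
        peaks = pick_peaks(Spectrum(mz=mz, intensity=y),
                           self._flat_noise(mz), 4.0, 300.0)
        assert len(peaks) == 1
        assert peaks[0].snr_at_pick == pytest.approx(4.0)

    def test_count_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        mz = np.arange(2000.0, 8000.0)
        y = rng.normal(10, 1, len(mz))
        for c in np.linspace(2200, 7800, 15):
            y += gaussian(mz, c, c / 300, rng.uniform(2, 30))
        s = Spectrum(mz=mz, intensity=np.clip(y, 0, None))
        noise = estimate_noise(s)
        counts = [len(pick_peaks(s, noise, thr, 300.0))
                  for thr in (2.0, 4.0, 6.0, 10.0, 20.0)]
        assert counts == sorted(counts, reverse=True)

    def test_dedup_keeps_higher_of_close_pair(self):
        mz = np.arange(2000.0, 4000.0)
        y = (gaussian(mz, 3000.0, 10.0, 20.0)
             + gaussian(mz, 3004.0, 10.0, 10.0))  # 4 Da apart, FWHM 10
        peaks = pick_peaks(Spectrum(mz=mz, intensity=y),
                           self._flat_noise(mz), 4.0, 300.0)
        assert len(peaks) == 1
        assert abs(peaks[0].centroid_mz - 3000.0) < 3.0

    def test_regions_truncated_at_midpoints(self):
        mz = np.arange(2000.0, 4000.0)
        y = (gaussian(mz, 2980.0, 10.0, 50.0)
             + gaussian(mz, 3010.0, 10.0, 50.0))
        peaks = pick_peaks(Spectrum(mz=mz, intensity=y),
                           self._flat_noise(mz), 4.0, 300.0)
        assert len(peaks) == 2
        left, right = sorted(peaks, key=lambda p: p.centroid_mz)
        assert left.right_mz <= right.left_mz + 1e-9


class TestIntegratePeaks:
    def test_zero_region_zero_area(self):
        mz = np.arange(2000.0, 3000.0)
        s = Spectrum(mz=mz, intensity=np.zeros(len(mz)))
        p = PeakDefinition(2500.0, 2480.0, 2520.0, 5.0, 1)
        assert integrate_peaks(s, [p], QuantityMode.AREA)[0] == 0.0

    def test_gaussian_area_closed_form(self):
        # unit-amplitude Gaussian, SD sigma: area = sigma * sqrt(2 pi)
        mz = np.arange(2000.0, 3000.0, 0.1)
        sigma = 5.0
        y = np.exp(-0.5 * ((mz - 2500.0) / sigma) ** 2)
        s = Spectrum(mz=mz, intensity=y)
        p = PeakDefinition(2500.0, 2450.0, 2550.0, 5.0, 1)
        area = integrate_peaks(s, [p], QuantityMode.AREA)[0]
        assert area == pytest.approx(sigma * np.sqrt(2 * np.pi), rel=0.01)

    def test_intensity_mode_is_max(self):
        mz = np.arange(2000.0, 2100.0)
        y = np.zeros(len(mz))
        y[50] = 7.5
        s = Spectrum(mz=mz, intensity=y)
        p = PeakDefinition(2050.0, 2040.0, 2060.0, 5.0, 1)
        assert integrate_peaks(s, [p], QuantityMode.INTENSITY)[0] == 7.5

    def test_region_outside_span_errors(self):
        mz = np.arange(2000.0, 2100.0)
        s = Spectrum(mz=mz, intensity=np.ones(len(mz)))
        p = PeakDefinition(5000.0, 4990.0, 5010.0, 5.0, 3)
        with pytest.raises(SpectrumError, match="peak 3"):
            integrate_peaks(s, [p])


class TestBuildPeakMatrix:
    def _cohort_and_peaks(self):
        mz = np.arange(2000.0, 3000.0)
        spectra = []
        for i, amp in enumerate([10.0, 10.0, 20.0, 20.0]):
            lab = "control" if i < 2 else "foa"
            y = gaussian(mz, 2500.0, 8.0, amp)
            spectra.append(Spectrum(mz=mz, intensity=y, sample_id=f"s{i}",
                                    label=lab))
        ss = SpectrumSet(spectra, "saliva")
        return ss, [PeakDefinition(2500.0, 2480.0, 2520.0, 9.0, 1)]

    def test_shape_and_no_missing(self):
        ss, peaks = self._cohort_and_peaks()
        m = build_peak_matrix(ss, peaks)
        assert m.values.shape == (4, 1)
        assert np.all(np.isfinite(m.values))

    def test_identical_spectra_identical_rows(self):
        mz = np.arange(2000.0, 3000.0)
        y = gaussian(mz, 2500.0, 8.0, 5.0)
        ss = SpectrumSet([Spectrum(mz=mz, intensity=y, sample_id=f"s{i}")
                          for i in range(3)], "saliva")
        m = build_peak_matrix(ss, [PeakDefinition(2500.0, 2480.0, 2520.0,
                                                  9.0, 1)])
        assert np.ptp(m.values, axis=0)[0] == 0.0

    def test_class_means_ordered_as_folds(self):
        ss, peaks = self._cohort_and_peaks()
        m = build_peak_matrix(ss, peaks)
        labs = np.asarray(m.labels)
        control = m.values[labs == "control", 0].mean()
        foa = m.values[labs == "foa", 0].mean()
        assert foa / control == pytest.approx(2.0, rel=1e-6)

    def test_permutation_equivariance(self):
        ss, peaks = self._cohort_and_peaks()
        m1 = build_peak_matrix(ss, peaks)
        perm = [2, 0, 3, 1]
        ss2 = SpectrumSet([ss.spectra[i] for i in perm], ss.fluid)
        m2 = build_peak_matrix(ss2, peaks)
        np.testing.assert_array_equal(m2.values, m1.values[perm])


def test_noise_free_cohort_precision_recall_one():
    """Picking on a noise-free synthetic average finds every injected peak
    and nothing else (precision = recall = 1 at zero noise)."""
    from conftest import quick_cohort_config
    from maldi_profiler import generate_cohort

    cfg = quick_cohort_config(noise_sd=0.0, baseline_amplitude=0.0,
                              mass_jitter_ppm=0.0, n_per_class=5)
    cohort, manifest = generate_cohort(cfg)
    avg = total_average_spectrum(cohort)
    noise = estimate_noise(avg)
    peaks = pick_peaks(avg, noise, 4.0, 300.0)
    truth = manifest["centroid_mz"].to_numpy()
    got = np.array([p.centroid_mz for p in peaks])
    tol = truth / 300.0  # one FWHM
    # recall: every injected peak has a picked centroid within one FWHM
    assert all(np.any(np.abs(got - t) <= tt) for t, tt in zip(truth, tol))
    # precision: every picked centroid corresponds to an injected peak
    for g in got:
        assert np.any(np.abs(truth - g) <= g / 300.0)
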