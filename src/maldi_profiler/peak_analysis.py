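"""Total-average-spectrum peak picking and peak-matrix construction.

Peaks are picked once, on the pointwise mean of all (preprocessed) cohort
spectra, so every sample shares a single peak list: local maxima whose
signal-to-noise ratio reaches the threshold (default 4, inclusive) are
accepted, deduplicated so no two centroids lie within one FWHM
(FWHM = centroid / resolution, resolution default 300), and assigned
integration regions of +-1 FWHM truncated at midpoints between neighbours.

Noise is estimated by a robust sliding-window procedure: the trace is
detrended with second differences (which annihilate locally linear signal),
scaled to unit variance for white noise, and summarized per window by
1.4826 x MAD; window centers are linearly interpolated to the full grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
from scipy.signal import find_peaks

from .core_io import (PeakDefinition, PeakMatrix, QuantityMode, Spectrum,
                      SpectrumSet, SpectrumError)


@dataclass
class NoiseProfile:
    """Per-point noise SD estimate on the same grid as its spectrum."""

    mz: np.ndarray
    sd: np.ndarray
    estimator_name: str = "second-difference MAD"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if len(self.mz) != len(self.sd):
            raise ValueError("noise grid length mismatch")
        if np.any(self.sd <= 0):
            raise ValueError("noise SD must be strictly positive")


def total_average_spectrum(spectra: SpectrumSet) -> Spectrum:
    """Pointwise mean of all spectra after linear interpolation onto the
    union of their m/z grids."""
    if len(spectra) == 0:
        raise SpectrumError("cannot average an empty spectrum set")
    grids = [s.mz for s in spectra]
    grid = reduce(np.union1d, grids) if len(grids) > 1 else grids[0]
    acc = np.zeros(len(grid))
    for s in spectra:
        acc += np.interp(grid, s.mz, s.intensity)
    return Spectrum(mz=grid, intensity=acc / len(spectra),
                    sample_id="total_average", fluid=spectra.fluid)


def estimate_noise(s: Spectrum, window_mz: float = 200.0,
                   detrend_mz: float = 20.0) -> NoiseProfile:
    """Robust per-point noise SD of a spectrum.

    The trace is detrended by subtracting a running median of width
    ``detrend_mz`` (which preserves baseline and broad peaks but not
    noise-scale wiggles, so the residual keeps the true local noise
    amplitude even after smoothing has correlated it); within each sliding
    window (default 200 Da/e, hopped by half a window) the residual scale
    is estimated as 1.4826 x median absolute deviation and linearly
    interpolated between window centers.
    """
    from scipy.ndimage import median_filter

    mz, y = s.mz, s.intensity
    step = float(np.median(np.diff(mz)))
    k = max(3, int(round(detrend_mz / step)) | 1)  # odd point count
    d = y - median_filter(y, size=min(k, len(y) | 1), mode="nearest")
    dm = mz
    centers = np.arange(mz[0] + window_mz / 2.0, mz[-1] + 1e-9, window_mz / 2.0)
    if len(centers) == 0:
        centers = np.array([(mz[0] + mz[-1]) / 2.0])
    est_c, est_v = [], []
    for c in centers:
        i0, i1 = np.searchsorted(dm, [c - window_mz / 2.0, c + window_mz / 2.0])
        seg = d[i0:i1]
        if len(seg) < 10:
            raise SpectrumError(
                f"noise window at m/z {c:.1f} contains {len(seg)} points (<10)")
        med = np.median(seg)
        est_c.append(c)
        est_v.append(1.4826 * np.median(np.abs(seg - med)))
    sd = np.interp(mz, est_c, est_v)
    floor = max(1e-12, 1e-12 * float(np.max(np.abs(y), initial=0.0)))
    return NoiseProfile(mz=mz, sd=np.maximum(sd, floor))


def pick_peaks(avg: Spectrum, noise: NoiseProfile, snr_threshold: float = 4.0,
               resolution: float = 300.0) -> list:
    """S/N-thresholded peak picking on the total average spectrum.

    The signal-to-noise ratio of a local maximum is its apex height above
    the local signal floor (the running median over +-1.5 FWHM, which a
    baseline-subtracted but noisy trace does not reach zero on) divided by
    the local noise SD; maxima with S/N >= ``snr_threshold`` (inclusive)
    are kept, and among maxima closer than one FWHM of the higher one the
    higher wins.  Each accepted peak gets the integration region
    [centroid - FWHM, centroid + FWHM], truncated at midpoints between
    adjacent accepted centroids and clipped to the spectrum span.
    """
    if not np.array_equal(avg.mz, noise.mz):
        raise ValueError("average spectrum and noise profile on different grids")
    idx, _ = find_peaks(avg.intensity)
    if len(idx) == 0:
        return []
    y, mz = avg.intensity, avg.mz
    snr = np.empty(len(idx))
    for k, i in enumerate(idx):
        half = 1.5 * mz[i] / resolution
        j0, j1 = np.searchsorted(mz, [mz[i] - half, mz[i] + half])
        floor = np.median(y[j0:j1]) if j1 > j0 else 0.0
        snr[k] = (y[i] - floor) / noise.sd[i]
    keep_mask = snr >= snr_threshold
    idx, snr = idx[keep_mask], snr[keep_mask]
    # greedy dedup, highest apex first
    order = np.argsort(avg.intensity[idx], kind="stable")[::-1]
    accepted: list = []
    for o in order:
        c = avg.mz[idx[o]]
        keep = True
        for a in accepted:
            fwhm_high = a["c"] / resolution  # a is the higher peak (greedy order)
            if abs(a["c"] - c) < fwhm_high:
                keep = False
                break
        if keep:
            accepted.append({"c": c, "snr": float(snr[o])})
    accepted.sort(key=lambda a: a["c"])
    lo, hi = avg.mz[0], avg.mz[-1]
    peaks = []
    for k, a in enumerate(accepted):
        fwhm = a["c"] / resolution
        left = a["c"] - fwhm
        right = a["c"] + fwhm
        if k > 0:
            left = max(left, (accepted[k - 1]["c"] + a["c"]) / 2.0)
        if k < len(accepted) - 1:
            right = min(right, (accepted[k + 1]["c"] + a["c"]) / 2.0)
        left = max(left, lo)
        right = min(right, hi)
        peaks.append(PeakDefinition(centroid_mz=float(a["c"]), left_mz=float(left),
                                    right_mz=float(right), snr_at_pick=a["snr"],
                                    index=k + 1))
    return peaks


def integrate_peaks(s: Spectrum, peaks, mode=QuantityMode.AREA) -> np.ndarray:
    """Quantify each peak region in one spectrum.

    mode=area: trapezoidal integral of the (baseline-corrected) intensity
    over [left, right], with interpolated boundary values; mode=intensity:
    maximal intensity inside the region.  A region with no signal yields 0.
    """
    mode = QuantityMode(mode)
    out = np.empty(len(peaks))
    lo, hi = s.mz[0], s.mz[-1]
    for k, p in enumerate(peaks):
        if p.right_mz < lo or p.left_mz > hi:
            raise SpectrumError(
                f"peak {p.index} (m/z {p.centroid_mz:.2f}) region outside "
                f"spectrum span [{lo:.2f}, {hi:.2f}]")
        # region bounds clipped to the span (ppm-scale recalibration can
        # move the edges of individual spectra slightly inside the
        # average-spectrum grid)
        left, right = max(p.left_mz, lo), min(p.right_mz, hi)
        i0 = np.searchsorted(s.mz, left, side="right")
        i1 = np.searchsorted(s.mz, right, side="left")
        xs = np.concatenate(([left], s.mz[i0:i1], [right]))
        ys = np.concatenate(([np.interp(left, s.mz, s.intensity)],
                             s.intensity[i0:i1],
                             [np.interp(right, s.mz, s.intensity)]))
        if mode == QuantityMode.AREA:
            out[k] = np.trapezoid(ys, xs)
        else:
            out[k] = ys.max()
    return out


def build_peak_matrix(spectra: SpectrumSet, peaks,
                      mode=QuantityMode.AREA) -> PeakMatrix:
    """Integrate every peak region in every spectrum of a cohort."""
    if len(peaks) == 0:
        raise ValueError("empty peak list")
    values = np.vstack([integrate_peaks(s, peaks, mode) for s in spectra])
    return PeakMatrix(values=values, peaks=list(peaks),
                      sample_ids=spectra.sample_ids, labels=spectra.labels,
                      quantity_mode=mode)
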