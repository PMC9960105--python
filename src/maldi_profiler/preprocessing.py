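"""Spectrum preprocessing: range restriction, Top-Hat baseline subtraction,
iterated Savitzky-Golay smoothing, TIC normalization and recalibration.

The canonical stage order is

    restrict -> tophat -> smooth -> normalize -> recalibrate

with defaults matching the published parameter set: analysis range m/z
2000-20,000, Top-Hat minimal baseline width 10% of the mass-range width,
10 cycles of a Savitzky-Golay filter of width 5 m/z, a maximal peak shift of
1000 ppm and a 10% calibrant match requirement.

All window semantics are defined on the m/z axis (Da/e), not in point counts,
so non-uniform grids are handled correctly; the morphological operators use a
monotonic-wedge sliding extremum that is exact for arbitrary grids.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks, savgol_coeffs
from scipy.ndimage import correlate1d

from .core_io import Spectrum, SpectrumSet, SpectrumError


@dataclass
class PreprocessConfig:
    mz_lo: float = 2000.0
    mz_hi: float = 20000.0
    tophat_min_baseline_pct: float = 10.0
    sg_width_mz: float = 5.0
    sg_cycles: int = 10
    sg_polyorder: int = 2
    max_peak_shift_ppm: float = 1000.0
    calibrant_match_fraction: float = 0.10
    normalize: str = "tic"  # "tic" | "none"

    def __post_init__(self) -> None:
        if not (0 < self.tophat_min_baseline_pct <= 100):
            raise ValueError("tophat_min_baseline_pct must be in (0, 100]")
        if self.sg_cycles < 1:
            raise ValueError("sg_cycles must be >= 1")
        if self.normalize not in ("tic", "none"):
            raise ValueError(f"unknown normalization {self.normalize!r}")


def restrict_range(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep only points with lo <= m/z <= hi."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    mask = (s.mz >= lo) & (s.mz <= hi)
    if mask.sum() < 2:
        raise SpectrumError(
            f"restriction to [{lo}, {hi}] leaves {int(mask.sum())} point(s)")
    return s.replace(mz=s.mz[mask], intensity=s.intensity[mask])


def _sliding_extremum(mz: np.ndarray, y: np.ndarray, half_width: float,
                      mode: str) -> np.ndarray:
    """Exact sliding min/max of y over the m/z window [m-hw, m+hw].

    Monotonic-wedge algorithm, O(n) amortized; windows are defined on the
    m/z axis so the grid need not be uniform.
    """
    n = len(mz)
    out = np.empty(n)
    wedge: deque = deque()  # indices with monotone y
    lo_ptr = 0
    hi_ptr = 0
    better = (lambda a, b: a <= b) if mode == "min" else (lambda a, b: a >= b)
    for i in range(n):
        hi = mz[i] + half_width
        while hi_ptr < n and mz[hi_ptr] <= hi:
            while wedge and better(y[hi_ptr], y[wedge[-1]]):
                wedge.pop()
            wedge.append(hi_ptr)
            hi_ptr += 1
        lo = mz[i] - half_width
        while wedge and mz[wedge[0]] < lo:
            wedge.popleft()
        out[i] = y[wedge[0]]
    return out


def tophat_baseline(s: Spectrum, min_baseline_pct: float = 10.0) -> Spectrum:
    """Subtract the morphological opening (erosion then dilation) of the
    trace with a flat structuring window of width
    ``min_baseline_pct/100 * (mz_hi - mz_lo)`` on the m/z axis.

    The opening is a lower envelope, so the result is nonnegative; peaks
    narrower than the window survive unchanged.
    """
    span = s.mz[-1] - s.mz[0]
    width = min_baseline_pct / 100.0 * span
    if width > span:
        warnings.warn("structuring window wider than spectrum span; clamped",
                      stacklevel=2)
        width = span
    hw = width / 2.0
    eroded = _sliding_extremum(s.mz, s.intensity, hw, "min")
    opened = _sliding_extremum(s.mz, eroded, hw, "max")
    return s.replace(intensity=s.intensity - opened)


def _sg_smooth_uniform(y: np.ndarray, half_pts: int, polyorder: int
                       ) -> np.ndarray:
    """One SG pass on a uniform grid; edges use shrinking symmetric windows."""
    n = len(y)
    coeffs = savgol_coeffs(2 * half_pts + 1, min(polyorder, 2 * half_pts))
    out = correlate1d(y, coeffs[::-1], mode="nearest")
    # redo the edges with shrinking symmetric windows
    for i in range(min(half_pts, n)):
        for idx in (i, n - 1 - i):
            r = min(idx, n - 1 - idx, half_pts)
            if r == idx or r == n - 1 - idx:  # window actually shrank
                if r == 0:
                    out[idx] = y[idx]
                else:
                    c = savgol_coeffs(2 * r + 1, min(polyorder, 2 * r))
                    out[idx] = np.dot(c[::-1], y[idx - r:idx + r + 1])
    return out


def _sg_smooth_general(mz: np.ndarray, y: np.ndarray, half_width: float,
                       polyorder: int) -> np.ndarray:
    """One SG pass on an arbitrary grid: local polynomial least squares over
    the points within +-half_width of each m/z."""
    n = len(mz)
    out = np.empty(n)
    for i in range(n):
        i0, i1 = np.searchsorted(mz, [mz[i] - half_width, mz[i] + half_width + 1e-12])
        x = mz[i0:i1] - mz[i]
        yy = y[i0:i1]
        deg = min(polyorder, len(x) - 1)
        if deg <= 0:
            out[i] = yy.mean() if len(yy) else y[i]
            continue
        coef = np.polynomial.polynomial.polyfit(x, yy, deg)
        out[i] = coef[0]
    return out


def sg_smooth(s: Spectrum, width_mz: float = 5.0, cycles: int = 10,
              polyorder: int = 2) -> Spectrum:
    """Apply a Savitzky-Golay filter of the given m/z width ``cycles`` times.

    The window at each point is the set of grid points within
    +-width_mz/2; edge points use shrinking symmetric windows (degenerating
    to the identity at the boundary).  Negative filter overshoot is clipped
    at zero after the final cycle.
    """
    mz, y = s.mz, s.intensity.astype(float)
    steps = np.diff(mz)
    uniform = np.allclose(steps, steps[0], rtol=1e-8, atol=0.0)
    hw = width_mz / 2.0
    if uniform:
        half_pts = int(np.floor(hw / steps[0]))
        if 2 * half_pts + 1 < polyorder + 1:
            raise SpectrumError(
                f"SG width {width_mz} covers {2 * half_pts + 1} point(s) at "
                f"grid step {steps[0]:.4g}; need >= {polyorder + 1}")
        for _ in range(cycles):
            y = _sg_smooth_uniform(y, half_pts, polyorder)
    else:
        counts = np.searchsorted(mz, mz + hw) - np.searchsorted(mz, mz - hw)
        bad = np.nonzero(counts < polyorder + 1)[0]
        if len(bad):
            raise SpectrumError(
                f"grid too sparse for SG width {width_mz} near m/z "
                f"{mz[bad[0]]:.2f}")
        for _ in range(cycles):
            y = _sg_smooth_general(mz, y, hw, polyorder)
    return s.replace(intensity=np.clip(y, 0.0, None))


def normalize_tic(s: Spectrum) -> Spectrum:
    """Scale intensities so the trapezoidal integral over the trace is 1."""
    total = float(np.trapezoid(s.intensity, s.mz))
    if total <= 0:
        raise SpectrumError("null spectrum: total ion current is zero")
    return s.replace(intensity=s.intensity / total)


def recalibrate(s: Spectrum, reference_peaks, max_shift_ppm: float = 1000.0,
                match_fraction: float = 0.10):
    """Align a spectrum to a calibrant peak list by a single multiplicative
    m/z correction.

    Local maxima of the trace within ``max_shift_ppm`` of a reference mass
    are matched one-to-one (nearest relative distance wins).  If the matched
    fraction of references falls below ``match_fraction`` the spectrum is
    flagged as excluded from recalibration and returned unshifted; otherwise
    the least-squares stretch factor over the matched pairs is applied.

    Returns ``(spectrum, matched_fraction, excluded)``.
    """
    refs = np.sort(np.asarray(list(reference_peaks), dtype=float))
    if len(refs) == 0:
        raise ValueError("empty reference peak list")
    idx, _ = find_peaks(s.intensity)
    obs = s.mz[idx]
    # candidate (ref, obs) pairs within the ppm window
    pairs = []
    for r_i, r in enumerate(refs):
        tol = max_shift_ppm * 1e-6 * r
        j0, j1 = np.searchsorted(obs, [r - tol, r + tol])
        for j in range(j0, j1):
            pairs.append((abs(obs[j] - r) / r, r_i, j))
    pairs.sort()
    used_r, used_o = set(), set()
    matches = []
    for _, r_i, j in pairs:
        if r_i in used_r or j in used_o:
            continue
        used_r.add(r_i)
        used_o.add(j)
        matches.append((refs[r_i], obs[j]))
    frac = len(matches) / len(refs)
    if frac < match_fraction or not matches:
        return s, frac, True
    m_ref = np.array([m[0] for m in matches])
    m_obs = np.array([m[1] for m in matches])
    factor = float(np.dot(m_ref, m_obs) / np.dot(m_obs, m_obs))
    return s.replace(mz=s.mz * factor), frac, False


def preprocess_spectrum(s: Spectrum, config: PreprocessConfig | None = None,
                        reference_peaks=None) -> Spectrum:
    """Run the canonical pipeline on one spectrum.

    Recalibration runs only when a calibrant list is supplied.
    """
    cfg = config or PreprocessConfig()
    out = restrict_range(s, cfg.mz_lo, cfg.mz_hi)
    out = tophat_baseline(out, cfg.tophat_min_baseline_pct)
    out = sg_smooth(out, cfg.sg_width_mz, cfg.sg_cycles, cfg.sg_polyorder)
    if cfg.normalize == "tic":
        out = normalize_tic(out)
    if reference_peaks is not None:
        out, _, _ = recalibrate(out, reference_peaks,
                                cfg.max_peak_shift_ppm,
                                cfg.calibrant_match_fraction)
    return out


def preprocess_set(spectra: SpectrumSet, config: PreprocessConfig | None = None,
                   reference_peaks=None) -> SpectrumSet:
    """Preprocess every spectrum of a cohort."""
    cfg = config or PreprocessConfig()
    done = [preprocess_spectrum(s, cfg, reference_peaks) for s in spectra]
    return SpectrumSet(spectra=done, fluid=spectra.fluid,
                       class_names=list(spectra.class_names))
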