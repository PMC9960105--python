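"""Figure-level outputs: 2D peak scatter with 95% confidence ellipses,
class-average spectrum overlays, and pseudo-gel views.

Every figure has a numeric backing artifact (point sets, traces, rasters)
that is returned and can be written as CSV; rendering to PNG/SVG through
matplotlib is a thin optional layer on top.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core_io import PeakMatrix, SpectrumSet


@dataclass
class Ellipse:
    """A confidence ellipse of a 2-D point cloud.

    ``semi_axes`` are ordered major, minor; ``rotation`` is the angle of the
    major axis from the x-axis in radians; ``level`` is the nominal coverage
    probability of the underlying Gaussian.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: float
    level: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float)
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be positive")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")

    def contains(self, points) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, s], [-s, c]])
        local = pts @ rot.T
        return ((local / self.semi_axes) ** 2).sum(axis=1) <= 1.0 + 1e-12

    def boundary(self, n: int = 200) -> np.ndarray:
        """n x 2 polyline tracing the ellipse (for plotting)."""
        t = np.linspace(0, 2 * np.pi, n)
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        x = self.semi_axes[0] * np.cos(t)
        y = self.semi_axes[1] * np.sin(t)
        return np.column_stack([c * x - s * y, s * x + c * y]) + self.center


def confidence_ellipse(points, level: float = 0.95) -> Ellipse:
    """Data ellipse covering ``level`` of the fitted bivariate Gaussian.

    Axes come from the eigendecomposition of the sample covariance scaled
    by the chi-square(2) quantile at ``level``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[1], 1.0):
        raise ValueError("singular covariance: points are (near-)collinear")
    scale = chi2.ppf(level, df=2)
    order = np.argsort(eigvals)[::-1]  # major axis first
    axes = np.sqrt(scale * eigvals[order])
    major = eigvecs[:, order[0]]
    rotation = float(np.arctan2(major[1], major[0]))
    return Ellipse(center=center, semi_axes=axes, rotation=rotation,
                   level=level)


def scatter_2d(matrix: PeakMatrix, peak_a: int, peak_b: int,
               level: float = 0.95) -> dict:
    """Per-class 2-D point sets and confidence ellipses for two peaks.

    ``peak_a`` / ``peak_b`` are 0-based column indices (x and y axes).
    Returns ``{class: {"points": n x 2 array, "ellipse": Ellipse}}``.
    """
    for idx in (peak_a, peak_b):
        if not (0 <= idx < matrix.n_peaks):
            raise ValueError(f"peak index {idx} out of range")
    labels = np.asarray(matrix.labels)
    out = {}
    for c in matrix.class_names:
        pts = matrix.values[labels == c][:, [peak_a, peak_b]]
        out[c] = {"points": pts, "ellipse": confidence_ellipse(pts, level)}
    return out


def _class_grid(spectra: SpectrumSet, lo: float, hi: float):
    grids = [s.mz[(s.mz >= lo) & (s.mz <= hi)] for s in spectra]
    grids = [g for g in grids if len(g)]
    if not grids:
        raise ValueError(f"no spectral points in window [{lo}, {hi}]")
    return reduce(np.union1d, grids)


def class_average_overlay(spectra: SpectrumSet, mz_window) -> pd.DataFrame:
    """Per-class pointwise mean trace over an m/z window.

    Returns a DataFrame with an ``mz`` column plus one column per class —
    the numeric content of a class-average overlay plot.
    """
    lo, hi = mz_window
    grid = _class_grid(spectra, lo, hi)
    df = pd.DataFrame({"mz": grid})
    labels = np.asarray(spectra.labels)
    for c in spectra.class_names:
        members = [s for s in spectra if s.label.value == c]
        if not members:
            raise ValueError(f"class {c!r} has no spectra")
        acc = np.zeros(len(grid))
        for s in members:
            acc += np.interp(grid, s.mz, s.intensity)
        df[c] = acc / len(members)
    return df


def gel_view(spectra: SpectrumSet, mz_window, n_bins: int | None = None):
    """Pseudo-gel raster of a cohort over an m/z window.

    Rows are spectra sorted by class (cohort order within class), columns
    are m/z bins, values are row-normalized intensities in [0, 1] (an
    all-zero row stays zero).  Returns ``(raster, row_sample_ids, bin_mz)``.
    """
    if len(spectra) == 0:
        raise ValueError("empty spectrum set")
    lo, hi = mz_window
    if not (lo < hi):
        raise ValueError("empty m/z window")
    grid = _class_grid(spectra, lo, hi)
    if n_bins is not None and n_bins < len(grid):
        grid = np.linspace(lo, hi, n_bins)
    order = []
    for c in spectra.class_names:
        order.extend(i for i, s in enumerate(spectra) if s.label.value == c)
    raster = np.zeros((len(order), len(grid)))
    ids = []
    for r, i in enumerate(order):
        s = spectra.spectra[i]
        raster[r] = np.interp(grid, s.mz, s.intensity)
        peak = raster[r].max()
        if peak > 0:
            raster[r] /= peak
        ids.append(s.sample_id)
    return raster, ids, grid


# ---------------------------------------------------------------------------
# optional matplotlib rendering
# ---------------------------------------------------------------------------

def plot_scatter_2d(scatter: dict, path, xlabel: str = "", ylabel: str = ""):
    """Render the output of :func:`scatter_2d` to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for c, d in scatter.items():
        pts = d["points"]
        sc = ax.scatter(pts[:, 0], pts[:, 1], s=14, label=c)
        b = d["ellipse"].boundary()
        ax.plot(b[:, 0], b[:, 1], color=sc.get_facecolor()[0], lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_overlay(df: pd.DataFrame, path):
    """Render a class-average overlay DataFrame to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for c in df.columns[1:]:
        ax.plot(df["mz"], df[c], label=c, lw=1)
    ax.set_xlabel("m/z")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gel_view(raster, bin_mz, path):
    """Render a gel-view raster to an image file (rainbow scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.imshow(raster, aspect="auto", cmap="rainbow",
              extent=[bin_mz[0], bin_mz[-1], raster.shape[0], 0])
    ax.set_xlabel("m/z")
    ax.set_ylabel("spectrum")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
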