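"""Synthetic saliva / gingival crevicular fluid (GCF) cohort generator.

The clinical cohorts this pipeline targets (three balanced groups: untreated
controls, fixed orthodontic appliances FOA, and Invisalign IN; 15 spectra per
group per fluid) are not publicly deposited, so every downstream stage is
exercised on a forward-simulated cohort with the same statistical structure:

* linear-mode MALDI-TOF profile traces over m/z 2000-20,000 on a uniform grid,
* Gaussian peaks whose full width at half maximum follows the instrument
  resolving power (FWHM = centroid / resolution, resolution 300),
* a decaying-exponential chemical background plus additive white noise,
* per-spectrum multiplicative mass calibration error (ppm-scale jitter) and
  log-normal amplitude scatter,
* a peak panel per fluid containing the discriminating masses reported for
  these cohorts, the alpha-defensin (HNP-1/2/3) triplet at m/z 3442/3371/3486
  with apex ordering HNP-1 > HNP-2 > HNP-3 (about 1 : 0.5 : 0.33), and
  class-neutral filler peaks.

Class structure of the panel: treated GCF groups carry roughly 2-fold elevated
HNP intensities over controls; in saliva the IN group is roughly 3-fold
elevated while FOA is only slightly raised; GCF HNP base intensities are 10x
the saliva ones.  Every injected peak is recorded in a ground-truth manifest
so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import Fluid, Label, Spectrum, SpectrumSet

HNP_MASSES = {"HNP-1": 3442.0, "HNP-2": 3371.0, "HNP-3": 3486.0}

# Discriminating masses reported for each fluid's GA panel.
SALIVA_DISCRIMINATING = [2124.46, 2317.74, 2972.16, 3965.61, 4471.34,
                         6058.96, 6401.79, 7454.8, 10710.72, 12614.78]
GCF_DISCRIMINATING = [3440.58, 7673.14, 3707.6, 9624.63, 2401.45,
                      3553.58, 7007.2, 8307.4, 13460.52, 14006.13]

_SALIVA_HNP_BASE = 20.0
_GCF_HNP_BASE = 200.0  # 10-fold GCF-over-saliva HNP scaling


@dataclass
class PeakSpec:
    """Ground truth for one injected peak."""

    centroid_mz: float
    base_intensity: float
    folds: dict = field(default_factory=dict)  # label -> positive multiplier
    name: str = ""

    def __post_init__(self) -> None:
        for lab, f in self.folds.items():
            if f <= 0:
                raise ValueError(f"fold for {lab} must be positive")

    def fold(self, label) -> float:
        return float(self.folds.get(Label(label).value, 1.0))

    @property
    def differential(self) -> bool:
        vals = [self.fold(lab) for lab in (Label.CONTROL, Label.FOA, Label.IN)]
        return max(vals) / min(vals) > 1.0 + 1e-9


@dataclass
class CohortConfig:
    """All knobs of the forward model; defaults match the study conditions."""

    fluid: Fluid = Fluid.SALIVA
    n_per_class: int = 15
    mz_range: tuple = (2000.0, 20000.0)
    grid_step: float = 1.0
    panel: Optional[list] = None          # None -> default_panel(fluid)
    resolution: float = 300.0             # m / FWHM
    baseline_amplitude: float = 30.0
    baseline_decay: float = 3000.0        # Da/e e-folding of chemical noise
    noise_sd: float = 0.5
    mass_jitter_ppm: float = 300.0
    intensity_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.fluid = Fluid(self.fluid)
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        if self.mass_jitter_ppm > 1000:
            raise ValueError("mass jitter above 1000 ppm defeats recalibration")
        lo, hi = self.mz_range
        if self.panel is None:
            # defaulted panel follows a narrowed analysis window
            self.panel = [p for p in default_panel(self.fluid)
                          if lo <= p.centroid_mz <= hi]
        for p in self.panel:
            if not (lo <= p.centroid_mz <= hi):
                raise ValueError(
                    f"panel centroid {p.centroid_mz} outside m/z range")

    def grid(self) -> np.ndarray:
        lo, hi = self.mz_range
        return np.arange(lo, hi + 0.5 * self.grid_step, self.grid_step)

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def _filler_peaks(fluid: Fluid, avoid: list, n: int = 24) -> list:
    """Deterministic class-neutral peaks spread over the analysis range."""
    rng = np.random.default_rng(0xF1 if fluid == Fluid.SALIVA else 0xF2)
    taken = np.array(avoid, dtype=float)
    fillers = []
    while len(fillers) < n:
        m = float(rng.uniform(2100, 19000))
        fwhm = m / 300.0
        if np.all(np.abs(taken - m) > 3 * fwhm):
            amp = float(rng.uniform(5, 60))
            fillers.append(PeakSpec(centroid_mz=m, base_intensity=amp,
                                    name=f"filler_{len(fillers):02d}"))
            taken = np.append(taken, m)
    return fillers


def default_panel(fluid) -> list:
    """The default peak panel for one fluid.

    Contains the fluid's ten discriminating masses with their reported class
    fold structure, the HNP-1/2/3 triplet, the two cluster-analysis masses,
    and 24 class-neutral fillers.
    """
    fluid = Fluid(fluid)
    panel: list = []
    if fluid == Fluid.SALIVA:
        # Treated groups elevated; IN dominates for 6058.96 / 10710.72,
        # IN ~ FOA for 2124.46 / 2317.74.
        fold_map = {
            2124.46: (2.0, 2.0), 2317.74: (1.9, 1.9), 2972.16: (1.6, 2.0),
            3965.61: (1.5, 2.1), 4471.34: (0.84, 0.56), 6058.96: (1.4, 3.0),
            6401.79: (1.5, 2.2), 7454.8: (1.6, 2.0), 10710.72: (1.4, 3.0),
            12614.78: (1.5, 2.2),
        }
        base_map = {2124.46: 30, 2317.74: 25, 2972.16: 18, 3965.61: 22,
                    4471.34: 3.0, 6058.96: 15, 6401.79: 12, 7454.8: 10,
                    10710.72: 8, 12614.78: 6}
        for m in SALIVA_DISCRIMINATING:
            foa, in_ = fold_map[m]
            panel.append(PeakSpec(centroid_mz=m, base_intensity=base_map[m],
                                  folds={"foa": foa, "in": in_},
                                  name=f"disc_{m:g}"))
        # Cluster-analysis mass 5502.59: controls high, both treated low.
        panel.append(PeakSpec(centroid_mz=5502.59, base_intensity=3.2,
                              folds={"foa": 0.58, "in": 0.59},
                              name="disc_5502.59"))
        hnp_base = _SALIVA_HNP_BASE
        # Saliva: IN ~3-fold over control, FOA only slightly raised.
        hnp_folds = {"foa": 1.2, "in": 3.0}
    else:
        fold_map = {
            3440.58: (1.744, 1.670),   # class averages 76 / 132.6 / 126.9
            7673.14: (2.0, 1.8), 3707.6: (2.5, 1.6), 9624.63: (1.9, 1.8),
            2401.45: (1.8, 2.0), 3553.58: (1.9, 1.9), 7007.2: (2.5, 1.6),
            8307.4: (1.8, 1.9), 13460.52: (2.0, 1.8), 14006.13: (2.5, 1.6),
        }
        base_map = {3440.58: 76, 7673.14: 30, 3707.6: 40, 9624.63: 20,
                    2401.45: 35, 3553.58: 28, 7007.2: 25, 8307.4: 18,
                    13460.52: 10, 14006.13: 8}
        for m in GCF_DISCRIMINATING:
            foa, in_ = fold_map[m]
            panel.append(PeakSpec(centroid_mz=m, base_intensity=base_map[m],
                                  folds={"foa": foa, "in": in_},
                                  name=f"disc_{m:g}"))
        hnp_base = _GCF_HNP_BASE
        # GCF: both treated groups ~2-fold over control.
        hnp_folds = {"foa": 2.0, "in": 2.0}
    # HNP triplet, apex ordering 1 : 0.5 : 0.33.
    for name, ratio in (("HNP-1", 1.0), ("HNP-2", 0.5), ("HNP-3", 1 / 3)):
        panel.append(PeakSpec(centroid_mz=HNP_MASSES[name],
                              base_intensity=hnp_base * ratio,
                              folds=dict(hnp_folds), name=name))
    panel.extend(_filler_peaks(fluid, [p.centroid_mz for p in panel]))
    return panel


def generate_spectrum(config: CohortConfig, label, rng: np.random.Generator,
                      sample_id: str = "synthetic") -> Spectrum:
    """Draw one spectrum from the forward model.

    intensity(m) = baseline * exp(-(m - lo)/decay)
                 + sum_p base_p * fold_p(label) * LogNormal(cv) * G(m; c_p*(1+jitter))
                 + Normal(0, noise_sd),   clipped at zero,

    where G is a unit-apex Gaussian with FWHM = centroid / resolution and
    jitter is one uniform draw in +-mass_jitter_ppm shared by all peaks of the
    spectrum (a multiplicative calibration error).
    """
    label = Label(label)
    mz = config.grid()
    lo = config.mz_range[0]
    y = config.baseline_amplitude * np.exp(-(mz - lo) / config.baseline_decay)

    jitter = rng.uniform(-1.0, 1.0) * config.mass_jitter_ppm * 1e-6
    cv = config.intensity_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv * cv))
        mu = -0.5 * sigma * sigma  # unit-mean log-normal
    for p in config.panel:
        amp = p.base_intensity * p.fold(label)
        if cv > 0:
            amp *= float(rng.lognormal(mu, sigma))
        c = p.centroid_mz * (1.0 + jitter)
        fwhm = p.centroid_mz / config.resolution
        sd = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        win = 5.0 * fwhm
        i0, i1 = np.searchsorted(mz, [c - win, c + win])
        seg = mz[i0:i1]
        y[i0:i1] += amp * np.exp(-0.5 * ((seg - c) / sd) ** 2)
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=len(mz))
    return Spectrum(mz=mz, intensity=np.clip(y, 0.0, None),
                    sample_id=sample_id, fluid=config.fluid, label=label)


def manifest_frame(config: CohortConfig) -> pd.DataFrame:
    """Ground-truth manifest: one row per injected peak."""
    rows = []
    for p in config.panel:
        rows.append({
            "name": p.name,
            "centroid_mz": p.centroid_mz,
            "base_intensity": p.base_intensity,
            "fold_control": p.fold(Label.CONTROL),
            "fold_foa": p.fold(Label.FOA),
            "fold_in": p.fold(Label.IN),
            "mean_amp_control": p.base_intensity * p.fold(Label.CONTROL),
            "mean_amp_foa": p.base_intensity * p.fold(Label.FOA),
            "mean_amp_in": p.base_intensity * p.fold(Label.IN),
            "differential": p.differential,
        })
    return pd.DataFrame(rows).sort_values("centroid_mz").reset_index(drop=True)


def generate_cohort(config: CohortConfig):
    """Generate a labeled cohort plus its ground-truth manifest.

    Returns ``(SpectrumSet, DataFrame)``.  The draw order is fixed (all
    controls, then FOA, then IN) so a given seed reproduces the cohort
    bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    spectra = []
    for lab in (Label.CONTROL, Label.FOA, Label.IN):
        for i in range(config.n_per_class):
            sid = f"{config.fluid.value}_{lab.value}_{i:02d}"
            spectra.append(generate_spectrum(config, lab, rng, sample_id=sid))
    manifest = manifest_frame(config)
    if not spectra:
        return SpectrumSet(spectra=[], fluid=config.fluid,
                           class_names=["control", "foa", "in"]), manifest.iloc[0:0]
    cohort = SpectrumSet(spectra=spectra, fluid=config.fluid,
                         class_names=["control", "foa", "in"])
    return cohort, manifest
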