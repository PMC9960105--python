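# maldi-profiler

An open, tested reimplementation of the MALDI-TOF/MS profiling-and-
classification workflow used to screen **whole saliva** and **gingival
crevicular fluid (GCF)** during orthodontic treatment — the kind of analysis
usually run inside closed commercial software. It targets three balanced
groups per fluid: orally healthy controls, patients with fixed orthodontic
appliances (FOA), and patients using Invisalign aligners (IN), and asks
whether their linear-mode protein/peptide fingerprints (m/z 2000–20,000)
can be told apart.

The package is aimed at mass-spectrometry and clinical-proteomics
researchers who want every step of such a pipeline — preprocessing, peak
picking, per-peak statistics, classifier training and validation —
inspectable, scriptable and reproducible. Because cohorts of this kind are
rarely deposited, a first-class synthetic-data module generates cohorts
with the reported statistical structure (including the α-defensin HNP-1/2/3
triplet at m/z 3442/3371/3486), so the whole chain can be exercised and
tested end to end.

## What it computes

**Preprocessing** (per spectrum): restriction to m/z 2000–20,000; baseline
subtraction by the Top-Hat transform `y − (y ∘ B)` with a flat structuring
window `B` of width 10% of the mass range on the m/z axis; 10 cycles of a
Savitzky–Golay filter of width 5 m/z; total-ion-current normalization; and
recalibration by a single multiplicative stretch fitted to calibrant
matches within 1000 ppm (spectra matching <10% of calibrants are flagged
and left unshifted).

**Peak picking** on the total average spectrum `ȳ(m) = mean_i y_i(m)`:
local maxima with signal-to-noise ≥ 4, where S/N is apex height above the
local median floor divided by a windowed-MAD noise estimate, deduplicated
at one FWHM (FWHM = m/R, resolving power R = 300), with integration regions
±1 FWHM truncated at inter-peak midpoints. Integrated areas (or maximal
intensities) form the samples × peaks matrix all classifiers consume.

**Per-peak statistics**: `Dave = max_c x̄_c − min_c x̄_c` (class-average
separation), `PTTA` (t-test / one-way ANOVA p), `PWKW` (Wilcoxon /
Kruskal–Wallis p), `PAD` (Anderson–Darling normality p on pooled
within-class residuals), plus class means ± SD. A balanced one-way ANOVA
power calculation via the noncentral F distribution
(λ = f²·N, Cohen's f) sizes cohorts.

**Classifiers** with a uniform train/predict contract:

* **GA** — genetic-algorithm selection of exactly 10 peaks (50 generations,
  mutation 0.2, crossover 0.5), fitness = stratified 5-fold CV accuracy of
  a 5-nearest-neighbour classifier on standardized columns;
* **SNN** — a prototype classifier (LVQ1: 5 prototypes per class, k-means
  init, 50 attract/repel epochs with decaying learning rate);
* **QC** — quick classifier: p-value-ranked peaks, automatic prefix-size
  detection, weights `w_j = −log10 p_j`, per-class output weights that sum
  to 1.

**Validation**: recognition capability (RC, training-set accuracy in %) and
cross-validation (CV, stratified 20%-holdout × 10 with full retraining per
split). **Reports**: 2-D peak scatter with 95% confidence ellipses
(χ²₂-scaled covariance ellipses), class-average spectrum overlays, and
pseudo-gel views — all with numeric CSV backing.

## Worked example

```python
from maldi_profiler import (CohortConfig, GAParams, build_peak_matrix,
                            estimate_noise, generate_cohort, pick_peaks,
                            preprocess_set, recognition_capability,
                            stats_table, total_average_spectrum, train_ga)

cfg = CohortConfig(fluid="gcf", seed=1)          # 3 classes x 15 spectra
cohort, manifest = generate_cohort(cfg)
pre = preprocess_set(cohort, reference_peaks=sorted(manifest["centroid_mz"]))
avg = total_average_spectrum(pre)
peaks = pick_peaks(avg, estimate_noise(avg), snr_threshold=4.0, resolution=300.0)
print(f"picked {len(peaks)} peaks from the total average spectrum")

matrix = build_peak_matrix(pre, peaks)
print(stats_table(matrix).sort_values("ptta")
      .head(3)[["mass", "dave", "ptta", "pwkw", "pad"]].to_string(index=False))

model = train_ga(matrix, GAParams(seed=1))
rc, _ = recognition_capability(model, matrix)
print(f"GA model: {len(model.peak_indices)} peaks, recognition capability {rc}%")
```

prints

```
picked 63 peaks from the total average spectrum
       mass     dave         ptta         pwkw      pad
7006.980058 0.014999 1.169326e-11 2.050921e-07 0.107297
2049.967366 0.000249 8.960945e-11 9.172959e-07 0.206238
2099.987829 0.000228 1.362687e-10 1.499706e-06 0.726569
GA model: 10 peaks, recognition capability 95.56%
```

63 peaks clear the S/N ≥ 4 threshold on this cohort's average spectrum.
The most discriminative peak is the injected FOA-elevated mass near m/z
7007; its tiny `PTTA`/`PWKW` reflect the planted ~2.5-fold class effect at
15 samples per class, and `PAD` ≈ 0.11 does not reject normality of the
within-class scatter. (The low-mass entries with small `Dave` are
TIC-normalization echoes of the class effect in the baseline region — a
real feature of intensity-normalized cohorts.) The GA keeps exactly 10
peaks by construction and classifies 43/45 training spectra correctly
(RC = 95.56%).

The same study runs end to end from the shell:

```bash
maldi-profiler run-all out/ --seed 1            # both fluids, all stages
cat out/summary.csv                             # model x fluid RC/CV table
```

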