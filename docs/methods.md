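# Methods

This note records the scientific and numerical choices behind
`maldi_profiler`: the forward model the synthetic cohorts are drawn from,
the preprocessing and peak-picking semantics, the statistics, the three
classifier families, and the places where a published parameter set left
the mechanism open and a concrete choice had to be made.

## The study design being emulated

Two fluids (whole saliva and gingival crevicular fluid, GCF) from the same
45 participants: 15 orally healthy controls, 15 with fixed orthodontic
appliances (FOA), 15 with Invisalign (IN). Linear positive-mode MALDI-TOF
profile spectra analyzed over m/z 2000–20,000. The cohort size follows a
balanced one-way ANOVA power calculation: Cohen's f = 0.48, k = 3 groups,
α = 0.05, target power 0.8 → N = 45 (the package's `anova_power` confirms
power ≥ 0.8 at these inputs via the noncentral F distribution with
λ = f²·N, and `required_n` brackets the minimal balanced N).

## Synthetic cohort forward model

Real cohorts of this kind are not publicly deposited, so every downstream
stage is developed and tested against a generator whose *defaults are the
study conditions*:

```
y(m) = A_b · exp(−(m − m_lo)/τ)                          chemical background
     + Σ_p  a_p · G(m; c_p(1+δ), c_p/R)                  peaks
     + ε(m),   ε ~ N(0, σ_n),   clipped at 0
```

* `G` is a unit-apex Gaussian with FWHM = centroid/R; R = 300 is the
  instrument resolving power, so FWHM grows from ~6.7 Da at m/z 2000 to
  ~67 Da at 20,000.
* `δ` is one uniform draw per spectrum in ±300 ppm — a multiplicative
  calibration error, deliberately below the 1000 ppm matching window so
  recalibration can succeed.
* `a_p = base_p · fold_p(class) · LogNormal(CV = 0.3)` — the lognormal CV
  matches the ~20–40% relative class SDs reported for peaks of this kind.
* Background: `A_b = 30`, `τ = 3000 Da`, `σ_n = 0.5` (arbitrary units,
  peak bases span 3–200). These were chosen once as plausible linear-mode
  MALDI values; none is derivable from the published parameters.

The default panels contain, per fluid: the ten reported discriminating
masses with fold structure matching the reported class differences, the
α-defensin triplet HNP-1/2/3 at m/z 3442/3371/3486 with apex ratios
1 : 0.5 : 0.33 (HNP-1 ≈ 2× HNP-2 ≈ 3× HNP-3), and ≥ 20 class-neutral
filler peaks. HNP folds: GCF treated ≈ 2× control; saliva IN ≈ 3× control
with FOA only slightly raised; GCF HNP bases are 10× the saliva ones. The
two cluster-analysis masses (saliva 5502.59 and 4471.34) follow the
published class-average table, where controls are *higher* — note that
table contradicts the prose claim that all saliva panel peaks are elevated
under IN; the table's numbers were used.

Every injected peak is recorded in a manifest (centroid, base, per-class
folds, differential flag), which is the ground-truth oracle for the
recovery tests.

**What the generator does not emulate:** isotope envelopes, detector
saturation, multiply charged ions, non-uniform TOF grids (readers accept
them; the simulator emits a uniform 1 Da grid), within-class *covariance*
between peaks (scatter is independent per peak), and matrix-suppression
effects below m/z 2000. Passing tests therefore demonstrate correctness of
the pipeline's operations and recoverability of planted effects under
these idealizations — not clinical performance on real fluids.

## Preprocessing

Canonical order: restrict → Top-Hat → smooth → normalize → recalibrate.

* **Top-Hat baseline.** `y − opening(y)` with a flat structuring window of
  width 10% of the analyzed mass range, *defined on the m/z axis* (not in
  points), computed by an exact monotonic-wedge sliding min/max that is
  O(n) and valid on non-uniform grids. The opening is a lower envelope, so
  output is ≥ 0 and the operation is idempotent. On a sloped baseline a
  narrow peak is recovered up to an error floor of (peak support ×
  baseline slope) — intrinsic to morphology, covered by the brute-force
  oracle test.
* **Savitzky–Golay smoothing**, 10 cycles, window = points within ±2.5 m/z,
  polynomial order 2 (order is configurable; only width and cycle count
  were published). Edge points use shrinking symmetric windows,
  degenerating to the identity at the boundary; non-uniform grids fall
  back to per-point weighted least squares.
* **TIC normalization** scales each trace so its trapezoidal integral is 1.
  Whether the reference analysis normalized intensities is unstated; it is
  on by default, switchable (`normalize: none`), and recorded in the run
  flags. One visible consequence on synthetic cohorts: classes with more
  total signal get globally down-scaled, which imprints a small
  anti-correlated class effect on non-differential regions.
* **Recalibration** fits a single multiplicative stretch (TOF-like) by
  least squares over one-to-one nearest matches between local maxima and a
  calibrant list within ±1000 ppm; a spectrum matching < 10% of calibrants
  is flagged excluded and left unshifted. Per-peak warping was rejected as
  overparameterized for ppm-scale errors.

## Noise estimation and peak picking

The noise profile is a windowed robust scale estimate: the trace is
detrended by subtracting a 20 Da running median, and within 200 Da windows
(hopped by half a window) the residual scale is 1.4826 × MAD, linearly
interpolated between window centers. Median-filter detrending was chosen
over difference filters because the 10-cycle SG filter correlates the
noise; difference filters annihilate exactly those smooth wiggles and can
underestimate the effective noise by an order of magnitude.

Peak picking runs once, on the total average spectrum (pointwise mean of
all spectra interpolated onto the union grid), so all samples share one
peak list. The S/N of a local maximum is its apex height *above the local
median floor* (window ±1.5 FWHM) divided by the noise SD. The floor term
matters because baseline subtraction by an opening leaves a positive
pedestal of ~2.5σ on noisy traces, and cohort averaging shrinks the noise
but not the pedestal; raw apex/noise would then pass essentially
everywhere. Height-above-local-baseline over noise is also how vendor
software defines peak S/N. The threshold (default 4) is inclusive — a peak
at exactly S/N 4.0 is kept. Deduplication: among maxima closer than one
FWHM of the higher one, the higher wins. Integration regions are
±1 FWHM, truncated at midpoints between adjacent accepted centroids;
region bounds are clipped to each spectrum's span (recalibration stretches
individual grids by ~100 ppm, so union-grid edge peaks may overhang a
single spectrum slightly); a region that misses a spectrum entirely is an
error. Both integrated area (default) and maximal intensity are supported.

## Per-peak statistics

Per peak: `Dave` = max − min of class means; `PTTA` = Student t (2 classes)
or one-way ANOVA (≥ 3); `PWKW` = Wilcoxon rank-sum (2) or Kruskal–Wallis
(≥ 3) — "Wilcoxon" cannot compare three groups, and Kruskal–Wallis is its
standard k-sample generalization; `PAD` = Anderson–Darling normality p on
within-class residuals pooled per peak (one PAD per peak). The AD p-value
uses A² with estimated moments, the (1 + 0.75/n + 2.25/n²) small-sample
correction and the Stephens piecewise-exponential tail approximation; it
agrees with R's `nortest::ad.test` to ~7 digits (tested). Constant columns
report p = 1 with a flag rather than NaN; pooled residual samples smaller
than 8 report PAD = 1 (too little data to assess normality). No
multiple-testing correction is applied by default (none was part of the
published protocol); Benjamini–Hochberg columns are available on request.

## Classifiers

All trainers z-score each column with training statistics before any
distance computation (peak areas span orders of magnitude), are
deterministic given a seed, and serialize to versioned JSON that
round-trips predictions bit-for-bit.

* **GA.** Chromosomes are peak-index subsets of size exactly
  `max_best_peaks` (10), since the reference tool reports exactly that
  many generated peaks. Fitness is mean stratified 5-fold internal-CV
  accuracy of a k-NN (k = 5, Euclidean, deterministic tie-breaks), *not*
  training accuracy, to prevent trivial overfit selection. Population 64,
  2-way tournament selection, elitism of 1, single-point crossover on
  sorted index lists with dedup-and-refill repair at rate 0.5, per-gene
  replacement mutation at rate 0.2, 50 generations. Fitness values are
  cached per subset. On ≤ 6-peak instances the GA provably reaches the
  exhaustive-search optimum (tested).
* **SNN.** "Supervised neural network" with "prototypes" is realized as an
  LVQ1 prototype classifier, not a multilayer perceptron: 5 prototypes per
  class initialized by k-means on that class's rows, then 50 epochs of
  attract-correct / repel-incorrect updates with a linearly decaying
  learning rate (0.3 → 0). Its peak subset is chosen by PTTA ranking with
  the subset size (from a small candidate grid) maximizing internal-CV
  accuracy — some selection mechanism must exist, since the reference
  reports 7–25 peaks for this model family; the exact mechanism is
  unpublished.
* **QC.** Peaks sorted by ascending p-value (PTTA by default); for each
  prefix size the internal-CV accuracy of the weighted-centroid rule is
  computed and the smallest size within one standard error of the maximum
  is kept ("automatic detection"). Peak weights are −log₁₀ p; prediction
  returns softmax(−weighted Euclidean distance to each class mean), a
  normalized per-class weight vector, with the heaviest class as label.

## Validation

RC = percent of training spectra classified correctly (with full confusion
counts; the percentage always equals the confusion-matrix ratio).
CV = stratified repeated random subsampling, 20% held out, 10 repetitions,
with the *entire* selection + training rerun inside each split; the picked
peak list itself is shared (picking happens on the average spectrum before
any model sees the data; a per-split re-pick is available via the stage
API but not default). Percentages are rounded to two decimals, half up,
matching the reporting granularity (40/45 → 88.89%).

## Reports

Fig-style outputs carry their numbers as CSV. "95% confidence ellipses"
are interpreted as 95% *data* ellipses — sample covariance scaled by the
χ²(2) quantile (semi-axes √(5.991·λᵢ)) — not standard-error-of-mean
ellipses; Monte-Carlo coverage is verified at 0.95 ± 0.01. Gel views are
row-normalized intensity rasters (rows = spectra sorted by class); the
colour map is a rendering detail.

## Pipeline and reproducibility

`run_pipeline` chains simulate → preprocess → pick → matrix → stats →
train(GA,SNN,QC) → validate → report per fluid; each stage reads only the
previous stage's serialized artifact, so runs restart from any stage. One
global seed fans out to per-stage, per-fluid seeds via
`numpy.random.SeedSequence` keyed by a CRC of the fluid name — models get
independent streams ("varying random seed") while the whole run is
bit-reproducible. Default problem sizes (45 spectra per fluid on an
18,001-point grid; CV with 10 repeats) run in minutes on one core; the
test suite uses narrowed m/z windows and fewer repeats where full-range
realism is not what is being tested.

## Known limitations

* The reference tool's internals (its exact noise estimator, GA encoding,
  SNN architecture, QC weight formula, CV scheme) are proprietary; this
  package implements parameter-faithful, behaviour-plausible versions and
  records every such choice here and in model/run metadata. Its published
  per-peak p-values cannot be reproduced from printed summary statistics
  (a plain ANOVA on the printed means/SDs gives far smaller values than
  the printed 0.000911), so printed p-values are not targets.
* Published peak counts and RC/CV percentages depend on the unavailable
  clinical spectra; the package reproduces the *shape* of those results on
  synthetic cohorts (RC ≫ CV, ten GA peaks), not their exact values.
* Integrated areas of peaks closer than ~3 FWHM mix their class effects;
  fold-recovery guarantees hold for isolated peaks.
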