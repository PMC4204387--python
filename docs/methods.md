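# Methods

This note documents the models implemented by melaspec, the assumptions they
make, the parameters that matter, and the design choices taken where the
original protocol left the design open.

## Data model

A *sample* is six spectral scans of one skin site: P-polarized (single
scattered, polarization preserving) and V-polarized (multiple scattered)
scans of two lesion spots and one nearby normal-skin spot. Each scan is a
32 × 512 matrix of non-negative CCD intensities; rows are detector lines
(the bright line sits at row 15, 1-based, in the emulated device) and
columns are spectral channels. Labels are +1 (melanoma) and −1 (benign);
melanoma is the positive class everywhere.

The original vendor encoding of scan files is not recoverable, so the
package defines two portable layouts: headerless little-endian float32,
row-major (`.f32`), and a comma-separated text matrix (`.csv`). Pixel
indices in documentation and error messages are 1-based with (1, 1) stored
first. Whether the device stored integers or floats is unknown; the float
layout sidesteps the question. Cohorts are described by a manifest CSV
(`sample_id,label,p1,p2,p3,v1,v2,v3`).

## Preprocessing

1. **Median filter.** The window size of the original denoiser is
   unreported; the default is the minimal 3 × 3 window with reflection
   padding (edge pixel included in the mirror), configurable per call.
   Whether the original filter was 1-D along the spectral axis or 2-D is
   also unreported; the default is 2-D, and a 1-D spectral filter can be
   requested as a (1, w) window.
2. **Min-max normalization** is per image — each scan is scaled against its
   own extrema, so the output attains exactly 0 and 1. A constant scan is
   rejected as a degenerate input (the transform is undefined, and a flat
   CCD frame indicates acquisition failure) rather than silently mapped to
   zero. Normalization is invariant under positive affine transforms of the
   input, which is what removes per-subject multiplicative device gain.
3. **Corrected intensity** Ī = (lesion1 + lesion2)/2 − normal, per
   polarization, on the normalized scans. Values are signed in [−1, 1] and
   are *not* clipped: the downstream statistics handle sign via absolute
   values and squares where appropriate. Subtracting the subject's own
   normal skin removes additive baselines (skin tone, age effects) that are
   common to all six scans.

Order matters and is fixed: filter, then normalize, then correct. Filtering
first prevents impulse outliers from stretching the normalization range.

## Features

Each corrected image is summarised by mean μ, standard deviation σ
(population divisor m·n, exactly as the defining formula is written — not
m·n − 1), mean absolute deviation MAD, L1 norm and L2 norm. μ and σ are
computed on the signed values; MAD ≤ σ and ‖x‖₂ ≤ ‖x‖₁ ≤ √(mn)·‖x‖₂ hold
for every input and are enforced as property tests. The 10-vector is
ordered (p_mean, p_sd, p_mad, p_l1, p_l2, v_mean, v_sd, v_mad, v_l1, v_l2);
the original feature order is unrecorded, so this documented order is
canonical for all tables and models. No feature selection is performed.

## Classifiers

All three learners are implemented in this package behind one
train/predict contract and are bit-deterministic given (data, spec).
Configurations mirror the classic defaults of the desktop toolkit era the
pipeline comes from.

**Naive Bayes.** Class priors are class frequencies. Each feature gets a
per-class Gaussian with the population SD floored at *precision*/6, where
precision is the mean gap between consecutive distinct sorted training
values of that feature (default 0.01 when fewer than two distinct values
exist). The floor mirrors the numeric-estimator behaviour of the historical
tool; its exact constants are unrecoverable, so the divisor is configurable
(`nb_sd_floor_divisor`) and recorded in the model file. Posteriors are
normalized to sum to one; exact ties resolve to benign, the clinically
conservative call. Features are not scaled for NB (per-feature Gaussians
are location/scale-free; predictions are invariant to common positive
scaling whenever the floor is inactive).

**k-NN.** Brute-force Euclidean search, k = 3 (odd k required, so binary
vote ties cannot occur), majority vote, distance ties broken by training
order via a stable sort. Features are min-max scaled to [0, 1] using
training ranges (constant features map to 0).

**MLP.** Fully connected 10 → 6 → 2, sigmoid everywhere. The hidden size
follows the half-of-(inputs+outputs) rule and is configurable, as any
tuning done after the original initial choice is unreported. Inputs are
min-max scaled to [0, 1]; targets are one-hot; weights and biases start
uniform in [−0.5, 0.5] from the seed; training is per-sample (online)
back-propagation of squared error with momentum on the previous update,
samples visited in table order for a fixed 500 epochs (learning rate 0.3,
momentum 0.2). No validation split is configured, so early stopping is
inert. Class imbalance is deliberately not reweighted — the original
evaluation applied no correction, and reproducing its behaviour (including
low ANN/k-NN sensitivity under imbalance) is part of the point.

## Evaluation protocol

Repeated random subsampling: `n_train` cases for training (default 60 of
187), the rest for testing, repeated 25 times; per-run randomness comes
from an independent substream of (seed, run_index) so any single run is
reproducible in isolation. Sensitivity = TP rate on melanoma,
specificity = TN rate on benign, accuracy overall; a metric whose
denominator class is absent from the truth is NaN and flagged, never
silently zero. Averages are arithmetic means at full precision; tables
render one decimal, half-up.

Splits are **stratified by default**: the published per-run sensitivities
are all integer multiples of 100/13, which implies exactly 13 melanoma
cases in every 127-case test set — i.e. proportional stratification of the
19:168 cohort (6 melanoma in every 60-case training set). Unstratified
splitting is available and recorded in the report. Whether the original
repetitions reused one split list across classifiers is unknown; here the
split sequence is a function of the split seed alone, so classifiers
evaluated with the same seed see identical partitions.

The published "probability of error" figures (0.16 / 0.24 / 0.26) do not
equal 1 − accuracy for any reported configuration and their definition is
unrecoverable; this package reports error_rate = 1 − accuracy/100 and makes
no attempt to reverse-engineer the printed values.

## Synthetic cohort generator

No raw clinical data is available, so every downstream stage is exercised
on synthetic cohorts. The generator is a modelling device for the
pipeline's assumptions, not a light-transport simulation. Each scan is
built in normalized-intensity space as

    target = clip(ridge(i) · spectrum(j) + envelope(i) · bulk(i, j), 0, 1)

and mapped to an arbitrary positive raw scale with a per-subject
multiplicative gain (log-normal, `subject_shift_sd`, default 0.15) shared
by all six scans. The components:

- **ridge(i) · spectrum(j)** — the bright detector line (Gaussian row
  profile at `peak_row`, default 15) times a smooth spectral profile; its
  crest saturates at 1 and anchors the per-image maximum.
- **envelope(i)** — edge vignetting: the outermost detector rows read near
  dark level, anchoring the per-image minimum.
- **bulk(i, j)** — diffuse tissue signal: a per-subject skin-tone offset
  (SD 0.03, shared by all six scans, removed by the lesion-minus-normal
  correction), a per-scan diffuse level (SD 0.025, probe-spot
  heterogeneity), per-pixel texture with per-scan amplitude (median 0.03,
  log-SD 0.3) and per-scan tail weight (standardized Student-t, df uniform
  in [3, 20]), and — on lesion spots only — bright micro-specks (Gaussian
  bumps, mean count 35, log-SD 0.8, amplitude ≈ 0.55, σ ≈ 1.3 px) wide
  enough to survive the 3 × 3 median filter, plus the class effect.

Benign lesion spots add a small diffuse excess (0.01) over normal skin, so
normalized benign pixels concentrate in the 0.2–0.4 band. Melanoma lesion
spots additionally add `effect_size` × (0.12 + 0.55 · Beta(2.2, 1.3)) per
pixel, producing the broad, high-intensity-heavy distribution over [0, 1];
at `effect_size` 0 the two classes are drawn from the identical
distribution. Impulse (salt-and-pepper) noise is injected per pixel at
`noise_rate` (default 0.002) — impulse rather than Gaussian noise because
the pipeline's denoiser is a median filter and should have something real
to remove. Scans are emitted at float32 precision, so identical specs are
bit-identical across runs and file round-trips are exact.

The per-scan heterogeneity terms (level, texture amplitude, tail weight,
speck rate) exist to give the five statistics of a corrected image honest,
partially independent between-sample variation; the magnitudes were chosen
once, against the generator's own contract (benign band concentration,
melanoma spread, zero-effect calibration below), and frozen.

Distribution targets are **per image**: the original class-conditional
histograms pool all images per class, and pooled and per-image targets are
indistinguishable from what survives of the study, so the generator aims at
the per-image reading and documents that choice.

What the generator does *not* emulate: optics and light transport, 
wavelength calibration, spatial correlation of real tissue texture beyond
the speck scale, device drift between sessions, and multi-sample
participants (each synthetic sample is an independent subject). Passing
tests on synthetic cohorts therefore demonstrate the pipeline's mechanics
and its behaviour under a known generative model — not clinical
performance.

## Known limitations

- **Zero-effect naive-Bayes calibration.** With stratified 60/127 splits
  the melanoma class contributes only 6 training samples. Gaussian NB with
  10 features is then measurably miscalibrated at the null: spurious
  class-mean gaps of order σ/√6 accumulate over features, and because the
  five statistics of any corrected image are intrinsically correlated
  (σ with MAD, L1 with L2), the log-likelihood-ratio noise is amplified
  further. Simulation shows mean null accuracy of ~87.5 % even for ideal
  independent Gaussian features and ~78–84 % for any feature set derived
  from real images, versus the 89.8 % always-benign baseline; this package
  measures ~80–82 % (scikit-learn's GaussianNB behaves the same). The
  zero-effect acceptance check asserts the ±3-point idealization and is
  expected to fail; the number it measures is reported by the acceptance
  script as `null_nb_accuracy`.
- The NB sd-floor constants and the MLP's post-initialization tuning (if
  any) in the original tool chain are unrecoverable; both are configurable
  and their defaults documented above.
- At the generator's nominal effect size the synthetic classes separate
  almost perfectly (all classifiers near 100 %), so synthetic accuracies
  are ceiling-limited and should not be compared numerically with the
  published clinical averages; the published table arithmetic is checked
  exactly instead.
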