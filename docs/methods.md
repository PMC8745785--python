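# Methods

## Problem and pipeline

The package classifies fixed-length windows of a single-lead nocturnal
ECG as normal breathing (N) or disordered breathing (A; apnea and
hypopnea are merged into one positive class). The processing chain is:

1. **Preprocessing** — subtract the record mean ("zero-means"), cut the
   signal into consecutive non-overlapping windows of 60 s (the native
   annotation granularity) or 10 s (sub-windows inherit the parent
   minute's label), and drop artifact-contaminated windows.
2. **Time–frequency transform** — complex Morlet CWT magnitude
   scalogram per window, restricted to one of four bands.
3. **Bag of visual features** — keypoint detection and 64-d SURF-style
   description on the rendered scalogram image, vector quantization
   against a k-means codebook, L1-normalized word histograms.
4. **Classification and validation** — SVM / KNN / bagged trees /
   random-subspace KNN, under window-level stratified k-fold CV,
   leave-one-subject-out CV, or REM/NREM stage-stratified evaluation.

## Continuous wavelet transform

The transform is taken in the L1-normalized convention
X_w(s, τ) = (1/s) ∫ x(t) ψ\*((t − τ)/s) dt with a complex Morlet wavelet
of the conventional ω₀ ≈ 6 parameterization (unit-variance Gaussian
envelope, center frequency 6/2π ≈ 0.9549 cycles per unit time; PyWavelets
name `cmor2.0-0.9549`). PyWavelets computes the L2-normalized transform,
so rows are rescaled by s^(−1/2). Under the L1 convention a pure tone has
a scale-independent ridge amplitude, which keeps the ridge unbiased: on
the default scale grid a 10 Hz tone localizes to within ~0.2% (the grid
step itself is 2^(1/12) ≈ 5.9%).

Scales are log-spaced at 12 voices per octave spanning each band
(configurable). Presets: overall 0.1–50 Hz, high 8–50 Hz, middle
0.8–10 Hz, low 0–0.8 Hz, with the low band's 0 Hz edge floored at
0.05 Hz — the lowest frequency a 60 s window resolves meaningfully. The
low band is refused for 10 s windows, which are too short to carry
sub-hertz variation. Band extraction is row slicing of a computed
scalogram; the 0.8–10 and 8–50 Hz presets intentionally share the
8–10 Hz rows.

Rendering compresses magnitudes with log1p by default (matching the
dB-like dynamic range scalograms are usually displayed with; `linear` is
available), min-max normalizes each image independently to [0, 255], and
resamples the time axis to 256 columns by linear interpolation, highest
frequency at the top. A constant scalogram renders all-zero rather than
erroring. Per-image normalization deliberately discards absolute
amplitude: classification rests on time–frequency *texture*, not global
signal scale.

## Artifact screening

The source databases removed "contaminated" windows by an unstated
manual criterion. Here contamination is three explicit tests, applied in
order, with the first violation reported: amplitude clipping
(|v| > 5 mV), flatline runs (> 1 s within 1 µV), and in-band power ratio
(fraction of Welch-PSD power in 0.5–40 Hz below 0.5). All thresholds are
configurable (`ArtifactPolicy`); this is a declared, reproducible
stand-in, not a reconstruction of the original screening.

## Bag of visual features

Descriptors follow the SURF layout: a 20s × 20s window around a keypoint
of scale s px, 4×4 subregions, 5×5 Haar-response samples per subregion
(filter size 2s, Gaussian weighting σ = 3.3s), pooled as (Σdx, Σdy,
Σ|dx|, Σ|dy|) per subregion → 64 dimensions, L2-normalized. They are
computed natively from integral images; the `surf` detector finds
determinant-of-Hessian extrema at three smoothing scales — the SURF
detection principle — while `dense` samples a regular grid at a fixed
scale. Dense sampling is the default for the pipeline: spectrograms are
texture-like images with no guaranteed blob structure, and dense BoF
sampling is the standard, deterministic choice in that regime. A
scikit-image ORB detector is exposed for comparison (256-bit binary
descriptors, dimension override).

The codebook is k-means (k-means++ init, one restart, 300 iterations
max, tolerance 1e-4, fixed seed) over descriptors pooled from training
images, keeping the strongest 80% of keypoints per image by detector
response. K defaults to 500 for real corpora; the synthetic study uses
K = 200 (the corpora are far smaller than a full night-study corpus).
Encoding is hard assignment to the Euclidean-nearest centroid (ties to
the lowest index) with L1 normalization — plain occurrence histograms,
no TF-IDF, spatial pyramids, or soft assignment. An image with no
keypoints encodes as the uniform histogram 1/K and is flagged
degenerate. `build_codebook` refuses any image tagged `split="test"`.

The codebook is learned once per corpus and shared across CV folds: the
vocabulary is unsupervised (label-free), and this mirrors the common
toolbox workflow of building a bag-of-features vocabulary before running
classifier cross-validation. Per-fold rebuilding is available
(`ExperimentConfig.codebook_per_fold`) for strict subject-level
protocols.

## Classifiers and validation

SVM uses an RBF kernel; the default grid is C ∈ {0.1, 1, 10, 100},
γ ∈ {scale, 0.1, 1, 10}. KNN uses k ∈ {1, 3, 5, 11} with Euclidean or
cosine distance (Mahalanobis is available on request but excluded from
defaults: covariance of sparse histograms is routinely singular). Bagged
trees use 30 bootstrap-resampled decision trees. Subspace KNN uses 30
nearest-neighbor learners on random feature subspaces of dimension
⌈d/2⌉, combined by hard majority vote (the member's probability output
is suppressed so the ensemble genuinely votes). The positive class is A
throughout, so sensitivity is the apnea detection rate. KNN voting ties
resolve to the lexicographically first label; default grids use odd k so
ties cannot occur.

Hyperparameter search is nested stratified 5×5-fold: inner folds score
each grid point by mean accuracy on the outer-training split only; the
winner is refit and scored on the held-out outer fold.

Metrics follow the condition-positive convention (accuracy, sensitivity
= TP/(TP+FN), specificity = TN/(TN+FP)); zero-denominator cases return
NaN with a warning, never a silent zero. K-fold CV is stratified at the
window level — a subject's windows may span folds, deliberately, since
that is what window-level validation means; LOSOCV is the subject-safe
protocol. Aggregates are unweighted fold means (pooled-confusion metrics
are also emitted). In LOSOCV a held-out subject with no positive (or no
negative) windows has an undefined sensitivity (specificity); the
primary average excludes undefined folds and reports the defined-fold
count, and an include-as-zero variant is emitted alongside, since
published per-subject tables print 0 for such rows and their convention
is ambiguous. Stage-stratified evaluation refuses corpora without
REM/NREM labels; optional balancing randomly undersamples the majority
class to the minority count with the given seed (a no-op when already
balanced).

## Synthetic corpus generator

The generator exists to exercise every pipeline stage and validation
scheme with known ground truth; it is a waveform-level stand-in, not a
physiological model.

* **Waveform**: a five-lobe Gaussian PQRST template (P, Q, R, S, T
  amplitudes 0.15/−0.15/1.0/−0.25/0.35 mV, widths 25/12/11/13/45 ms)
  repeated at RR intervals with 2% beat-to-beat jitter; additive white
  noise (20 µV RMS) and stochastic baseline wander (band-limited
  0.05–0.5 Hz Gaussian drift, 0.1 mV RMS — a random process, as real
  respiratory/movement drift is, so the sub-hertz band carries genuine
  class-independent variability).
* **Apnea minutes** (defaults): cyclic heart-rate oscillation of 10 bpm
  depth and 40 s period (classic cyclic bradycardia–tachycardia),
  R-amplitude modulation of depth 0.3 at the same period (EDR-like), and
  QRS broadening by a factor 1 + 2·drop with amplitudes attenuated so the
  R lobe's 5–10 Hz energy equals (1 − drop) times normal, using the
  closed-form Gaussian spectrum (erf); drop defaults to 0.5. This
  reproduces the observed direction of the contrast — normal breathing
  distinctly stronger in the 5–10 Hz band (measured A/N mid-band power
  ratio ≈ 0.6 at defaults) — with zeroed effects yielding statistically
  indistinguishable classes.
* **Subjects**: baseline heart rate (70 bpm nominal) and per-lobe
  amplitudes/widths perturbed per subject by a relative SD of 0.1
  (clipped to ±30%), so LOSOCV faces a real domain shift.
* **Labels**: per-minute Bernoulli apnea labels (fraction 0.5 by
  default, giving balanced classes); AHI is computed from the planted
  sequence as disordered minutes per hour. Stage labels alternate 70 min
  NREM / 20 min REM blocks with a random per-subject phase — a
  convenience for stage-stratified evaluation, with no claim of sleep
  architecture realism.
* **Artifacts**: per-minute probability 0.02 by default; flatline (3 s
  pinned at a constant) or saturation bursts (2 s railed at ±6 mV),
  positions recorded in the manifest.

What the simulator does **not** emulate: real HRV spectra, respiratory
sinus arrhythmia physiology, cardiopulmonary coupling, arrhythmias,
electrode drift over hours, or annotation noise. Passing tests therefore
demonstrate that the implementation detects the kind of time–frequency
contrast the method targets — not that it attains any particular
accuracy on clinical recordings.

## Study sizes and observed behavior

The synthetic study (tests and `scripts/acceptance.py`) uses a default
corpus of 2 subjects × 200 minutes for separability, the same
conditions with a morphology-only contrast for the band comparison, and
4 subjects × 100 minutes for the k-fold/LOSOCV comparison, with a
K = 200 vocabulary — sizes chosen so a full run completes in minutes on
one CPU while each corpus still yields ~400 windows.

At the default effect strengths the planted contrast is strong: 5-fold
CV accuracy on the 8–50 Hz band reaches 100% and LOSOCV sits at the same
ceiling, so the window-level-vs-LOSOCV comparison shows the inequality
(LOSOCV never exceeds window-level k-fold) rather than a dramatic gap;
the permuted-label control collapses to chance, confirming the
separation is signal, not capacity. The low band stays far behind the
high band (and well below it even with the contrast planted purely in
QRS morphology), reproducing the band ordering that motivates using the
8–50 Hz range.

## Known limitations

* The WFDB reader covers the single-signal format-16 subset plus
  MIT-format annotations — sufficient for the Apnea-ECG layout, not a
  general WFDB implementation (no multi-lead, format 212, or EDF).
* SURF here means "SURF-style": determinant-of-Hessian detection and
  the 64-d Haar-response descriptor layout, without orientation
  assignment (scalogram images have a canonical orientation) or the
  original's box-filter scale pyramid.
* Codebook sharing across k-fold folds (above) slightly optimistic for
  subject-level claims; use LOSOCV with `codebook_per_fold` for those.
* 10 s windows inherit their parent minute's label, so a sub-window may
  be labeled A while the event occupies a different part of the minute;
  this mirrors the annotation granularity, not event boundaries.
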