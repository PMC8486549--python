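# Methods

## Signal model of the simulator

Each subject's continuous 16-channel recording is

    x_c(t) = n_c(t) + Σ_trials Σ_comp a_{c,comp,trial} · s_comp(t − t_trial) + coherent sources

with:

* **Background noise** `n_c(t)`: independent per channel, 1/f^β spectrum
  (β = 1 by default, exponent 0 gives white noise), scaled to a target
  RMS (default 10 µV). Generated by spectral shaping of complex Gaussian
  noise, so it is exactly reproducible from a seed.
* **Component shapes** `s_comp`: P300 is a Gaussian bump centred at
  300 ms (σ = 50 ms); LPP is a plateau over 550–700 ms with 50 ms
  raised-cosine edges. Both are numerically zero before stimulus onset.
  Shapes are calibrated by their mean over the component's measurement
  window, so the **window-mean amplitude feature recovers the configured
  µV value** (the P300 Gaussian peak is amplitude/0.527). Shape details
  are deliberately irrelevant to window-mean features; they only need to
  be smooth and band-limited.
* **Amplitudes** `a_{c,comp,trial}`: class-conditional means per channel
  and component come from an effect table (defaults carry a real
  food/nonfood contrast pattern with the P300 difference concentrated at
  Oz and T7). On top of the class mean, each subject draws one shared
  offset per channel × component (std = condition-averaged
  between-subject std × `subject_sd_scale`), optionally an independent
  per-condition offset (`condition_offset_sd_uv`; the across-subject
  difference-score sd is √2 × this), and each trial adds i.i.d. Gaussian
  jitter (`trial_jitter_uv`, default 5 µV). The shared/per-condition
  split exists because a single "mean/std" summary cannot distinguish
  between-subject from between-condition variance; both are exposed.
* **Coherent sources**: for designated pairs (defaults: Fp1–Fp2 theta in
  the P300 window, Fp2–Fz delta in the LPP window), the *same* unit-RMS
  band-passed noise realization (4th-order Butterworth of white noise,
  Tukey-tapered) is added to both channels inside each trial's window,
  scaled by the trial's condition gain (defaults 4 µV food / 2 µV
  nonfood). Identical realizations on both members give directly
  controllable coherence.

Schedule: 5 blocks × (73 food + 28 nonfood) randomly interleaved trials
per subject (505 trials, 365:140), 1024 Hz, stimulus-onset asynchrony
1000 ms (configurable down to the 800 ms stimulus duration; below 1000 ms
the next trial's pre-stimulus baseline overlaps the previous epoch).
21 subjects by default. Units are µV throughout; there is no
reference-electrode or head-model forward simulation, no ocular/EMG
artifact model beyond what the peak-to-peak rejector needs for testing.

`null_epochs` is a fast calibration path that emits i.i.d. noise epochs
directly (white Gaussian by default): food and nonfood are exchangeable
by construction, which is what type-I-error and classifier-baseline
calibration need; p-value uniformity under the null does not depend on
the noise spectrum. `subject_condition_means` draws from the exact
subject-level marginal of the amplitude model and is used for
statistical power checks where simulating continuous EEG would add
nothing but runtime.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass, corners
0.1 and 40 Hz; the double pass squares the magnitude response. Epochs
are the half-open sample window [onset − round(0.2·fs), onset +
round(0.8·fs)) — exactly 205 + 819 = 1024 samples at 1024 Hz. Baseline
correction subtracts the per-trial, per-channel mean over [−200, 0) ms.
Artifact rejection drops whole trials whose peak-to-peak amplitude on
any channel exceeds a threshold (default 100 µV — a conventional value;
the criterion is configurable and a custom predicate can be plugged in).
Trials, not channels, are rejected, and kept + dropped is asserted to
equal the input count on every run.

## Features

**Amplitude**: mean voltage over the component window per channel.
The P300 window default is [250, 450) ms — a 200 ms window centred on
the nominal peak; LPP is [550, 700) ms. Both are configurable.

**Morlet CWT**: complex Morlet with centre frequency ω₀ = 6
(PyWavelets `cmor` with B = 2, C = ω₀/2π). Analysis frequencies are
integer-spaced within each band; delta uses {1, 2, 3, 4} Hz because a
1 s epoch cannot support 0.5 Hz. Epochs are reflection-padded by at
least one epoch length *and* at least four times the largest scale
(the slowest wavelet's effective support), else low-frequency
coefficients are quenched by the implicit zero extension. Coefficients
are rescaled by 2/scale so that a unit-amplitude sinusoid at an
analysis frequency yields its spectral band power A²/2 (µV²), directly
comparable to a Welch estimate (exact in continuous math:
|W|² = scale/4 for a unit cosine under this wavelet's normalization).
The cone of influence is not masked; features are taken from window
interiors.

**Band power**: mean of the rescaled |W|² over band frequencies ×
window samples. Agreement with a Welch periodogram oracle is checked by
Spearman correlation on long stationary tones at the analysis
frequencies (8 s segments, interior window): ≥ 0.95 in every band.
On 1 s epochs the delta estimates remain valid features but are
attenuated, window-limited quantities — 1 Hz barely completes one cycle
in an epoch — which is why the oracle comparison uses long segments.

**Coherence**: magnitude-squared wavelet coherence per unordered pair,
time-averaged over the component window only (no scale smoothing),
then frequency-averaged over the band. This smoothing choice is
load-bearing: without any averaging, single-trial coherence is
identically 1. The null level is set by the window's effective degrees
of freedom and is far above zero for short windows — with the ω₀ = 6
wavelet, independent channels give mean coherence ≈ 0.56 in alpha and
≈ 0.61 in theta over a 200 ms window (tabulated by Monte-Carlo in the
test suite). Planted common sources must therefore be, and are, judged
against this null, not against zero. Degenerate all-zero channels yield
coherence 0 with a logged warning; values are clipped to [0, 1] against
floating-point overshoot.

Gamma (30–40 Hz, capped at the low-pass corner) is computed on request
but excluded from default reports, which group the four classical bands.

Pair count: 16 channels → 120 unordered pairs; the pair enumeration is
lexicographic in montage order and each pair is computed once (symmetry
is structural, not numerical).

## Statistics

Per feature, trials are averaged within subject × condition; food and
nonfood subject means are compared with a two-sided paired t-test,
t = mean(d)/(sd(d)/√n), sd with n−1 denominator, df = n−1. Zero-variance
differences are flagged degenerate, never reported as p = 0 or t = ±∞.
No multiple-testing correction is applied by default — the battery
reports raw per-feature tests; Bonferroni and Benjamini–Hochberg are
opt-in flags (via statsmodels). The battery covers every (channel,
component) amplitude, (channel, component, band) power and (pair,
component, band) coherence: 16 + 16·B + 120·B tests per component for
B bands.

## Classification

Each row is z-scored across its own features (n-denominator sd) before
classification; this removes within-subject and single-trial amplitude
scale differences and, being sample-local, can be applied before
splitting without train/test leakage. A consequence worth knowing:
class differences that are a *common* shift across all features are
removed by row normalization — only differential (pattern) effects
survive.

Cross-validation is stratified k-fold (default 10) with shuffling under
a fixed seed; fold assignment is a function of (labels, k, seed) only.
Pooled mode mixes subjects within folds; per-subject mode runs the same
CV inside each subject and reports the across-subject mean and
population std of per-subject mean accuracies (subjects with fewer than
k trials in a class are skipped with a warning and listed). Plain
accuracy is the headline metric; because the class prior is ~72 % food,
balanced accuracy and a single-class-predictor flag are carried in
every report — a degenerate majority predictor scores the baseline
while carrying no information, and the flag makes that visible.

Classifier defaults (all configurable): kNN k = 5 Euclidean; logistic
regression L2, C = 1; decision tree Gini, unlimited depth (depth is
exposed because shallow trees behave very differently); LDA default
(svd) solver, no shrinkage; Gaussian naive Bayes; SVM RBF, C = 1,
γ = 1/(n_features·var); MLP one hidden layer of 100 ReLU units, Adam,
≤ 200 iterations, seeded.

On label-free data, classifiers split into two regimes: margin- or
prior-driven rules (LR, LDA, SVM, NB) collapse to the majority class and
score the baseline, while interpolating/memorizing rules (kNN with
k = 5, unlimited-depth DT, MLP) *underperform* the baseline — e.g. an
unlimited-depth tree on noise predicts with the class proportions,
giving ≈ p² + (1−p)² ≈ 0.60 against a 0.72 baseline. This is expected
behavior, asserted in the calibration tests: no classifier shows
spurious skill above the baseline's binomial interval, and the four
collapse-prone ones sit inside it.

## Problem sizes used in checks

Calibration and validation runs are sized for a desk machine: null
type-I-error uses 200 replicates of 21 subjects × 5 trials/condition at
the epoch level; classifier null calibration uses 2000 trials at 72:28;
power against the planted Oz P300 effect (5.218 vs 4.275 µV,
difference-score sd 1 µV, 21 subjects) uses 200 subject-level
replicates against the noncentral-t oracle; coherence planting uses 120
trials; the end-to-end benchmark in `scripts/acceptance.py` simulates 4
subjects × 101 trials. The full default configuration (21 subjects ×
505 trials) runs through the same code paths via `erpfood run`.

## Known limitations

* The generator plants additive, time-locked components on stationary
  1/f noise; it does not emulate latency jitter, ocular/muscle
  artifacts, volume conduction, re-referencing, or non-stationary
  background — passing tests demonstrate the pipeline's correctness
  against its own generative model, not performance on real EEG.
* Single-trial delta-band quantities from 1 s epochs are intrinsically
  window-limited (see above).
* Default classification accuracy sits near the majority baseline
  because the default planted class differences (≲ 1 µV) are small
  against 5 µV trial jitter; the monotonicity tests document how
  accuracy grows with the planted effect.
* The t-test battery treats subjects as the inference unit; no
  mixed-effects or cluster-based permutation machinery is provided.
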