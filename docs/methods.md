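# Methods

`semtrf` implements an encoding-model analysis of semantic processing during
naturalistic listening: temporal response functions (TRFs) relating
continuous-speech features to EEG, the added predictive value of word
surprisal, spatiotemporal cluster statistics, and TRF component measures
(N1, P2, and an N400-like semantic component), exercised end-to-end on
synthetic EEG with known ground truth.

## Model

The TRF is a linear kernel mapping stimulus features to each EEG channel
over lags τ:

    y_c(t) = Σ_f Σ_τ w(f, τ, c) · x_f(t − τ) + b_c + ε_c(t)

with lags −100…1000 ms. Estimation solves the Tikhonov-penalized normal
equations `(DᵀD + λM) w = Dᵀy` on a time-lagged design matrix `D`. The
penalty `M` is the identity (classical ridge, default) or a per-feature
second-difference matrix that penalizes kernel curvature; the intercept is
never penalized (implemented exactly by centering the training sufficient
statistics). λ is chosen by leave-one-trial-out cross-validation over
`2⁻⁵ … 2¹⁵` (21 log-spaced values), scoring each held-out trial by the
channel-averaged Pearson correlation between predicted and observed EEG;
ties resolve to the smallest λ. Per-condition TRFs are fit per epoch at the
chosen λ, averaged across epochs, and baseline-corrected by subtracting the
mean over −100…−4 ms.

### Edge handling in epoched fits

Epochs cut from a continuous recording carry responses to stimuli from
before the cut. Fitting on zero-padded lagged designs therefore biases the
kernels (we measured envelope-kernel correlations dropping from 1.0 to
~0.75 on noiseless data with 30-s epochs). The estimator consequently uses
only *interior* rows — samples whose full lag window lies inside the epoch —
for the normal equations (`trf.valid_rows`); edge rows are still predicted
when scoring. With this choice the noiseless forward model inverts to
machine precision even on epoched data.

## Stimulus features

* **Envelope** — magnitude of the analytic (Hilbert) signal, low-passed with
  an 8th-order Butterworth at 0.4 × the target rate before polyphase
  resampling, clipped at zero.
* **Word onset** — a binary step set at each word onset and held across the
  word's extent; contiguous words merge into one step, so the channel
  integrates to total spoken time and falls to zero in pauses.
* **Word surprisal** — the same step encoding with amplitude equal to the
  word's surprisal in bits, `S(w) = −log₂ p(w | 4 preceding words)` from a
  backoff 5-gram model.

Word onsets map to samples by half-up rounding. Audio recorded on an
auxiliary EEG channel is aligned to the clean soundtrack by maximizing
cross-covariance (ties → smallest lag).

### Language model

Interpolated add-k smoothing is the default:
`p_n(w|ctx) = (c(ctx,w) + k·p_{n−1}(w|ctx[1:])) / (c(ctx) + k)`, grounded in
an add-k unigram over vocabulary ∪ UNK (k = 0.01). Every conditional
distribution sums to one to ≈1e−15 and backs off *exactly* to the
lower-order model on unseen contexts. Unknown words map to a single UNK
symbol with smoothed mass, so surprisal is finite for any substituted word
(out-of-vocabulary replacements score ≈25–55 bits on the packaged corpus,
comfortably above the 20-bit substitution floor). Interpolated Kneser–Ney
(absolute discount 0.75, add-k unigram base so the distribution closes over
UNK) and raw maximum likelihood (diagnostic; may return infinite surprisal)
are also provided. Sentence punctuation becomes a boundary token that
participates in contexts but carries no timing.

## Preprocessing

Stage order: broadband 0.1–40 Hz band-pass (2nd-order Butterworth,
zero-phase) → audio alignment → resample to 250 Hz → 1–20 Hz band-pass →
joint z-scoring of EEG channels and regressors over the whole recording →
segmentation into 60-s trials (trailing remainder discarded, logged).
Regressors are filtered with the same filter as the EEG; convolution
commutes with filtering, so the kernel relationship is preserved.
Z-scoring uses statistics pooled over a participant's merged conditions:
per-condition scaling would rescale the two conditions' kernels by
different factors and distort condition difference waves. Artifact
decomposition (ICA/SOBI) and bad-channel interpolation are out of scope;
bad channels are supplied as a list and excluded from ROIs and adjacency.

## Statistics

* **Added value of surprisal** — Δr = CV accuracy(envelope+onset+surprisal)
  − CV accuracy(envelope+onset), each model at its own best λ, conditions
  averaged; cohort-level one-sided Wilcoxon signed-rank on Δr (H1: median
  > 0) with mean/SD of Δr as a d-like effect size (the convention for a
  rank test is not unique; this one is reported and labelled).
* **Cluster permutation test** — per-point paired t (or Welch for
  independent groups); points with |t| above the two-sided α = .05 quantile
  cluster via temporal contiguity + spatial adjacency (electrodes within
  4 cm center-to-center; "diameter" wording is ambiguous, the radius is a
  parameter); cluster mass = Σt, positive and negative clusters formed
  separately; null distribution of max |mass| from sign-flips or label
  shuffles; corrected p = (1 + #{null ≥ obs}) / (n_perm + 1). Observed
  cluster masses are verified against mne's spatio-temporal clustering in
  the test suite.
* **Peaks** — sensory TRF-N1 = minimum in 50–150 ms and TRF-P2 = maximum in
  150–250 ms of the frontal-central envelope kernel; the semantic TRF-N400
  latency is the minimum of the parietal surprisal-kernel difference wave
  (high-surprisal condition − control) in 200–1000 ms, amplitude the mean
  within ±10 ms of the peak. Ties break to the earliest extremum.
* **Group statistics** — Welch t with Satterthwaite df, Cohen's d
  (pooled SD) with noncentral-t confidence intervals; a split-plot ANOVA
  (1 between × up to 2 within factors) by partitioned sums of squares,
  cross-checked against pingouin's mixed ANOVA on the 2-way reduction;
  Spearman correlations with Benjamini–Hochberg FDR; chi-square with
  optional Yates correction; minimum detectable effect size by
  noncentral-t root finding.

## Synthetic data

The generator emulates the study conditions: ~15-min stories at 170
words/min sampled from the packaged 5-gram language model with jittered
word slots and sentence-final pauses; a "violation" story variant replaces
the first word at/after each 45-s interval midpoint with an
out-of-vocabulary word (surprisal > 20 bits, spacing ≥ 45 s); EEG at 250 Hz
is the sum of each raw (physical-unit) regressor convolved with a
ground-truth kernel, projected onto Gaussian scalp topographies
(frontal-central for envelope/onset, centro-parietal for surprisal), plus
1/f (exponent 1.0) and white noise mixed 70/30 and scaled to the configured
SNR (RMS signal / RMS noise; default 0 dB).

Kernels are sums of Gaussians in lag space. Defaults: normal-hearing-like
subjects have an early small N1 (95 ms) and large P2 (185 ms) envelope
kernel and a semantic (surprisal) kernel at 427.2 ms; cochlear-implant-like
subjects have delayed sensory components with reversed N1/P2 prominence and
a semantic kernel at 554.3 ms (a 127.1-ms group delay). Per-subject jitter:
latency SD 10 ms, log-normal semantic gain SD 0.15.

The condition effect is realized as a condition-dependent semantic gain
(`e45_surprisal_gain`, default 2×): the violation-rich variant drives the
semantic kernel twice as strongly per bit. This directly generates the
phenomenon the pipeline measures — a larger fitted surprisal TRF in the
violation condition and a clean difference-wave component. A mechanistic
alternative (an extra response to surprisal above a threshold) was
implemented and rejected: its pickup through the linear surprisal regressor
is smeared by whitening and produces a difference wave too weak and
misshapen to support per-subject latency extraction.

Behavioral scores are generated with a logistic link from the subject's
(standardized log) semantic gain to sentence-judgment accuracy plus
binomial trial noise, so a negative amplitude–accuracy association is
recoverable by construction; recall uses a weaker version of the same link.

What the simulator does *not* emulate: realistic head-volume conduction
(topographies are Gaussian blobs), implant stimulation artifacts, eye and
muscle artifacts, non-stationary noise, attention lapses, and any
nonlinearity of real semantic processing beyond the condition gain. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated forward model, not robustness to real-data
artifacts.

## Validation problem sizes

Checks run single-core at desk scale; the scaled studies keep the design's
event statistics rather than its raw duration (15-s substitution spacing,
preserving ≈13–16 violation events per run against the study's 20):

* solver oracle: λ=0 vs. explicit normal equations, ≤50-sample instances;
* kernel recovery: one subject, 10 × 30-s trials, 8 channels, 250 Hz,
  0 dB SNR — envelope-kernel correlation ≥ 0.95 and semantic latency within
  one sample, measured on the unfiltered forward model;
* added value: 20 subjects, 4 × 40-s trials at 64 Hz, 2 channels, −10 dB,
  5-point λ grid; the matching null (semantic kernel zeroed, fixed stimulus,
  200 noise repeats) estimates the test's false-positive rate;
* cluster calibration: 500 null and 100 planted-effect datasets of
  16 subjects × 12 channels × 250 samples with 200 permutations each;
* latency-shift recovery: 20 subjects/group, 5 × 40-s trials per condition
  at 250 Hz, 0 dB, fixed λ = 2¹².

## Known limitations

* **Nested-model Δr is conservative under the null.** With a common λ per
  model, ridge cannot shrink the surprisal feature selectively, so the full
  model's extra columns always cost held-out accuracy when surprisal
  carries no signal: per-subject Δr is biased negative by several times its
  between-subject SD (measured t-shift ≈ −10 across sizes, grids, and
  SNRs). The one-sided Wilcoxon therefore under-rejects — its false-positive
  rate is far *below* nominal. The test remains valid (conservative), and
  true effects are still detected with large margins, but its null
  rejection rate cannot be expected to sit near α. Banded ridge (a separate
  λ per feature band) would remove the asymmetry and is out of scope.
* Exact surprisal values depend on the packaged corpus and smoothing; no
  attempt is made to reproduce surprisal statistics of any specific
  large-corpus language model.
* The anti-alias filter, resampling scheme, and envelope values are
  implementation-defined within the documented tolerances.
* MLE smoothing can return infinite surprisal and is intended for
  hand-checkable diagnostics only.
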