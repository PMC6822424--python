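# Methods

This note records the models, conventions and numerical choices behind
`sqsleep`, in the order the pipeline applies them.

## Signal model and preprocessing

A recording is a set of equal-length channels in µV at a common
sampling rate, with a per-sample boolean validity mask. Masking is the
package's only artifact mechanism: samples are never deleted, so the
30-s epoch grid (anchored at the start of the recording, epoch *k*
covering [30·k, 30·k+30) s) is preserved, and every downstream
statistic simply skips invalid samples.

- **Filtering.** 4th-order Butterworth band-pass 0.5–100 Hz plus a
  Q = 30 IIR notch at 50 Hz, each applied forward–backward
  (`sosfiltfilt`/`filtfilt`), so the output has zero group delay and
  epoch timing is untouched. The realization is a design choice;
  zero-phase filtering is standard EEG practice and protects epoch
  alignment.
- **Resampling.** Polyphase rational resampling
  (`scipy.signal.resample_poly`), with the ratio approximated to a
  denominator of at most 1000 (e.g. 207/1024 exactly). Only
  downsampling is supported; the polyphase filter provides
  anti-aliasing. The validity mask is carried across by
  nearest-sample mapping.
- **Artifact rejection.** Samples with |x| > 300 µV are masked,
  extended by a configurable 0.5 s guard on each side (the guard width
  is a conservative choice; the underlying criterion leaves the
  excision extent open). Rejection is applied after filtering, which
  matters for the masked fraction and is therefore stated here as the
  package's convention. The operation is idempotent because it never
  modifies sample values.
- **Synchronization.** Two co-recorded devices are aligned on a 30-s
  epoch-by-epoch basis: the integer lag within ±2 s maximizing the
  normalized cross-correlation, computed with masked samples zeroed
  (so large artifacts cannot dominate) and normalized by the unmasked
  energy. Ties resolve to the smallest |lag|. Fully masked epochs get
  a missing lag and a warning. The ±2 s default bound reflects slow
  clock drift between co-recorded devices.

## Time–frequency features

The feature transform is a continuous wavelet transform with the
analytic generalized Morse wavelet with symmetry parameter γ = 3 and
time–bandwidth product P² = 60 (hence β = P²/γ = 20). It is
implemented as a frequency-domain filter bank: for each centre
frequency the scaled wavelet

  ψ̂(ω) = 2·(ω/ω_p)^β · exp(β/γ · (1 − (ω/ω_p)^γ)),  ω > 0

(ω_p = (β/γ)^{1/γ} the peak frequency) multiplies the signal's FFT,
normalized so a unit sinusoid at the centre frequency yields unit
magnitude. The grid is logarithmic with 12 voices per octave spanning
0.5–100 Hz (93 frequencies at 207 Hz). Nights are transformed in
chunks of 20 epochs padded with 5 s of real neighbouring signal
(reflection only at the recording edges) and cropped, suppressing
cone-of-influence artifacts; interior epochs therefore see their true
context. Masked samples are zeroed *before* the transform, which makes
every feature exactly independent of masked sample values.

Per band, the **band power series** is the mean of |W|² over the
band's frequency rows at each time sample; the broadband reference
uses all rows in [0.5, 100] Hz. The "power distribution" of an epoch
is read as the distribution over time of these within-band power
samples — this makes the moment features commensurate with the
activation duration, which is explicitly a time duration.

The 30 per-channel features of an epoch (metric-major order: mean,
variance, skewness, kurtosis, entropy, activation × five bands) use
only unmasked samples:

- moments are population (biased) definitions; kurtosis is the
  non-excess (Pearson) form; zero-variance epochs return
  skewness = kurtosis = 0 by convention;
- Shannon entropy (natural log) is computed on the power samples
  normalized to sum to one — no histogram binning, so the value is
  deterministic; an all-zero epoch is treated as the uniform limit,
  entropy log(n). Entropy is therefore bounded by [0, log n];
- activation duration = 30 s × fraction of unmasked samples where the
  band series exceeds 1.5× the *same epoch's* median broadband power.
  The per-epoch scope of the median makes the feature
  amplitude-invariant and robust to slow impedance drift in
  weeks-long recordings; a per-recording scope would couple epochs.

Scaling the signal by c > 0 scales mean power by c² and variance by
c⁴ and leaves skewness, kurtosis, entropy and activation unchanged.
Epochs with fewer than 10% unmasked samples are invalid; their feature
rows are NaN.

**Context stacking** concatenates row k with rows k−1, k+1 and k+2
(column count ×4). Edge epochs replicate the nearest existing row, so
every scored epoch remains classifiable; an invalid neighbour is
replaced by the nearest valid epoch's features so one artifact epoch
does not poison its neighbours. Row validity remains that of the epoch
itself.

## Classifier

A bagging ensemble of 100 CART trees: each tree is grown on a
bootstrap resample, splits on Gini impurity over a random subset of
⌈√d⌉ features (the canonical forest default; the number is a design
choice), and stops splitting pure nodes or nodes with fewer than ten
observations. This is exactly scikit-learn's `RandomForestClassifier`
configuration, which the module wraps. No class rebalancing is applied
by default — rare stages (N1) are expected to show poor sensitivity,
which is the behaviour of an unweighted forest; a weighting option
exists but is off.

Prediction is a per-tree plurality vote. Ties resolve to the earlier
stage in the fixed order W, N1, N2, N3, R. Invalid epochs inherit the
nearest preceding valid prediction (leading invalids take the first
valid one), with a log entry. Both channels' features are concatenated
(60 base columns), not averaged.

Cross-validation never splits a night across folds: **PS** trains one
model per patient on that patient's other nights; **LONO** pools all
other nights regardless of patient. A runtime assertion verifies that
no test night appears in its own training set. Training nights are
stacked in sorted order so fold identity, not listing order,
determines the fitted model. One global seed drives bootstrap and
feature subsampling and is recorded in the run manifest.

## Sleep measures

All durations are epoch counts × 0.5 min. TATS defaults to the
hypnogram's duration (device mount-to-dismount convention) and can be
overridden by explicit metadata, which takes precedence. TST is time
in any sleep stage; SL runs to the first sleep epoch, RL to the first
REM epoch; SE = TST/TATS × 100; WASO = TATS − SL − TST, so
TST + SL + WASO = TATS holds exactly whenever SL is defined. On an
all-wake night SL, RL and WASO are missing and SE = 0. REM latency is
computed across the whole night even when a night contains two
separated sleep periods — no sleep-period segmentation is attempted.
Two-class traces map W → wake and everything else → sleep without
retraining; TST, SL, SE and WASO are invariant under the merge.

## Agreement statistics

- **Cohen's κ** = (p_o − p_e)/(1 − p_e), with p_e from the marginal
  products; implemented from the confusion counts so κ from a matrix
  and κ from raw sequences agree identically. The degenerate case
  p_e = 1 (both raters constant and identical) is defined as κ = 1
  with a warning.
- **Confusion matrices** pool counts over nights (an epoch-weighted
  population average); row percentages are class sensitivities. For
  wake/sleep matrices the wake row comes first and sleep is the
  positive class, so the diagonal reads (specificity, sensitivity).
- **Deming regression** with error-variance ratio λ = 1 (orthogonal
  regression; no information supports another ratio), closed form,
  with Pearson r alongside.
- **Bland–Altman**: differences are truth − estimate, so a positive
  bias means underestimation. Limits of agreement are
  mean ± 1.96·SD of the differences (the standard definition); an
  `loa_scale="sem"` variant exists because the two conventions are
  sometimes conflated in the literature and silent mixing would
  corrupt comparisons.
- **Exact permutation test**: within-pair sign flipping with the mean
  as statistic, all 2ⁿ assignments enumerated for n ≤ 20, so p-values
  are exact multiples of 2⁻ⁿ (at n = 11 the smallest attainable
  two-sided p is 2/2048). Larger n falls back to seeded Monte-Carlo
  with an add-one correction. The sign-flip scheme is the natural
  exact test for paired differences; full label permutation is out of
  scope. Nights with missing measures are dropped pairwise with a
  logged count.

## Synthetic data

The generator produces the *statistical* structure the pipeline
assumes, not physiological EEG:

- hypnograms are first-order Markov chains over the five stages
  starting in W, with a self-transition-dominated default matrix
  (0.85 diagonal) emulating sleep-bout persistence — no ultradian
  cycle structure;
- each epoch's two channels are Gaussian noise spectrally shaped by
  the stage's band weights over a 1/f background, sharing a common
  source (70% of variance) plus independent noise; per-epoch lognormal
  jitter on amplitude (σ = 0.15) and band weights (σ = 0.25) and a 30%
  spectral blend with the previous stage on the first epoch after a
  transition provide realistic within-stage variability and ambiguous
  transition epochs;
- N2 epochs receive spindle-like 11–15 Hz bursts (0.5–1 s, 3/min) and
  N3 epochs slow-wave bursts (0.5–1.5 Hz, 6/min) so the within-epoch
  power distribution features (skewness, kurtosis, activation) are
  exercised nontrivially;
- each patient draws one lognormal gain (σ = 0.2) shared across their
  nights; artifact bursts exceeding the 300 µV threshold are injected
  at 2/hour.

The default study mirrors the target design: 4 patients with
(3, 2, 3, 3) nights — 11 nights — at 207 Hz. The default night length
is 720 epochs (6 h), a realistic night for epilepsy-monitoring-unit
patients who sleep poorly and whose devices are sometimes removed
early; examples and some tests use shorter nights, and the
acceptance script uses the full default study. Because the default
stage spectra are strongly stage-specific, cross-validated recovery on
synthetic studies is near ceiling (κ ≳ 0.9); passing therefore shows
that the pipeline recovers the structure the generator encodes, not
that it would reach any particular accuracy on clinical recordings,
where stages overlap far more (N1 in particular) and artifacts are
richer. Degrading the spectral contrast toward identical stage
spectra drives κ to chance, which is tested explicitly.

## Numerical and I/O conventions

- EDF: 16-bit storage with a symmetric per-channel physical range in
  µV, so round-trip error is bounded by one LSB of that range; the
  physical bounds used for quantization are the ones actually written
  into the 8-character header fields. Whole-second signals use 1-s
  records, others a single record. Reading goes through `mne` after a
  structural header check that rejects truncated or malformed files
  by naming the offending field. Channel labels are truncated to
  EDF's 16 characters with a warning.
- Hypnograms: CSV `epoch_index,onset_sec,stage` with AASM tokens
  W/N1/N2/N3/R; optional `# tats_min:` and `# epoch_len_s:` comment
  metadata. Epoch indices must be contiguous from 0; unknown tokens
  and gaps are rejected by row.
- The CWT filter bank is cached per (grid, rate, FFT length); chunked
  night processing runs in float32 (the public single-epoch transform
  is float64). Feature values are insensitive to this at the
  precision any test asserts.

## Known limitations

- The synthetic generator is a testbed, not a simulator of sleep EEG;
  absolute performance numbers on it do not transfer to patients.
- No temporal smoothing (HMM or otherwise) of predictions, no class
  rebalancing, no hyperparameter search — the classifier is
  deliberately the plain bagged forest described above.
- Synchronization models per-epoch constant lags only; continuous
  clock-drift estimation is out of scope.
- EDF support covers the needs of this pipeline (16-bit, µV,
  equal-rate channels on write); it is not a general EDF+ library.
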