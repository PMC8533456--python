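# Methods

`eegsq` implements an EEG decoding pipeline for automobile sound quality:
listeners hear acceleration sounds judged *comfortable* (label −1),
*powerful* (0) or *accelerating* (+1), and the task is to recover the
sound class from 1-s EEG epochs.  Because no public recordings exist for
this paradigm, the package ships a first-class synthetic session
generator with the same statistical structure the analysis assumes; all
tests and the acceptance script run end-to-end on generated sessions.

## Listening paradigm and synthetic sessions

A session presents 3 sounds per class × 3 classes × 27 repetitions = 243
stimuli of 5 s each, in seeded random order, recorded at 1000 Hz over a
62-channel extended 10-20 montage (26 left/right homologous pairs + 10
midline electrodes, shipped as an editable YAML pair table).  Each 5-s
stimulus is later cut into five 1-s epochs, giving 27 × 9 × 5 = 1,215
epochs per session.

Within a stimulus, every channel receives a sum of five exactly
band-limited noise processes (δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–49 Hz)
whose power follows the class signature, plus a 1/f background (default
exponent 1.0, 2 µV RMS) and white sensor noise (default 1 µV RMS).  Band
components are white noise masked in the rFFT domain with the same
half-open `[low, high)` convention the band-power estimator bins with,
and are renormalized to the exact target variance **per epoch-length
chunk**.  Two deliberate choices here:

- *Spectral masking rather than IIR filtering for synthesis.*  An
  order-4 Butterworth band-pass leaves only ~83–90% of a component's
  variance inside its nominal band, so injected and measured band power
  could never agree to the 5% the generator promises.  Brickwall masking
  makes the injected power an exact function of the signature.
- *Per-epoch rather than per-stimulus normalization.*  Fixing the total
  power of a whole 5-s stimulus anticorrelates the band power of its
  five epochs (one high epoch forces its siblings low).  That is an
  artifactual cue no real recording has, and it biases epoch-level
  cross-validation; per-epoch normalization removes it.

A class signature specifies per-band gains, an overall power scale
(µV² per band), and signed per-band, per-region hemispheric offsets: a
left-hemisphere channel in region ρ gets power scaled by (1 + a/2) and
its right homologue by (1 − a/2).  The defaults plant three distinct
patterns: comfort is low-power (10 µV²/band) and hemispherically
balanced; powerfulness has elevated overall and δ/θ power with a strong
left-dominant frontal δ/θ asymmetry (+0.6 frontal, +0.3 temporal);
acceleration has the highest broadband power with elevated β/γ and a
right-dominant frontal β/γ asymmetry (−0.5 frontal, −0.25 central).
Asymmetry features are mathematically blind to hemispherically symmetric
power changes, so a fully symmetric class would be indistinguishable
from any other symmetric class; giving each class its own asymmetry
fingerprint is what makes the planted contrast recoverable by the
feature set the pipeline actually uses.  A second preset
(`gamma_contrast_signatures`) differs across classes only in γ-band
asymmetry and is used to probe band-specific decoding.

The inter-stimulus gap (background only) is an explicit configuration
knob, default 1 s: the original protocol's prompt/feedback pauses are
not part of the analysed data, and short gaps keep simulated sessions
compact.

What the generator does **not** model: auditory evoked potentials and
ERP components, eye/muscle artifacts, channel-specific noise floors,
inter-subject variability, and any acoustic content.  Passing tests
therefore show that the pipeline recovers planted band-power asymmetry
structure through the full preprocessing/feature/classification chain —
not that real EEG supports any particular accuracy.

## Preprocessing

Zero-phase (forward–backward) filtering: order-4 Butterworth band-pass
0.1–100 Hz, quality-factor-30 IIR notch at 50 Hz (≥30 dB at the mains
line), then polyphase anti-aliased resampling to 200 Hz.  Zero-phase
realization matters because phase distortion would bias Hjorth mobility.
`filtfilt` is padded with 10 s of reflected signal: the 0.1 Hz high-pass
pole rings for seconds, and scipy's default padding leaves visible
low-frequency edge transients.  Epochs are half-open windows
`[onset, onset + length)` with 0-based sample indices; each stimulus
contributes `floor(stimulus/epoch)` epochs inheriting its label.
Amplitude-based rejection (any-channel peak-to-peak above a threshold)
is available but off by default — synthetic sessions contain no
artifacts, and the rejection criterion used on real data is a
configuration choice, not something the analysis infers.

## Features

Per epoch, electrode and rhythm band:

- **Band power (PSD)** — Welch estimator with a rectangular 1-s window
  and 50% overlap, band power = Σ density bins in `[low, high)` × bin
  width.  For 1-s epochs this degenerates to a single periodogram; with
  1-Hz bins, energy within half a bin of a band edge is assigned to the
  neighbouring band, which is why the generator's self-consistency check
  uses the same estimator with a longer (10-s) window.
- **Hjorth parameters** of the band-filtered signal — activity
  (variance, µV²), mobility (≈ dominant angular frequency, rad/s),
  complexity (bandwidth measure, dimensionless).  Derivatives are first
  differences scaled by the sampling rate; zero-variance input returns
  (0, 0, 0).  Computing Hjorth per band (not broadband) gives the
  5 × 3 structure behind the 390-dimension count.
- **Differential entropy (DE)** — ½·ln(2πe·σ̂²) nats with σ̂² the
  unbiased time-domain variance of the band-filtered epoch (the Gaussian
  closed form; a log band-power surrogate).  Zero variance yields a
  −∞ sentinel.

Asymmetry features contrast homologous pairs: DASM = left − right,
RASM = left / right, with ε = 10⁻¹² added to the RASM numerator and
denominator so equal inputs keep RASM = 1 even at zero power.  With 26
pairs and 5 bands this yields 130 features for PSD or DE and 390 for
Hjorth.  γ is capped at 49 Hz because recordings are notch-filtered at
50 Hz and resampled to 200 Hz.  Column order is deterministic: mode,
then pair in montage order, then band, then base component.  The
per-class topography table (mean band power per electrode) is emitted as
tidy CSV; no scalp interpolation or rendering is attempted.

## Kalman feature smoothing

Each feature dimension is a scalar local-level state space: random-walk
state with process noise q, observed with noise r.  A forward Kalman
filter plus backward fixed-interval (RTS) recursion gives the smoothed
posterior mean; the backward pass starts from the last filtered
estimate, and the smoothed variance never exceeds the filtered one.
The forward/backward recursion is verified in the tests against a dense
joint-Gaussian solve of the tridiagonal precision matrix at 10⁻⁸.

Noise parameters come either from a fixed ratio (r = column variance,
q = 0.01·r, the default) or per-column expectation-maximization (closed
form M-step with smoothed lag-one covariances; ≤50 iterations, relative
log-likelihood tolerance 10⁻⁶; the initial-state prior m₀ = first
observation, p₀ = 10× sample variance is held fixed so the likelihood is
monotone).  A constant column is returned unchanged.

Smoothing runs independently within each contiguous stimulus block —
level shifts at stimulus boundaries are signal, not noise.  Inside
cross-validation the (q, r) statistics are fitted on training rows only;
the transform itself never consults labels, so class information cannot
leak through smoothing by construction.

## Feature selection

mRMR greedily ranks features by Φ = D − R: D is the mean mutual
information between selected features and the class label, R the mean
pairwise MI among selected features with the 1/|S|² normalization over
all ordered pairs, self-information included, exactly as the criterion
is printed in the mRMR literature.  The first pick maximizes relevance
alone; ties break to the lowest column index.  MI is the plug-in
estimate in nats on discretized features: columns are z-scored and cut
at ±0.5σ into three states (the convention of the mRMR source
literature), with equal-frequency binning for other bin counts — which
makes the ranking invariant to strictly monotone per-column transforms.
The PCA baseline is a mean-centered projection onto the top-k principal
axes (orthonormal loadings, non-increasing explained variance); asking
for more components than the matrix rank is an error.

## Classification

- **LDA**: Gaussian class conditionals with a shared pooled covariance,
  shrunk toward a scaled identity ((1−λ)S + λ·(tr S/p)·I, λ = 10⁻⁴) to
  guarantee invertibility; prediction maximizes posterior density under
  empirical priors; exact ties resolve to the lowest class label.
- **One-vs-one RBF-SVM**: features standardized with training
  statistics, one binary soft-margin machine per unordered class pair
  (three machines for three classes), prediction by majority vote over
  signed decision values; vote ties break by the largest summed decision
  value, residual ties by the lowest label.  This reconciles "largest
  judgment value" with "majority voting": votes decide, decision values
  arbitrate.
- **Evaluation**: stratified 5-fold cross-validation with a fixed seed.
  The (C, γ) grid — C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, exponent step 4 — is
  searched by 3-fold inner CV on the training folds only, as are
  smoothing and selection statistics.  The step-4 grid (30 combinations)
  covers the classical step-2 ranges at a quarter of the cost; fold
  accuracies are flat near the optimum, and a finer grid can be passed
  explicitly.  Group differences between accuracy sets are tested with
  one-factor fixed-effects ANOVA (degenerate all-equal input returns
  F = 0, p = 1).

## Problem sizes

The default configuration (62 channels, 243 stimuli, 1,215 epochs,
DASM_DE + grid-searched SVM) runs end to end in about three minutes on
one CPU.  The secondary study conditions are deliberately compact so the
whole battery stays fast: a 17-channel (8-pair) layout with 9
repetitions (405 epochs) for the smoothing and band-contrast sessions,
5 repetitions (225 epochs) for the chance-level session, 300 samples
with 4 informative / 20 redundant / 30 noise columns for the
selection comparison, T = 2,000 for EM noise recovery, and 1,000 null
replicates for the ANOVA calibration.

## Known limitations

- DASM/RASM see only hemispheric asymmetry; symmetric power structure,
  however strong, is invisible to the shipped feature set by design.
- RASM of DE divides two signed quantities; near-zero denominators are
  ε-guarded but RASM_DE remains heavy-tailed, mirroring its behaviour on
  real features.
- The Welch estimator's 1-Hz bins blur band edges for 1-s epochs; DE and
  Hjorth use IIR band filters whose transition bands overlap adjacent
  rhythms slightly.
- EM estimates of (q, r) on short blocks (5 epochs) are driven almost
  entirely by the pooled column statistics; the per-block smoother is
  best understood as shrinkage toward the block trajectory.
- European Data Format ingestion requires the optional `mne` package;
  EDF export is not provided.
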