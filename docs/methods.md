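# Methods

`bdeeg` implements a complete analysis chain for discriminating bipolar
depression (BD) from healthy controls (HC) with scalp EEG recorded under
three paradigms — eyes closed, eyes open, and free viewing — together with a
synthetic cohort generator that provides ground truth for every stage.

## Signal model and preprocessing

The analysis assumes multichannel EEG on the 19 electrodes of the 10–20
system (Fp1, Fp2, F3, F4, F7, F8, Fz, T7, T8, P7, P8, C3, C4, Cz, P3, P4,
Pz, O1, O2) sampled at 250 Hz, roughly 180 s per paradigm. Preprocessing is:

1. **Average re-reference** — subtract the instantaneous mean over channels.
2. **Broadband filter** — 1–49 Hz Butterworth bandpass (order 4, applied
   forward–backward so the effective order is 8 and the phase response is
   zero) plus a second-order IIR notch at 50 Hz with Q = 30. The filter
   family is standard; the order and notch Q are this package's choices
   (typical resting-EEG practice), since only the corner frequencies are
   dictated by the procedure being implemented.
3. **Epoching** — non-overlapping, contiguous 6-s epochs; the trailing
   remainder is discarded. Epochs are half-open intervals
   [k·6 s, (k+1)·6 s) with 0-based samples.
4. **Band decomposition** — zero-phase Butterworth bandpass per canonical
   band: δ (1–4), θ (4–8), α (8–12), β (12–30), γ (30–49 Hz). γ is bounded
   above at 49 Hz because the broadband filter removes everything beyond it.
   Band filtering of epochs uses 1 s of reflection padding per side to
   suppress edge transients, which matter most for δ in 6-s epochs.

Ocular-artifact removal (ICA) is deliberately out of scope: the synthetic
data contain no ocular artifacts, and real-data artifact rejection is an
interactive step upstream of this pipeline.

## Features

Twelve feature families are computed per channel (12 × 19 = 228 columns):

- **Band power** (five families): Welch PSD on broadband epochs (2-s Hamming
  segments, 50% overlap, one-sided density), integrated over [low, high) Hz
  and averaged over epochs. A unit-amplitude in-band tone yields ≈ 0.5 µV².
- **Differential entropy** (five families): DE = ½ ln(2πeσ̂²) in nats, with
  σ̂² the per-epoch sample variance of the band-filtered signal, averaged
  over epochs. For Gaussian band processes this is the exact differential
  entropy (1.4189 nats at σ = 1); in general it is a log-variance feature.
- **dPAC** (δ→β debiased phase–amplitude coupling): with δ phase φ_t and β
  envelope a_t pooled across epochs,
  dPAC = |mean(a·e^{iφ}) − mean(a)·mean(e^{iφ})| — the amplitude-weighted
  mean phase vector minus the phase-clustering bias. For a_t = 1 + κ·cos φ_t
  with uniform phase the closed form is κ/2. The exact published definition
  of this estimator is cited rather than printed in the source procedure;
  the debiased construction implemented here follows the cited estimator
  family, without amplitude normalization by default (a normalized variant
  is exposed via a flag).
- **AAC** (δ–β amplitude–amplitude coupling): Pearson correlation of the two
  Hilbert envelopes pooled across epochs (pooling stabilizes the estimate
  for 6-s epochs relative to per-epoch correlation).

Phase and envelope come from the per-epoch Hilbert analytic signal of
band-filtered epochs. Whether the original analysis averaged per-epoch
features or pooled samples is unstated; pooling is the default here and
per-subject epoch averaging is retained for PSD/DE where it is the natural
estimator.

## Phase lag index

For each band and channel pair, PLI = |mean sgn(Δφ)| with Δφ the phase
difference wrapped to (−π, π] and sgn(0) = 0, so zero-lag
(volume-conduction-like) synchrony contributes nothing. The estimator
averages the sign over time within each 6-s epoch, then over epochs, and
takes the modulus last; a brute-force per-sample evaluation of the same
definition is kept as a test oracle at 1e-12. The sign is computed by range
comparisons on the raw difference (equivalent to the wrapped sign everywhere
except the measure-zero set Δφ ≡ π mod 2π). A stated acquisition window of
0.1–11 s is incompatible with 6-s epochs; the full epoch is used.

## Group statistics

- **Edgewise connectivity comparison**: two-sample Mann–Whitney rank-sum
  test per unique edge (171 per band), two-sided, exact for small untied
  samples and normal-approximated with mid-rank tie correction otherwise.
  The source text names a signed-rank test, which is undefined for
  independent groups of 28 and 42; the rank-sum form is the standard
  reading. Benjamini–Hochberg correction is applied within each band across
  its 171 edges (conclusions are reported per band). Direction is the sign
  of the BD−HC median difference.
- **Feature significance table**: independent-samples t-test per (family,
  electrode) cell, pooled-variance by default with a Welch option, reported
  uncorrected at p < 0.05 (matching the published table's convention); a
  BH-corrected mode exists. Electrodes are grouped into frontal
  {Fp1, Fp2, F3, F4, F7, F8, Fz}, parietal/central
  {C3, C4, Cz, P3, P4, P7, P8, Pz}, occipital {O1, O2}, temporal {T7, T8}.
- **Feature–cognition correlations**: Spearman ρ per (score, family,
  electrode) across subjects, flagged at p < 0.05; per-paradigm significant
  cell counts feed the paradigm ranking.
- **Demographics**: Welch t from summary statistics (mean, SD, n) — Welch is
  the default because it reproduces the published table's age/YMRS/HAMD-24
  t-values, which a pooled test does not — and Pearson χ² (df = 1, no
  continuity correction) for the 2×2 sex table. The published TMT-B, DST
  and SDMT t-values are not reproducible from their own printed means and
  SDs under either variance convention and are treated as typographical.

## Classification

Six classifiers: AdaBoost.M1 with 100 decision-stump weak learners, KNN
(k = 5), Gaussian naive Bayes, random forest (100 trees, √p features per
split), linear SVM (C = 0.25), and a CART decision tree (Gini, unlimited
depth). Features are z-scored inside each training fold only. The
validation scheme is repeated stratified 5-fold (10 repeats by default) with
subject-level splits: all rows of a subject share a fold, so epoch-level
features cannot leak. An epoch-level evaluation mode is available through
the same subject-grouped fold machinery but is not the default, since
subject-level evaluation is the conservative choice when the original
protocol is unstated. Accuracy and the F1 of the BD (minority, positive)
class are reported as percentages alongside the majority-class baseline.

## Synthetic cohorts

Each subject × paradigm recording is the sum of:

- five band-limited Gaussian processes — white noise shaped in the frequency
  domain by the zero-phase Butterworth band magnitude (spectrally identical
  to forward–backward filtering; phases drift realistically, unlike pure
  tones, whose Hilbert phases are degenerate);
- a 1/f noise floor (power exponent 1, flat below 1 Hz), default RMS 5 µV;
- for each coupling edge (a, b, band, lag, strength): a shared unit-RMS
  narrowband source injected into channel a, and into channel b as
  strength·(source rotated by the lag) + √(1−strength²)·(independent
  narrowband noise), all scaled by the band amplitude. The rotation is a
  constant phase shift of the analytic signal, i.e. an exact per-frequency
  lag, so strength 1 with zero noise drives the pair's PLI to ~1 (Hilbert
  phase estimation at envelope dips costs about 1%, and average
  re-referencing mixes a little of the lagged source into every channel);
- β-envelope modulation by the channel's own δ phase:
  β·(1 + κ·cos φ_δ)/√(1+κ²/2) (RMS-preserving), with group-specific κ.

Band RMS defaults are typical resting scalp values (δ 8, θ 6, α 10–12
eyes-closed / 6–7 otherwise, β 4, γ 2 µV). The default cohort is 28 BD + 42
HC with the group contrast carried as in the target study: eyes closed has
stronger BD coupling in δ/θ/β/γ (0.6 vs 0.2) plus an equal-strength α edge,
higher BD δ/θ amplitude, and κ 0.40 vs 0.15; eyes open has identical group
parameters; free viewing reverses the δ/θ contrast (HC 0.5 vs BD 0.2). No
generative mechanism for *why* paradigms differ is modeled — the overrides
simply encode the reported contrast pattern.

Cognitive scores are a linear model on each subject's realized δ/θ log band
power (z-scored across the cohort) plus Gaussian noise; intercepts and noise
SDs sit at the published score scales and the coefficient signs follow the
reported correlation directions (TMT-A ~ θ+, TMT-B ~ δ+/θ+, DST ~ δ−,
SDMT ~ δ−/θ−). Subject seeds derive from the master seed by counter
(`SeedSequence(seed, spawn_key=(subject, paradigm))`), so any subject can be
regenerated independently and identical (spec, seed) gives bit-identical
arrays.

What the generator does **not** emulate: ocular/muscle artifacts, volume
conduction and reference-field geometry, non-stationarity beyond envelope
modulation, and realistic cross-band spectra correlation. Passing tests
therefore demonstrate correct recovery of the statistical structure the
analysis assumes, not performance on clinical recordings; the published
classification accuracies are locked to unreleased patient data and are not
reproduction targets.

## Validation studies and problem sizes

- **Parameter recovery**: single-band recovery cohorts (28/42 subjects,
  30 epochs, five δ edges at strength 0.8 vs 0.2, lag π/4) over 20 seeds in
  the test suite (5 seeds in the acceptance script); the edgewise comparison
  must flag ≥ 90% of true edges at q = 0.05.
- **FDR control**: global-null simulations draw each subject's edgewise PLI
  from |N(0, 1/(n_epochs·n_samples))| — the CLT law of the sign mean under
  uniform phase differences — with 200 simulations in the test suite and 100
  in the script; the mean false-discovery proportion must stay within the BH
  guarantee plus twice the Monte-Carlo error.
- **Classifier sanity**: a separable cohort (8-SD shift on the δ-power
  block) must reach 100% accuracy for all six classifiers;
  label-permutation nulls must keep mean accuracy inside the attainable
  interval [minority rate, majority rate] (40–60% at 28/42) widened by the
  95% binomial band; and when only the eyes-closed feature matrix carries a
  1-SD group shift on the δ-power/DE block, eyes closed must rank first by
  best-classifier accuracy in ≥ 95% of 20 seeds (feature-level cohorts;
  signal-level group effects are exercised by the recovery study).
- Unit tests run on shortened cohorts (12–60 s, 2–10 subjects per group) to
  keep the suite fast; durations only change estimator variance, not the
  contracts under test.

## Numerical notes and edge cases

- Zero-variance epochs make DE undefined and raise; constant envelopes make
  AAC undefined and raise; constant feature cells are reported
  non-significant with a warning rather than NaN-propagating.
- BH adjustment uses the step-up construction with cumulative-minimum
  monotonicity; the rejection mask equals the classic step-up set (both are
  cross-checked in tests).
- EDF export writes 16-bit samples in 1-s records with per-channel symmetric
  physical ranges; quantization error is bounded by max|x|/32767.
- All randomness flows through `numpy.random.Generator` seeded from
  explicit integers or spawn keys; no global RNG state is touched.

## Known limitations

- PLI on fewer than ~20 epochs is noisy; the 3/√n_epochs null bound used in
  tests is loose by design.
- The free-viewing paradigm is modeled only through its parameter overrides;
  nothing distinguishes it mechanistically from eyes-open data.
- The dPAC/AAC estimator choices (no amplitude normalization; pooled
  samples) follow the cited estimator family but cannot be verified against
  the original code, which is unreleased.
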