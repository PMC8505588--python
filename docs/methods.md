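# Methods

This note documents the models, parameter choices and numerical decisions
behind `eegauth`, and what the synthetic experiments do and do not show.

## The identification problem

Closed-set identification: given a trial of multi-channel EEG, decide which
of the enrolled subjects produced it. Two acquisition protocols are
modelled, both deliberately short: 30 s of eyes-closed rest (EC) and a
~4 min word-presentation session (VS; 120 stimuli, 1 s word + 1 s black
screen). The montage is the 14-channel consumer-headset subset of the
10–20 system (AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4)
sampled at 256 Hz; amplitudes are microvolts throughout.

## Synthetic cohort generator

No public recordings exist for this acquisition setup, so the pipeline is
driven by a generator that reproduces the statistical structure the method
measures — between-channel correlation patterns that are stable within a
subject and different between subjects.

**Signal model.** Each subject is a linear spatial-mixing model: a fixed
`14 × 6` mixing matrix applied to six latent sources — two alpha-band
oscillators (Gaussian spectral band of width 1.5 Hz centred at the
subject's alpha peak and 0.5 Hz above it) and four 1/f^β background
processes (flat below a 3 Hz corner) — plus independent per-channel white
sensor noise and a constant per-channel electrode offset. VS recordings add
two stimulus-locked ERP components per onset (Gaussian bumps; `width_ms` is
the Gaussian σ): an early posterior component (~170 ms, σ 30 ms) and a late
centro-parietal one (~320 ms, σ 60 ms), each with per-stimulus amplitude
(±10%) and latency (±2 ms) jitter, the single-trial variability familiar
from evoked-potential averaging. Blinks are a Poisson process (0.2 Hz) of
300 ms raised-cosine transients, frontally weighted, 150 µV at the peak;
their onsets are recorded as ground truth for artifact-removal tests.

**Defaults** (all config-overridable): alpha 10 µV RMS, background 5 µV
RMS per source, sensor noise 2 µV RMS, electrode offsets ~10 µV. These
give channel signals tens of microvolts peak-to-peak with a visible alpha
bump over a 1/f floor, representative of a dry-electrode consumer headset.

**Separation dial.** `separation` interpolates every between-subject
deviation. The mixing matrix is `normalize((1−s)·base + s·delta)` with a
shared `base` and per-subject `delta`, so `s = 0` gives all subjects
identical generative parameters (only noise seeds differ) and `s = 1`
gives fully independent spatial fingerprints. Alpha peak frequency spreads
over 8–12 Hz at `s = 1`; alpha amplitude (±30%), 1/f slope (±0.2) and ERP
latency/amplitude/topography spread proportionally. The two calibration
points are enforced by tests: at `s = 1` the full pipeline identifies the
default 8-subject cohort at ≥95% accuracy on both tasks under both
decompositions; at `s = 0` its top-1 accuracy lies in the binomial 99%
interval around 1/8.

**Exact-spectrum synthesis (why, not just how).** The latent sources are
synthesised from their *target magnitude spectra with random phases only*,
then ZCA-whitened per recording so the realised source covariance is
exactly the identity. This pins every recording's second-order statistics
(band powers, source cross-covariances) to the ensemble values rather than
letting them fluctuate by O(1/√T). The point is the null calibration: all
trials of one subject come from one continuous recording, so any realised
deviation of that recording's statistics from the ensemble is a
*recording-identity fingerprint* that a cross-validation splitting trials
of the same recording can learn — and at `separation = 0` that fingerprint
is the only signal there is. For the same reason the alpha rhythm is a
phase-drifting narrowband process (a deterministic carrier would stay
phase-locked to the trial grid for a whole recording), the 1/f background
has a low-frequency corner keeping its correlation time well under the
trial length, and the session effect is modelled as *fresh realizations*
(new seeds, new per-stimulus jitter draws) rather than a session-constant
parameter offset, which would be such a fingerprint by construction.
These choices trade a little realism for an exact null: real resting EEG
does drift in band power across a session, and real pipelines genuinely
suffer the recording-confound this generator is built to exclude.

**Sessions.** Two sessions per subject (a morning/afternoon analogue) are
fresh realizations of the same subject parameters. No circadian model is
claimed.

## Preprocessing

Pipeline order is fixed: filter → ocular removal (VS only) → segmentation.

- **Band-pass.** Linear-phase windowed-sinc FIR, 1–55 Hz, Blackman window,
  1 Hz transition width (1409 taps at 256 Hz; ~90 dB at DC, <0.01 dB
  passband ripple). The group delay is compensated exactly by centred
  convolution with reflect padding, so filtered samples stay aligned with
  stimulus onsets. The deep DC attenuation matters: electrode offsets must
  not leave residuals that double as recording fingerprints.
- **Ocular removal** (VS only; EC is recorded eyes-shut and is left
  untouched). A blink reference — the mean of AF3/AF4/F7/F8 low-passed at
  5 Hz — is restricted to blink-dominated samples (>5 robust SDs, dilated
  by 150 ms) and its least-squares projection subtracted per channel. On
  generator ground truth this removes ≥50% (typically ~90%) of blink-window
  RMS; on blink-free recordings the mask is empty and the operation is the
  identity.
- **Segmentation.** EC: discard the first 5 s (settling), then
  non-overlapping 1 s frames — 25 trials of 256 samples from a 30 s
  recording; a partial final frame is dropped. VS: one epoch per onset over
  [−0.5 s, +1.5 s), i.e. 512 samples covering black screen, word, black
  screen; the text's alternative [−1.0, +1.0) reading of the same 2 s
  window is available via `pre_s`/`post_s`. Out-of-bounds events are
  dropped with a logged count.
- **Epoch rejection** (VS): drop trials whose peak absolute amplitude
  exceeds 100 µV (the conventional ocular-artifact threshold;
  configurable). Idempotent; refuses to return an empty set.

## Features

Per trial, the full-lag cross-correlation of each of the 91 channel pairs
is reduced to (max, mean, variance) over lags and concatenated pair-major
into 273 dimensions. The raw correlation sum is used (no energy
normalization; a normalized-coefficient mode exists but is off by default).
The FFT implementation is verified against a brute-force double sum to
1e−9 relative tolerance. Min–max normalization is fitted on training folds
only and applied unclipped to test folds; constant dimensions map to 0.
Fitting on pooled train+test statistics would leak fold information and is
deliberately not offered.

## Classification

Explicit OVO (n(n−1)/2 pairwise machines, majority vote; ties broken by
summed decision values, then class order) and OVA (n one-vs-rest machines,
argmax) over binary polynomial SVMs (degree 3, coef0 1, C 1). The kernel
scale is γ = 1/(d·Var(X)) — the variance-scaled convention — because the
min–max-normalized features have variance ≪ 1, and a variance-blind
γ = 1/d flattens the kernel toward a constant and underfits badly (observed
as an ~8-point accuracy drop on the EC task). γ, degree, coef0 and C are
all configurable and recorded in every report.

## Evaluation

5-fold cross-validation with randomized, mutually exclusive folds,
stratified by subject by default. Stratification was made the default after
measuring fold behaviour under the null: with unstratified folds a class
over-represented in the test fold is under-represented in training, which
biases top-1 accuracy on label-independent data systematically *below*
chance (~6% instead of 12.5% at 8 × 25 trials) — a bias that would poison
the zero-separation calibration. Stratified folds are unbiased at chance
(verified on iid features); `stratify=False` restores the plain behaviour.

Metrics are computed from per-class one-vs-rest confusion counts and
macro-averaged (micro available). Note that one-vs-rest *accuracy*
((TP+TN)/total) is systematically higher than plain top-1 accuracy for
multi-class problems; both are reported and labelled. 0/0 ratios are
defined as 0 with a logged warning. F1 defaults to the standard
2PS/(P+S); a `paper_literal` mode computes PS/(P+S) (half the harmonic
mean — a perfect classifier scores 0.5) for comparability with reports
using that variant. Fold dispersion is the sample standard deviation
(ddof = 1).

**Protocol comparison.** Per metric, Shapiro–Wilk on both per-fold
samples; if both pass at α = 0.05, a paired t-test, otherwise a
non-parametric test — rank-sum by default, signed-rank (the strictly
paired variant) selectable. Identical samples short-circuit to p = 1 with
a warning instead of an undefined statistic; zero-variance samples are
treated as non-normal. The per-fold macro metric samples are the units of
comparison.

## What the synthetic experiments show — and what they don't

Passing tests demonstrate that the pipeline is correct and well calibrated:
it extracts the between-channel structure the generator encodes, identifies
well-separated subjects near-perfectly, collapses to chance when subjects
are statistically identical, and its metrics and statistics agree with
independent oracles. They do *not* demonstrate field performance on real
EEG: the generator's subjects differ by construction in exactly the
features the method measures; real inter-subject differences are smaller
and entangled with recording confounds (electrode placement, impedance,
vigilance) that the exact-spectrum synthesis intentionally excludes.
Accuracies on the synthetic cohort should be read as calibration numbers,
not as forecasts for human data.

## Numerical and degenerate-input conventions

- All randomness flows from one top-level seed through named,
  protocol-tagged streams; recordings are bit-reproducible.
- EDF export quantizes to 16 bits over per-channel symmetric physical
  ranges (error ≤ range/65535); non-whole-second signals are zero-padded
  to complete the final 1 s record with a warning.
- Cross-correlation requires N ≥ 2; trials with a single channel, empty
  trial sets, schedules with no stimuli, and recordings shorter than the
  filter order or the discard window raise typed errors
  (`EmptyInputError`, `EmptyOutputError`, `InsufficientDataError`).
- `segment_ec` floor-truncates; concatenating EC trials reproduces the
  post-discard signal exactly over the kept span.

## Known limitations

- No physiological forward head model, impedance simulation or word
  semantics; ERP content does not depend on the stimulus identity.
- Only amplitude-threshold epoch rejection is implemented (no ICA or
  visual inspection analogue); ocular correction is regression-based, not
  a full artifact-removal toolbox.
- Closed-set identification only: there is no verification mode
  (accept/reject of a claimed identity with a threshold).
- The statistical comparison uses k = 5 paired fold samples; with so few
  observations the normality gate and the rank tests have limited power,
  which mirrors the small-sample regime the evaluation design implies.
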