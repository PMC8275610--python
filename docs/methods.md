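# Methods

This note records the models, parameter choices and numerical conventions
behind `gaitscope`, and what the synthetic experiments do and do not show.

## The synthetic cohort generator

Remote walk-test accelerometry of people with MS is not openly available, so
every experiment in this package runs on generated data whose *class
structure* matches what such recordings look like. The generator is a signal
model, not a biomechanical simulation.

One subject is a draw of a `SubjectProfile` from per-group Gaussian
distributions; one test is then a pure function of that profile and the
subject's seeded random stream.

The vertical (y) axis of a walk test is

    a_y(t) = 1 g + steps(t) + harmonics(t) + perturbations(t) + noise

* **Steps** — a Gaussian-windowed single-cycle sinusoid per step
  (window SD = 0.25/cadence, carrier at the cadence), placed at
  `k/cadence + N(0, jitter)`. The window keeps each impulse band-limited
  around the cadence fundamental while looking like a discrete step. Sharp
  impulses put their 2nd harmonic at twice the cadence (~3.8 Hz for healthy
  walking), which is physically reasonable — real step transients are
  broadband — and worth remembering when reading the 3.5–17 Hz band.
* **Harmonics** (mild MS) — step-locked components at k × cadence for
  harmonics above 3.5 Hz, scaled by `harmonic_gain`.
* **Perturbations** (moderate MS) — an exponentially decaying burst at every
  step, amplitude 0.3 g, carrier drawn around 8.5 Hz (5–12 Hz range), decay
  constant 0.15 s. The decay constant is the one free parameter the class
  description pins only qualitatively: it must be long enough that the bursts
  register as a visible concentration of above-gait-band energy coinciding
  with each step in a scalogram, rather than a single-sample click; 0.15 s is
  about a quarter of a slow step period.
* The horizontal axes carry attenuated (×0.40, ×0.25), quarter-period
  phase-shifted copies of the vertical gait signal; independent Gaussian
  noise (SD `noise_sd_g`) is added to all three axes.

Default group parameters (all overridable in `SyntheticConfig`):

| group     | cadence (Hz) | jitter (ms) | step amp (g) | extras |
|-----------|--------------|-------------|--------------|--------|
| HC        | 1.9 ± 0.15   | 10          | 0.50         | — |
| PwMSmild  | 1.8 ± 0.2    | 15          | 0.45         | harmonic gain 0.3 |
| PwMSmod   | 1.5 ± 0.2    | 35          | 0.35         | 0.3 g bursts at 5–12 Hz, 1.5× noise |

The cohort default is 24 / 52 / 21 subjects (HC / mild / moderate) with
120 s tests at 50 Hz — the study conditions this package models. The HAR
source domain uses the same gait model for walking (2.0 Hz), jogging
(2.7 Hz, larger impulses) and stairs (walking with amplitude alternation at
cadence/2); static activities are gravity along an activity-specific
orientation plus low noise.

Per-subject random streams are derived from one root seed by stable hashing
of the subject id, so a cohort is byte-reproducible and extensible without
reshuffling existing subjects.

**What passing tests show** — that the pipeline recovers class structure
carried by cadence, harmonic content, timing variability and step-locked
bursts at realistic amplitudes and noise levels. **What they do not show** —
performance on real MS gait, which adds within-subject day-to-day
variability, turning artifacts, device placement variation, fatigue-related
drift within a test, and disease heterogeneity far beyond three parameter
clusters.

## Preprocessing

Fixed order: resample → low-pass → gravity alignment → magnitude → detrend +
normalise → epoch.

* Resampling to 50 Hz uses monotone (shape-preserving) piecewise-cubic
  interpolation; it is the identity when the input is already at 50 Hz.
* The low-pass is a 4th-order Butterworth at 17 Hz applied
  forward-and-backward. Zero-phase filtering is chosen so that relevance
  overlays line up with the unshifted step morphology; the consequence is a
  squared magnitude response, i.e. gain 0.5 (−6 dB) rather than 1/√2 at the
  cutoff. This is asserted against the analytic response in the tests.
* Frame alignment estimates gravity as the whole-test mean acceleration
  vector and applies the minimal rotation taking it to +y (Rodrigues
  formula). If ‖mean‖ < 0.1 g there is no identifiable gravity direction and
  alignment is skipped with a warning. Rotation preserves ‖a‖ exactly.
* The magnitude channel is computed from the aligned signal *before*
  normalisation; then all four channels are linearly detrended and z-scored
  per channel over the whole test (not per epoch). A zero-variance channel
  becomes all-zeros with a warning rather than dividing by zero.
* Epochs are half-open 128-sample windows at step 64 starting at sample 0;
  a trailing partial window is discarded, so a test of N samples yields
  ⌊(N−128)/64⌋+1 epochs.
* To equalise subjects with different numbers of repeated tests, m = 10
  tests per subject are resampled with replacement before training; class
  imbalance in training/validation splits is removed by random oversampling.
  Test splits are never balanced or resampled away from their natural
  distribution.

## The classifier

A deliberately small 1D CNN on the 4×128 epoch:
conv(32 filters, kernel 9) → ReLU → maxpool(2) → conv(64, 5) → ReLU →
maxpool(2) → flatten → dense(100) → ReLU → dense(n classes) → softmax.
Training minimises cross-entropy with Adam (lr 1e-3, batch 64), early
stopping on validation loss (patience 10 by default), restoring the best
weights. Validation is held out subject-wise (~10 % per class) inside every
training split. All randomness flows from a single integer seed and the
implementation is plain NumPy, so runs are bit-reproducible.

The architecture and optimiser settings are conventional defaults sized so
that full training on a synthetic cohort takes well under a minute per run on
one CPU core; they are not tuned, and any ReLU-only stack of the supported
layer kinds can be configured instead. Hidden activations other than ReLU
are rejected at build time because the relevance rules below assume
positive, monotonically increasing activations.

## Transfer learning

* `end_to_end` — fresh network, target data only.
* `direct` — the trained source body is fully frozen; only the final dense
  layer is replaced by a disease head and retrained. (A raw HAR model has no
  disease outputs, so "applying it directly" necessarily means retraining a
  head.)
* `fixed` — convolutional blocks frozen as a fixed feature extractor; all
  dense layers retrain.
* `fine_tune` — every parameter is initialised from the source model (head
  replaced) and retrained at lr × 0.1. We implement fine-tuning as a full
  warm start rather than freezing the convolutional stack: freezing would
  make the regime identical to `fixed` but slower, capping it at the source
  features' fit to the target task, whereas a warm start can both exploit
  and adapt them. `TransferPlan.frozen_layers` makes any partial-freezing
  variant available.

Freezing is exact — the optimiser never touches a frozen layer, and the
tests assert bit-identity.

The transfer-benefit experiment is directional only: with target training
restricted to 6 subjects per class, fine-tuning from the HAR source matches
or beats end-to-end training in most seeds. No fixed margin is claimed; on
clean synthetic data both regimes often saturate, and the published gains on
real data (8–15 %) are not reproducible here.

## Evaluation

Folds partition *subjects* (stratified by group when every group has ≥ k
members, otherwise unstratified with a warning); validation subjects are
carved from training folds per class. The no-leakage property — empty
intersection of train/validation/test subject sets — is hard-asserted on
every fold of every run.

Epoch predictions aggregate to a test label by majority vote, test labels to
a subject label the same way. Ties break deterministically: first by the
higher mean predicted probability across the tied classes, then toward the
more severe class (HC < mild < moderate). The severity tie-break is our
convention; voting ties are rare but must be reproducible.

Metrics: macro accuracy = mean per-class recall; MF1 = unweighted mean
per-class F1; Cohen's κ with marginal-product expected agreement. The
implementations are our own (they are the quantities under test) and are
cross-checked against scikit-learn to 1e-9 on random confusion matrices.

## Layer-wise relevance propagation

Relevance starts at the pre-softmax logit of the explained class (default:
the predicted class; configurable). The logit rather than the probability is
decomposed because the propagation rules are defined on pre-activation
quantities. Rules, per layer kind:

* convolutional: α₁β₀ (only excitatory contributions propagate), applied per
  output position over its receptive field;
* dense: signed-ε rule with ε = 0.01 and sign(0) = +1;
* ReLU: pass-through; max-pool: winner-take-all to the argmax; flatten:
  index-preserving reshape.

Bias relevance is absorbed, never pushed to the inputs; every layer's
relevance sum is recorded in an audit trail so conservation and absorption
are inspectable.

Two numerical conventions matter:

* A denominator smaller than 1e-12 in magnitude is replaced by ±1e-12.
* **Degenerate α₁β₀ outputs.** If an explained neuron has *no* positive
  contribution at all (z⁺ = 0), the positive-share redistribution is 0/0 and
  a naive stabiliser silently destroys all relevance. This can only happen
  at the unrectified head (a hidden unit with positive activation always has
  z⁺ > 0), e.g. when the explained logit is negative with all excitatory
  paths dead. Such outputs fall back to signed proportional shares — the
  ε-rule in the limit ε → 0 — which keeps conservation exact. Both the
  vectorised implementation and the independent per-neuron oracle implement
  this convention.

For bias-free networks propagated with α₁β₀ everywhere, the input relevance
sum equals the explained logit to machine precision (asserted at 1e-4
relative, observed ~1e-16).

## Time-frequency analysis

Scalograms use the real Morlet wavelet with scales mapped from a log-spaced
frequency grid, 64 voices over 0.25–17 Hz — fine enough to resolve the gait
band and reaching the low-pass edge. Magnitudes |CWT| are stored; band
energies E_s are mean squared magnitudes over a band × time region
(normalised by region size so bands of different widths compare). Default
bands: gait 0.5–3 Hz, fast gait 1.5–3 Hz, perturbation 3.5–17 Hz. Pure
tones between 1 and 10 Hz localise to the nearest grid frequency (asserted
within one bin).

## Representative epochs (DTW/DBA)

DTW is the classic dynamic program with squared-difference local cost, unit
steps {(1,0),(0,1),(1,1)}, no band constraint, and diagonal-preferred ties;
it is exact against brute-force path enumeration for short sequences.

Epoch selection per class: correctly classified, posterior > 0.85, at most
40 epochs from any single test, then uniform sampling without replacement up
to the target count (2000 at study scale; the synthetic experiments use 60).

DBA initialises at the medoid and iterates align-then-average until the
objective (sum of squared-cost DTW distances) improves by less than 1e-6 or
30 iterations. Multichannel epochs are averaged under a *shared* warping
computed on the magnitude channel — this keeps the four channels temporally
aligned, and makes the monotone-decrease guarantee apply to the
magnitude-channel objective, which is what the trace records. The barycenter
is then re-scored by the trained classifier and explained with LRP.

## Problem sizes in the shipped experiments

The experiment helpers default to desk scale: 10 subjects per group, 4 tests
per subject of 16–20 s each, m = 10 resampled tests, two or three held-out
subjects per class; the transfer experiment restricts target training to 6
subjects per class and uses an 8-subject, 6-activity source domain. These
sizes exercise every stage of the pipeline in minutes on a single CPU core
while keeping the statistical properties (held-out-subject accuracy ≥ 0.85,
voting never hurting, the transfer direction) stable across seeds. Full
study-scale settings (120 s tests, 24/52/21 subjects, n = 2000 DBA epochs)
remain the package defaults in `SyntheticConfig` and `DbaSelection`.

## Known limitations

* The generator's groups are parameter clusters, not patients; no
  within-subject progression, fatigue or placement variation is modelled.
* The α₂β₁ relevance rule (which also visualises contradicting evidence) is
  not implemented; the configuration accepts general (α, β) with
  α − β = 1, β ≥ 0, but α₁β₀ is the tested path.
* Gyroscope/magnetometer channels, smartwatch placements and walking-bout
  detection inside a test are out of scope — tests are assumed to be
  walking.
* DTW/DBA complexity is quadratic in epoch length; the numba-accelerated
  recurrence handles the shipped sizes comfortably but no band constraint or
  lower-bounding is implemented.
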