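# Methods

This note documents the models, estimators and numerical choices behind
`pfrkit`, what the synthetic-data generator does and does not emulate, and
the known limitations of each stage.

## The measurement model

The post-saccadic following response (PFR) is an involuntary smooth drift of
the eye, after a saccade to a peripheral motion aperture, along the motion
direction that was present at the target before the saccade. Because the
stimulus motion in the task is tangential to the center-out saccade vector,
drift along the motion axis is orthogonal to residual saccadic (radial)
velocity, which is why the analysis projects eye velocity onto the motion
direction rather than using its magnitude.

Two epochs are distinguished, both time-locked to saccade offset:

- **open-loop, 20–100 ms**: too early for post-saccadic foveal motion to
  influence the eye; drift here reflects pre-saccadic peripheral motion
  processing. The first 20 ms are excluded to avoid saccade-related
  transients.
- **foveally-guided, 100–200 ms**: when the stimulus is still present at
  landing, foveal motion drives ordinary ocular following here.

The per-trial open-loop measure is deliberately filter-free: the raw
eye-position difference between the samples nearest t_off+20 ms and
t_off+100 ms, divided by the nominal 80 ms, projected on the target motion
unit vector, and normalized by the 10 °/s target speed to give a
dimensionless gain. Nearest-sample lookup (no interpolation) keeps the
measure strictly raw; at 220 Hz this contributes a bounded quantization
error of up to one sample interval (≈4.5 ms) at each epoch edge, i.e. a
relative error of a few percent per trial, unbiased to first order and
negligible after averaging. Trials whose primary saccade is not labelled
correct, or whose trace does not cover the epoch with valid samples, are
excluded from all PFR statistics rather than imputed.

## Saccade detection

Detection follows the adaptive 2D velocity-threshold scheme: velocity is a
central difference over a (2h+1)-sample window (h = 2 by default, which both
differentiates and smooths), per-component noise scales come from the
median-of-squares estimator σ = √(median v² − (median v)²), and a sample is
saccadic when (vₓ/λσₓ)² + (v_y/λσ_y)² > 1 with λ = 6. Runs shorter than
15 ms are discarded and runs separated by less than 20 ms merged — standard
values for this detector family; the source method is cited without
parameters, so these defaults are ours and are configurable.

Numerical choices:

- σ is floored at 3 °/s per axis. On noiseless synthetic traces the median
  of squared velocities is exactly zero and the threshold would collapse,
  classifying the post-saccadic drift itself as saccadic. The floor
  corresponds to the velocity noise of an implausibly clean 220 Hz recording
  (≈0.05° RMS position noise) and is inactive on any realistic trace.
- Ties between events exiting the fixation window in the same sample
  resolve to the earlier onset index.
- Velocity smoothing can advance detected onsets by up to the window
  half-width on noise-free traces; empirically, at the default noise level,
  detected onsets are unbiased (mean error −0.7 ms, SD 1.7 ms) and offsets
  nearly so (+0.7 ms, SD 1.5 ms).

The correctness rule — gaze within 3.5° of the cued center at some sample no
later than 90 ms after the eye leaves the ±1° fixation window — is applied
to the trace, so a trial can be labelled correct on a mid-flight sample if
the saccade path passes near the center. The generator therefore records a
ground-truth correctness flag computed from the same rule on the noise-free
path, and recovery tests compare the classifier against that flag rather
than against the raw mis-selection probability.

## The synthetic generator

`gaze_synth.make_trial` composes, on a uniform 220 Hz grid:

1. fixation at the origin with white per-sample Gaussian jitter
   (default SD 0.08°/axis — see calibration below);
2. a saccade at cue time + latency, with latency Gaussian
   (mean 360 ms, SD 45 ms intact-field defaults) truncated at 100 ms;
3. a raised-cosine position profile whose duration follows the main
   sequence, 2.2 ms/deg × amplitude + 21 ms;
4. a landing point at the selected aperture center plus isotropic Gaussian
   scatter parameterized by its mean absolute radial error
   (per-axis σ = MAE/√(π/2); default MAE 1.59°); with probability
   `misselect_prob` the saccade instead targets a uniformly chosen non-cued
   aperture;
5. post-offset drift along the *selected* aperture's motion direction:
   `open_loop_gain` × speed for 0–100 ms, then `foveal_gain` × speed if the
   stimulus is present at landing, else exponential decay of the drift
   velocity with a 100 ms time constant.

The generator is field-agnostic: callers pass the gain appropriate to the
cued field (intact vs cortically blind), and the cohort builder in
`pipeline` selects the profile from the cued aperture's field label. The
maximum accepted saccade latency (the task's response grace period) has no
canonical value and is exposed as configuration (default 1000 ms).

**Noise calibration.** The per-sample jitter SD (0.08°) was set so that the
per-trial open-loop gain noise it induces, √2·0.08°/80 ms/10 °/s ≈ 0.14,
yields a subject-level standard error of ≈0.0115 at 150 trials — the scale
of the reported blind-field group data (SEM ≈ 0.012). The default cohort
carries no additional between-subject gain heterogeneity, so recovered group
means converge on the generating gain at that SEM scale. The
location-level analyses in the test suite *do* add between-location gain
scatter (SD 0.05), matching the spread of per-location gains in the study's
field-level figures.

What the generator does **not** emulate: blinks and track loss, saccadic
curvature and dynamic overshoot, corrective saccades, drift/tremor
microstructure of fixation, pink (correlated) tracker noise, pixel
quantization, and the contrast dependence of the response. Passing
round-trip tests therefore demonstrate that the estimators are unbiased and
correctly scaled under the stated noise model, not that they are robust to
every artifact of real recordings.

## Psychophysics

The 2AFC global-direction task is simulated by a Bernoulli observer with
p(correct) = 0.5 + (0.5 − lapse)·exp(−(range/α)^β), α anchored so that
p(threshold) = 0.75, slope β = 2 and lapse 0.01 by default. The staircase is
3-up/1-down over 0–360° in 40° steps starting at 0°, which converges where
p³ = ½, i.e. near the 79.4%-correct level.

The Weibull fit is maximum likelihood over all trials pooled by level,
optimized with L-BFGS-B in (log α, log β, lapse), lapse bounded in
[0, 0.06], guess fixed at 0.5, three starting points (α₀ = 80, 200, 330),
relative function tolerance 1e-12. The 75% threshold is
α·(−ln(0.25/(0.5 − lapse)))^{1/β}; NDR = (360 − threshold)/360. Sessions
with a single level or uniform responses, failed optimizations, and fits
whose threshold falls outside (0, 360] are flagged unmeasurable and mapped
to NDR = 1 (no extrapolation beyond the stimulus range). A chance-level
observer consequently yields NDR at — or numerically indistinguishable
from — 1, via a vanishing fitted threshold.

**Known limitation (documented, deliberate).** With the shallow β = 2
observer, the staircase concentrates trials near the ~79% level, which for
high-threshold (low-NDR) observers lies far below the 75% threshold level;
the threshold must then be extrapolated from the sampled region. At 100
trials/session the median |recovered − true| NDR is ≈0.09 at NDR 0.1–0.2,
falling below 0.05 only for NDR ≥ 0.5. This is an information floor of the
design, not an estimator defect: fixing the generating slope and lapse in
the fit (an oracle no real analysis has) still leaves a median error of
0.08 at NDR 0.1. Steeper observers recover proportionally better; the
defaults are left as stated. The same noise attenuates location-level
NDR–gain correlations, which is why the qualitative-pattern tests average
the correlation over replicate cohorts.

## Statistics

- t-tests: one-sample (vs 0), paired, and two-sample with pooled variance
  (df = n₁+n₂−2) by default, Welch behind a flag. Zero-variance samples are
  flagged (infinite t) rather than raised.
- JZS Bayes factor: Cauchy(0, √2/2) prior on the standardized effect size,
  marginal likelihood ∫ nct(t; ν, δ√N)·Cauchy(δ) dδ by adaptive quadrature
  (effective N = n for one-sample, n₁n₂/(n₁+n₂) for two-sample), divided by
  the central-t density. Agreement with an independent implementation
  (pingouin) is ≤0.1% across the tested range; quadrature failure raises
  rather than returning a value.
- Bootstrap: seeded percentile intervals, B = 10,000 by default.
- Exponential NDR–gain fit: least squares for gain = a·e^(−b·ndr) + c with
  three b starting values; the pointwise 95% confidence band is a percentile
  bootstrap over intact-field location resamples (resamples with fewer than
  three distinct NDR values are redrawn). Blind-field locations with
  NDR < 0.35 — the midpoint between the intact-field NDR ceiling (0.3) and
  the next staircase increment — are counted inside/outside the band, and
  the lower binomial tail P(X ≤ k), X ~ Bin(n, 0.95) quantifies overlap.
- Location-level rows are treated as independent samples in the primary
  analysis; `pooled_by_participant` provides the unweighted within-
  participant pooling used as the robustness variant.

## Problem sizes used by tests and the acceptance script

Gain round trips use 11 subjects × 150 trials per field; accuracy and
landing error use 2,000-trial sessions; psychometric recovery uses 200
sessions of 100 trials per true threshold; detector equivalence uses 100
randomized traces against an exhaustive per-sample re-scan; qualitative
pattern checks use five replicate cohorts of 34 locations × 75 trials.
These sizes match the study's session scale while keeping the full suite
fast on one CPU.
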