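# Methods

## Task generative model

A session tiles `floor(session_duration / 0.75)` flash slots (250 ms
image + 500 ms gray) and lays trials over them contiguously. For each
trial a change time is drawn from the offset-exponential sampler and
snapped *up* to the next flash onset, so changes always occur on flash
boundaries. The sampler is `change_time_min + Exp(s)` with draws above
`change_time_max` rejected; the scale `s` is found by Brent root-finding
on the closed-form truncated-exponential mean
`E[X | X ≤ L] = s − L·e^(−L/s)/(1 − e^(−L/s))` so that the truncated
mean equals the configured 4.25 s (s ≈ 2.792 s for the default bounds).
The calibration is cached per (span, mean) pair.

Trial identity comes from the transition path, not from an independent
coin flip: paths are Eulerian circuits over the complete digraph on the
image set including self-loops, built by randomized Hierholzer
traversal; a self-transition is a catch trial. With 8 images this makes
the catch fraction structurally 1/8 = 12.5 %, matching the configured
`catch_fraction`; the parameter is retained for validation and for
non-default image counts. A matrix of 1000 paths is pre-generated per
session and sampled at random; because circuits are cyclic, a fresh path
is rotated to start at the image currently on screen, preserving
continuity.

Pre-change licks abort a trial, which restarts at the next flash slot
with the *same* scheduled change time, up to `max_trial_repeats = 5`
repeats; a sixth abort records the trial as ABORTED and the session
advances. Because the skipped change was never displayed, advancing
blindly along the path would produce an unflagged image jump; instead
the next trial re-selects a path rotated onto the on-screen image.

Reward bookkeeping: the first five trials are free-reward trials (go
trials with a non-contingent reward at the change time), and a MISS
counter — incremented by go-trial MISS outcomes only, reset by any
reward delivery — converts the next trial into a free-reward trial when
it reaches 10. Counting MISS outcomes rather than literally consecutive
trials is deliberate: catch trials and aborts interleave freely, and
this rule is the one that yields exactly ten MISS trials between
successive automatic rewards for a never-licking subject.

Omissions are independent Bernoulli(0.05) draws over eligible flashes
(neither a change flash nor the flash immediately before one; the flash
*after* a change is eligible). Consecutive omissions are allowed.
Omitted flashes keep their slot — the gray screen continues.

The HIT window is half-open on the left, (change, change + 750 ms], so
the printed 750 ms latency is attainable and a lick at exactly the
change time counts as pre-change (abort).

## Agent model

The agent is a parametric stand-in for the mouse: per-go-trial hit
probability, per-catch false-alarm probability, per-flash spontaneous
lick probability (the source of aborts), and reaction times from a
normal truncated to (0, 750 ms]. Running speed (60 Hz, the stimulus
clock) is bouted — exponential bout durations with mean 10 s, each bout
running with probability `run_fraction` at `run_speed_mean` ± 20 % —
and pupil area (30 Hz) is a baseline with slow detrended drift. Defaults
(p_hit 0.8, p_FA 0.25, p_spontaneous 0.02/flash, RT 0.35 ± 0.10 s) give
a moderately proficient, engaged subject: hit rates near 0.8 and d′
around 1.5.

## Synthetic activity

Event traces are inhomogeneous Poisson on the 30 Hz frame grid: per
frame, a Poisson count with mean rate·dt and an exponential magnitude
per event (mean 1 a.u.; a k-event frame carries a Gamma(k) magnitude).
Background events at 0.05 events/s everywhere. Rate profiles:

* excitatory — Gaussian bump after onset (center 130 ms, SD 50 ms, peak
  25 events/s for the preferred image), tuning weights
  `exp(−d·sharpness)` in circular image distance d; the familiar
  condition scales amplitude by 0.65 and sharpness by 1.5 (direction of
  the experience effect; the sizes are free model parameters, not
  claims). Omitted flashes are silent.
* VIP driven — untuned bump (center 150 ms, SD 60 ms, peak 20 events/s,
  baseline 1/s); silent on omissions.
* VIP suppressed-ramping — rate is a function of time since the last
  *presented* flash: zero for 150 ms (suppression), then a linear ramp
  reaching the 20 events/s peak at the next scheduled onset; through an
  omitted flash the clock keeps running, so the ramp keeps growing
  (capped at 2× peak) until a stimulus finally appears. This implements
  the omission expectation signal.

VIP mode counts are fixed per population (80/20 suppressed-ramping vs
driven under familiar, the reverse under novel) rather than drawn per
cell, so small populations realize the configured mixture exactly.

What the generator does *not* emulate: correlated population noise
beyond shared rate profiles, adaptation across repeats, running/pupil
modulation of firing, ROI overlap or imaging noise. Passing tests
therefore show that the analysis recovers structure the generator
plants — directionally matching the experimental phenomenology — not
that it would survive every nuisance of real imaging data.

The fluorescence forward model (for testing the processing chain) is
FC_true = F0 + events ⊛ exp(−t/τ) with τ = 0.7 s (GCaMP6f-like), an
independent smooth neuropil trace FN, and FM composed exactly as
FC_true + r·FN with r = 0.7 by default; r is a known simulation input
here, not estimated.

## Trace processing

* Neuropil subtraction: FC = FM − r·FN, the algebraic inverse of the
  forward model.
* dF/F: F0 is the histogram mode (bin width 0.1 % of the trace range;
  ties to the lowest bin) over a *trailing* 180 s window — trailing so
  the baseline never uses future samples; a centered window would halve
  the response to a sustained step. (F − F0)/F0; nonpositive F0 raises
  with the offending frame index.
* Event smoothing: causal half-Gaussian, SD 65 ms, truncated at 4 SD,
  unit-sum normalized so total event mass is conserved; output at t
  depends only on events at ≤ t.
* Alignment: each imaging frame maps to the latest stimulus clock time
  *strictly* before it (ties map backwards), so no response is
  attributed to a stimulus after the frame.
* Pupillometry: least-squares ellipse fit (scikit-image `EllipseModel`)
  to tracked points with confidence ≥ 0.8; missing with fewer than six
  such points or a degenerate (axis ratio < 10⁻³) fit. Pupil area is
  the area of a circle with radius equal to the major *semi*-axis — the
  "major axis" phrasing is ambiguous; the full-axis reading would scale
  all areas by 4 and affects nothing downstream that is
  scale-invariant. Trace cleaning drops frames > 3 SD from the mean and
  the two frames on each side of every missing run, then interpolates
  linearly with flat edges.

## Behavioral metrics

Engagement uses a centered 5-minute rolling window (the criterion names
the 2 rewards/min threshold but no window; 5 min is long enough to
bridge inter-trial gaps and short enough to track disengagement), with
edge windows clipped to the session and the rate computed over the
actual overlap; the threshold is inclusive. d′ clips rates to
[1/(2n), 1 − 1/(2n)] per trial type before the inverse-normal
transform. Reaction times are raw first-lick latencies after the
change, not truncated at the response window. Locomotor state is
running iff windowed mean speed strictly exceeds 5 cm/s ([−0.5, 0.75] s
around flashes, ±2 s around omissions).

## Response metrics

Windowed responses use half-open [onset, onset + w) frame membership,
w = 500 ms for presented flashes and 750 ms for omissions (anchored at
the scheduled, never-shown onset). Preferred image is the argmax of
per-image mean responses, ties to the lowest index.

The responsiveness classifiers resample the complementary pool with
replacement 10,000 times; each target presentation's p-value is the
fraction of resampled values ≥ it — the tie rule (≥, not >) makes an
all-zero cell come out with p = 1 everywhere and never responsive. The
null pool for image-responsiveness is the cell's omission responses,
for omission-responsiveness the cell's presented-flash responses.
Fractions: ≥ 25 % of preferred-image presentations (image), ≥ 10 % of
omissions (omission), both at p < 0.05. Lifetime sparseness is only
reported for image-responsive cells; population tuning curves are
suppressed in the pipeline below 10 responsive cells.

Ramp index: log₂((R_late + ε)/(R_early + ε)) with ε = 10⁻⁶ a.u.
guarding zeros. The log-ratio form is used because it is the form
consistent with the stated sign convention (positive for rising
traces); R_early/R_late are the first/last sub-window means. Windows:
pre-stimulus (−400→0 ms, 120 ms sub-windows = 4 frames at 30 Hz),
stimulus (0→125 ms from *onset*, 65 ms sub-windows = 2 frames; an
offset-anchored variant is provided as `STIMULUS_RAMP_FROM_OFFSET`),
omission (0→750 ms halves — this window's split is a package choice).
Sub-window frame counts round to the nearest frame and may overlap
mid-window, as the 65 + 65 > 125 ms stimulus spec implies. Ramp indices
and time-to-peak are computed on causally smoothed event traces, the
same processing the response windows see.

Dynamics class is the sign of the stimulus ramp index (zero counts as
suppressed; an exactly-zero index on real-valued data is a measure-zero
event).

## Group statistics and pipeline

`compare_image_sets` always runs the pairwise Welch tests; the ANOVA
gates nothing (pairwise p-values are reported regardless). Bonferroni
alpha = 0.05/6 ≈ 0.0083 for four sets. Confidence intervals are
percentile bootstrap of the mean (n_boot = 1000, dedicated seed); a
parametric alternative was considered and rejected to avoid normality
assumptions on fraction-valued metrics.

`run_pipeline` derives one seed per condition from the master seed
(seed·1000 + index, kept below 2³¹ for small master seeds) so that
conditions are independent but the whole run is reproducible
byte-for-byte. The CLI is a thin wrapper; the library functions are the
primary interface.

## Problem sizes

Tests and the acceptance script run on desk-scale problems chosen to
keep the statistics meaningful: 10-minute sessions (800 flash slots,
~100 trials) for population analyses, 20 one-hour sessions for pooled
task-structure rates, 24–100 cells per synthetic population, 10,000
classifier resamples, 100,000 sampler draws. These sizes give sampling
errors comfortably inside the assertion tolerances (e.g. the pooled
omission rate over ~74,000 eligible flashes has SE ≈ 0.08 percentage
points against a ±0.5 tolerance).

## Known limitations

* The simulator does not reproduce the per-session presentation counts
  reported for the original apparatus (which are internally
  inconsistent); the structural rates (750 ms period, 12.5 % catch, 5 %
  omission) are the contract.
* Engagement filtering is applied to behavioral metrics only by
  default; whether it should gate neural metrics is configurable.
* The neuropil ratio r is a simulation input, not estimated per ROI.
* Training-stage progression, water restriction, hardware timing jitter
  and figure rendering are out of scope.
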