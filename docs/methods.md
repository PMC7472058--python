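# Methods

`actichild` implements a supervised pipeline for recognizing the movement
behavior of preschool-aged children from raw tri-axial accelerometry
collected under free-living (free-play) conditions, with ground truth from
continuous video-based direct observation. This note documents the models,
conventions and design choices; the README shows how to run it.

## Problem setting and data model

Each subject wears two ActiGraph-style devices (right hip, non-dominant
wrist) sampling acceleration in g at a fixed rate (100 Hz by default).
A trained observer codes the session as a sequence of non-overlapping
intervals labeled with one of five activity classes —

| code | meaning |
|---|---|
| `SED` | sedentary (sitting/lying, stationary) |
| `LIGHT_AG` | light activities and games (standing, easy limb/trunk movement, slow translocation) |
| `MV_AG` | moderate-to-vigorous activities and games (fast, non-steady translocation, climbing, riding) |
| `WALK` | steady walking |
| `RUN` | steady running |

— plus `OUT_OF_VIEW` for intervals where the child left the camera frame.
Event intervals are treated as half-open `[start, end)` so a boundary
sample is never labeled twice. Samples not covered by any event get the
sentinel `UNLABELED`, kept distinct from `OUT_OF_VIEW`; both are excluded
from training. Device/video clock synchronization is assumed to have
happened upstream; both placements are assumed to share timestamps.

## Windowing

Annotated recordings are tiled from their first sample into non-overlapping
windows of a fixed duration (1, 5, 10, 15 s in the standard sweep); a
trailing partial window is dropped. The window label is the code covering a
strict majority (>50%) of its samples. Windows with no strict-majority
class, or whose majority code is `OUT_OF_VIEW`/`UNLABELED`, are labeled
`EXCLUDED`: they remain in the window sequence (so lag/lead indexing stays
contiguous and their signal can still feed neighboring windows' temporal
features) but never appear in feature tables. An exact 50/50 tie is
`EXCLUDED` rather than broken arbitrarily — a ">50%" rule leaves ties
undefined, and unstated tie-breaks create label noise. Windows overlapping
more than one observed code are flagged `mixed`; the mixed-window share is
reported per placement and grows with window duration for bout-structured
behavior. The majority is computed over samples, which at a uniform rate
equals wall-time coverage.

## Features

Within each window the tri-axial signal is collapsed to the vector
magnitude `VM_i = sqrt(ax_i^2 + ay_i^2 + az_i^2)`. Twenty base features are
computed: VM mean, SD, min, max, IQR, the 10/25/50/75/95th percentiles,
coefficient of variation, signal sum, signal power, peak-to-peak amplitude,
median crossings, the three cross-axis Pearson correlations (the only
features computed on the raw axes), and the dominant frequency in
0.25–5.0 Hz with its magnitude. Conventions, where the field literature is
silent:

* all SD-type quantities use the population convention (divide by N);
* `vm_cv = vm_sd / vm_mean`, 0 when the mean is 0 (cannot occur under gravity);
* `vm_power` is the *mean* squared VM so the feature is window-length
  invariant; `vm_sum` is the plain sum;
* percentiles interpolate linearly between order statistics;
* median crossings count strict sign changes of `VM − median`; samples
  exactly on the median do not count;
* a zero-variance axis yields correlation 0 rather than NaN;
* the spectrum is the FFT magnitude of the mean-removed VM, zero-padded to
  `max(1024, n)` points. Padding to at least 1024 points makes the
  0.25–5 Hz band addressable even for 1 s windows, whose native resolution
  (1 Hz) could not honor the 0.25 Hz band edge; windows longer than 1024
  samples keep their own length. Magnitudes are scaled by `2/n`; ties break
  toward the lower frequency, so a constant window reports the lowest
  in-band bin with magnitude 0. Rates below 10 Hz trigger a logged warning
  because the band is then poorly resolved.

Five temporal (lag/lead) features summarize local context: the VM SD of the
windows 1 and 2 positions before and after the current window, and the
population SD of the five per-window VM means centered on the current
window (n = 5). Edge windows replicate their nearest existing neighbor,
keeping every window usable. The five-window SD uses per-window means; a
pooled-samples variant (one SD over all samples of the five windows) is
available via `five_window_sd="pooled_samples"` since the summary level is
a genuine modeling choice.

Feature fusion for the combined placement concatenates the hip and wrist
blocks column-wise with `hip_`/`wrist_` prefixes (20 or 25 features per
placement); windows usable at only one placement are dropped from the
fused table.

## Classifier

One Random Forest per placement x feature-set x window-size cell, 500
trees. `mtry` (features sampled per split) is tuned by out-of-bag error
over the grid {⌊√p⌋, ⌊p/3⌋, ⌊p/2⌋}; OOB tuning needs no extra data split.
Tuning probes use 100 trees — the OOB ranking of mtry values stabilizes
well before the full forest is grown — and the winner is refit with 500
trees. Ties in OOB error break toward the smaller mtry. No class
resampling or weighting is applied; class imbalance is handled at the
metric level (support-weighted F-scores). Mixed windows stay in training
and testing. Prediction aligns feature columns by name and breaks
probability ties by the fixed class order. All stochastic components
derive from a single integer seed; per-fold seeds are derived
deterministically, so repeated runs are bit-identical.

## Evaluation

Leave-one-subject-out cross-validation: one fold per subject, the held-out
subject never contributes training windows, predictions are pooled across
folds before metrics are computed (per-subject summaries are also emitted).
Confusion matrices are 5x5 with rows = predicted, columns = observed, in
fixed class order. Per class, precision = TP/row-sum, recall = TP/col-sum,
F = 2PR/(P+R), with zero-denominator cases set to 0. The overall score is
the support-weighted mean of per-class F-scores; zero-support classes carry
zero weight. Weighting by observed window support is the standard reading
of a "weighted average F-score"; subject-averaged weighting would be the
alternative. Inter-observer agreement between two coders' label sequences
is quantified with unweighted Cohen's kappa over the six-code alphabet;
kappa is undefined (an error) when chance agreement is 1. A repeated-
measures ANOVA across sweep cells is deliberately out of scope — any
standard statistics package does that downstream.

## Synthetic free-play cohorts

The simulator exists so every stage, including end-to-end LOSO recovery,
is testable with known ground truth. It emulates: ~20 min sessions; short
intermittent activity bouts (semi-Markov chain, no self-transitions by
default, exponential durations with class means 40/20/8/7/4 s for
SED/LIGHT_AG/MV_AG/WALK/RUN); occasional out-of-view intervals (5% of
bouts, which keep a hidden true class that still drives the signal); two
correlated placements sharing bout structure and per-bout phase/tempo; and
subject-level random effects (lognormal amplitude/noise multipliers,
stride-tempo shifts) so leave-one-subject-out evaluation is non-trivial.

Per class the signal is gravity on the vertical axis plus class-specific
noise, a sinusoidal stride component for WALK (~2 Hz, 0.30 g) and RUN
(~3 Hz, 0.70 g), and a mean-VM elevation that accompanies movement. All
classes are *intermittent*: a two-state moving/quiet telegraph process
with exponential dwell times gates the movement noise (and, for
locomotion, the stride itself — children stop and turn, so a 1 s window
can miss the gait signature entirely). Crucially, light and vigorous play
share a similar instantaneous movement intensity (move-state SDs 0.30 vs
0.42 g) and their quiet-state noise equals the sedentary level, so they
differ mainly in duty cycle (~30% vs ~73% of time moving; a seated child
fidgets ~4% of the time at 0.12 g). Dwell times of 1–2.5 s sit between
the window scales: a duty cycle cannot be estimated from a 1 s snapshot —
such a window mostly sees a single state, so a moving LIGHT_AG second
resembles a moving MV_AG second and a quiet one resembles sedentary
time — while a 10 s window averages over several dwell cycles. All
dynamic content is additionally modulated by a lognormal intensity
envelope (correlation time 0.45 s, sigma 0.5–0.6) and per-bout intensity
jitter. This temporal structure, not the amplitude table, is what makes
longer windows genuinely more informative and reproduces the window-size
gradient seen in free-living data.

The wrist channel additionally carries: extra broadband noise (0.08 g);
occasional random-phase hand-movement bursts during SED and LIGHT_AG
bouts (children fidget while otherwise stationary; rare enough that a
corrupted window sits among clean neighbors); per-bout attenuation of the
stride component (children hold objects while walking/running, suppressing
arm swing); and arm-stillness episodes (mean 4 s) during LIGHT_AG/MV_AG
bouts in which the wrist's dynamic content drops to a near-sedentary
residual although the body remains active. These mechanisms make wrist
windows harder to classify from a single window than hip windows, and make
the lag/lead context — whose neighboring windows reveal the bout's true
intensity — specifically valuable at the wrist, mirroring the
placement and feature-set effects reported for real free-living cohorts.

Default class parameters were calibrated so that the hip model with
lag/lead features and 10 s windows achieves a LOSO weighted F-score in the
0.85–0.95 range on a 15-subject cohort — the performance regime of real
free-living hip models — without claiming to reproduce any particular
published value.

What the simulator does **not** model: biomechanically realistic limb
kinematics, device quantization or ±6 g clipping, non-wear, posture
transitions, or inter-device clock drift. Passing tests on synthetic
cohorts therefore demonstrate pipeline correctness and qualitative
behavior (window-size, placement and feature-set trends), not field
accuracy on real children.

## Problem sizes used in tests and the acceptance script

Simulation-backed checks run at sizes chosen to keep the full suite fast
while leaving comfortable statistical margins: the end-to-end recovery
check and the acceptance script use the study-like cohort (15 subjects x
20 min, 100 Hz; ~1,800 ten-second windows), while the window/placement/
feature-set trend checks use 8 subjects x 10 min, whose ~4,500 one-second
windows per placement are the cost driver. Feature-level verification uses
1,000 random windows against brute-force implementations; metric-level
verification uses 50 random confusion matrices against hand computation.

## Known limitations

* The mixed-window share is only guaranteed to be non-decreasing in window
  duration in the large-sample regime; for very short sessions (tens of
  windows) the exclusion of tied/out-of-view-majority windows from the
  denominator can produce small inversions between adjacent window sizes.
* `mtry` tuning assumes OOB error ranks grid values as full-forest OOB
  would; with very small tables the 100-tree probe adds selection noise.
* The combined-placement table silently drops windows that are usable at
  one placement only (the count is logged); with heavily desynchronized
  devices this could discard a material share of windows.
* Percentile and SD conventions are fixed (linear interpolation,
  population SD); tables produced with other conventions will differ at
  the 3rd–4th decimal and should not be mixed.
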