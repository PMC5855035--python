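# Methods

This note documents the models, parameter choices and numerical decisions
behind `cogload`, and what the synthetic validation does and does not
establish about real recordings.

## Windowing model

Gaze samples are labeled *active(aoi)* when a fixation's coordinates fall
inside an AoI rectangle (half-open `[min, max)`, so shared edges are
unambiguous), *transition* when on-screen but in no AoI — including
saccades, which are never hit-tested — and *inactive* when coordinates are
missing (blinks, tracking loss). Maximal same-state runs become candidate
windows; runs shorter than 500 ms are deleted, and same-element candidates
on both sides of deleted material are joined into one window whose span
includes the gap. Signal samples inside the gap are retained for feature
extraction.

Two points of this rule are genuinely open and were fixed as follows:

* **Joining applies to transitions too**, treating "between elements" as
  one element class, symmetric with the per-AoI rule for active windows.
* **Join order is innermost-first** (smallest deleted gap first, by a
  priority queue over candidate pairs). This matters: inside an active
  window, every micro-saccade between fixations is a sub-500 ms transition
  run, while the window itself is flanked by long transitions. Joining the
  smallest gaps first stitches the fixations into a valid active window
  before the flanking transitions can bridge across it; once a stitched
  chain reaches 500 ms it blocks outer merges. A greedy left-to-right scan
  provably gets this wrong (it dissolves every active window built from
  short fixations into the surrounding transition).
* Inactive runs ≥ 500 ms act as barriers; shorter ones are bridgeable gaps,
  so a blink inside an AoI dwell does not split the window.

## Signal conditioning

All FIR filters use a Blackman-window design with the transition band at
25% of the cutoff, applied as a centred symmetric kernel (zero phase, so
event timing is preserved; a forward–backward pass would square the
magnitude response for no benefit with kernels this steep). Cutoffs:
pupil 2 Hz, EDA 5 Hz (then decimation 120→10 Hz), PPG 16 Hz, temperature
1 Hz, EEG 0.5–40 Hz. Two deviations from the uniform recipe:

* The **EEG high-pass** uses a transition band equal to its 0.5 Hz cutoff;
  at 25% the kernel would be ~5600 taps — longer than a short recording —
  while the relaxed design still removes DC/drift completely and passes
  2 Hz within 5%.
* The **ECG low-pass** is frequency-domain (FFT, raised-cosine edge at
  100 Hz ± 10%), which is exactly zero-phase and leaves R-peak times
  unchanged to the sample.

Baseline correction subtracts the mean of the 500 ms pre-stimulus segment
(filtering has unit DC gain, so the raw baseline mean is the correct
offset); z-scoring is per participant per channel over the whole session,
with the sample (n−1) denominator used everywhere a variance or sd
appears. The pupil chain converts diameter to circular area *before*
baseline subtraction, so the corrected quantity is a dilation/constriction
area in mm².

Ambiguities resolved in this module:

* Heart rate follows HR = 6000/Δt with Δt in **centiseconds** — the only
  unit reading under which the formula is dimensionally consistent.
  Peak detection uses an adaptive threshold (0.5 × rolling 2 s maximum)
  with a 250 ms refractory period.
* The EDA phasic component is **signal minus a running median** over a
  ±4-sample window at 10 Hz (the window shrinks at the edges). "Average of
  the current sample" is not a well-defined operation; the running-median
  tonic is the standard reading and is recorded in the provenance log.
* Hampel parameters (EEG outlier replacement) are unspecified upstream;
  the defaults ±3 samples / 3 scaled MADs follow common practice and are
  arguments of `clean_eeg`.
* Saccade samples in the pupil series are excised and bridged linearly,
  like blink gaps; gaps longer than 1 s are still bridged but flagged so
  windows overlapping them can be discarded.

## Feature layer

44 features per window: pupil area mean and variance (2); EDA accumulated
normalized signal, its time average, AC spectral power, and phasic mean /
max modulus / peak count (6); temperature mean and median (2); mean,
median and variance of the ECG absolute deviation from the window median
(3); HR mean, sd and RMS (3); and per-EEG-channel band power and circular
mean phase of the 2–15 Hz analytic signal for 14 electrodes (28).

Decisions:

* The normalized EDA divides by the **grand mean** of the cleaned signal
  over all m task segments (m = 1 by default, configurable in the session
  manifest). The printed normalization formula uses a sum where its
  surrounding text says mean; the mean is the reading under which a
  constant signal normalizes to exactly 1, and is what is implemented.
  The time average uses T = window sample count.
* Spectral power is the raw periodogram sum of the standardized window
  with the DC bin excluded; Welch averaging would waste the short windows.
* The pupil features are **mean and variance of baseline-corrected area**
  (reconciling a mean-of-area table entry with a mean-and-variance text:
  the 44-feature total requires two pupil features).
* EEG phase is summarized by the circular mean of instantaneous phase —
  an arithmetic mean of wrapped angles is meaningless.
* Per-participant z-scoring fixes each channel's total variance, so
  alpha-suppression shows up *within* a session (high-level windows carry
  less 2–15 Hz envelope power than low-level ones), not as a between-
  configuration change in mean power. The coupling test asserts the
  within-session rank correlation.

## Workload labeling

Clustering uses the standardized pooled **mean pupil area** per window
(1-D by default; the variance feature can be added). K is selected over
K = 2…10: both the CH index and WSS are min–max normalized over the grid,
and the selected K is the smallest grid value at which the normalized CH
curve has risen to meet or exceed the normalized WSS curve — the grid
point at the curves' intersection, with exact ties resolved downward.
Nearest-integer rounding of the interpolated crossing was rejected: on
well-separated four-level data the crossing interpolates to ≈ 3.4–3.6, so
rounding systematically returns 3 even though the CH optimum and the WSS
elbow both sit at 4; "first grid point at/past the crossing" recovers the
true K across 1-D mixtures (K = 3, 4) and 2-D cloud fixtures (K = 2).
If the curves never cross, the K minimizing their gap is returned and
flagged. Levels are numbered 1…K by ascending centroid pupil mean, making
"level" monotone in workload.

Stability is the clusterboot-style bootstrap Jaccard: recluster each
resample, match every original cluster to its best-overlapping resample
cluster on the shared points, and average over B = 100 resamples.
Calibration caveat: k-means boundaries on structureless data are fairly
stable (a single Gaussian forced into K = 4 scores ≈ 0.55–0.8, and ≈ 0.85
in 1-D), so the informative contrast is between genuine clusters (> 0.95)
and the ≈ 0.85 "highly stable" threshold, not an expectation that null
data score near zero.

## Classification protocol

Each repetition draws a stratified 70/30 split, optionally scores a
stratified 10-fold cross-validation inside the training portion (a sanity
metric — the held-out 30% produces the reported numbers), fits, and
records accuracy, macro recall, macro precision and Cohen's kappa from the
held-out confusion matrix; reports average over 100 repetitions by
default. Macro averaging was chosen for recall/precision because the
cluster-derived classes are imbalanced. Kappa is computed from the
confusion-matrix marginals, with the degenerate p_e = 1 case defined as 0.

The MLP is scikit-learn's two-hidden-layer ReLU network trained with Adam
and an L2 penalty of 1e-5. The reference architecture (1000 units per
layer, 500 epochs, 50% dropout, mixed L1+L2 penalties) is kept as the
default `ModelSpec`, with two caveats: the backend offers neither dropout
nor an L1 term (λ1 is effectively 0), and desk-scale runs in the tests and
examples use smaller layers (16–64 units) and fewer epochs/repetitions —
on the strongly separated synthetic fixtures the smaller network is
already at ceiling, so nothing is lost at validation scale. Pupil features
are excluded from classifier inputs by default: they generate the labels,
and including them (supported via `include_pupil_features`) leaks the
target.

RF-RFE drops the least important feature per step of a random forest,
tracks cross-validated accuracy per subset size, and returns the smallest
subset within one sd of the best; a selection whose best accuracy does not
beat the majority-class baseline by more than twice the larger of the CV
sd and the binomial sd is flagged degenerate.

## Statistics and QC

The window-type test aggregates windows to per-participant means per type
and runs a classical 2-level repeated-measures ANOVA (pingouin's
`rm_anova`). A window-level RM-ANOVA over the "complete universe of
windows" is nonstandard with unbalanced repeated measures, so the
aggregate design is primary and a within-participant permutation test over
window labels is provided as a secondary, assumption-free alternative.
Baseline validation tests, per participant, whether correction changed the
series: Shapiro on the paired differences, then Wilcoxon signed-rank;
participants where the null is retained are listed as indistinguishable.
QC utilities compute per-frame brightness (mean grayscale / 255 × 100) and
the EDA variation rate over consecutive 500 ms windows, flagging cohorts
whose mean rate magnitude reaches the 3–4.5% arousal band.

## Synthetic generator

Defaults mirror the emulated study: 53 participants, ~60-minute sessions,
sensor rates 120/120/50/1000/128 Hz, an 11-element AoI layout (7 news,
4 ads, menu), four workload levels with standardized pupil shifts
(−1.5, −0.5, 0.5, 1.5), within-level spread 0.25 SD, and a 0.5 SD pupil
decrement in transition windows. The pupil drive passes through a smoothing
kernel with ≈ 300 ms lag (response latency), blinks are 100–300 ms gaps
with missing values, ECG is a template pulse train and PPG a smoothed
pulse train sharing the same beat times (sufficient for peak detection and
deviation features, deliberately not a biophysical model), EEG channels
are independent alpha/theta oscillations plus smoothed noise (per-channel
features only — no cross-channel structure is consumed downstream), and
EDA is a slow tonic drift with exponential-rise/decay phasic events whose
rate grows with level. Everything is deterministic given
`(seed, participant_index)`.

What passing tests show — and don't: recovery of K = 4, ANOVA calibration
and classifier sanity demonstrate that the *pipeline machinery* is correct
under data whose generative structure matches its assumptions. Real
recordings add non-Gaussian artifacts, cross-channel coupling, drifting
baselines within sessions and AoI-dependent luminance effects that the
generator deliberately omits; results on synthetic cohorts therefore
validate implementation, not effect sizes in humans.

## Problem sizes used in validation

Tests and examples run scaled-down configurations chosen to exercise every
code path at desk scale: sessions of 30–600 s, cohorts of 3–30
participants, 20–200 simulated cohorts for calibration, B = 20–100
bootstrap resamples, and 2–20 evaluation repetitions. The statistical
calibration (type-I error within [1%, 9%] at α = 5% over 200 null
cohorts; ≥ 90% power at a 0.5 SD transition effect with 30 participants)
uses gaze-only simulation, which is why the generator's channel list is
configurable.
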