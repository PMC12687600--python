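# Methods

This note documents the models and procedures implemented in `smbench`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Percept maps and coverage

Percept drawings live on a shared two-panel hand template: a procedurally
drawn silhouette (palmar panel left, dorsal panel right, default 256 px
per panel) with labeled digit/palm zones, a straight wrist row, and a
physical scale calibrated so the wrist-to-middle-fingertip distance is
19.0 cm. Only pixels distal to the wrist row count as hand; `clip_to_hand`
intersects a drawing with that region before any statistic. "Total hand
area" counts both panels — whether the original analyses counted one or
both views is not documented, and both-views is assumed throughout.

Coverage of a drawing set is |union of masks| / total hand pixels.
Category filters (`tactile-only`, `proprioceptive-only`, `pain-only`)
require an exact category match, so a mixed tactile+proprioceptive
percept belongs to neither "only" subset. Categories derive from
free-text quality descriptors via a user-editable lexicon
(`DEFAULT_QUALITY_LEXICON`); the original mapping is unpublished, so the
default covers the descriptor families reported for each category
(pressure/touch/tingling/vibration → tactile; movement/joint/posture →
proprioceptive; pain/burning/stinging/ache → painful), and unknown
descriptors are ignored by default (`unknown="strict"` raises instead).

The wrist cut is a single row per template rather than an anatomical
contour: no wrist contour is available, and a row cut is exactly
reproducible across resolutions.

## Unique percept locations

Location dissimilarity between two binary masks is D = 1 − |L₁∩L₂| /
|L₁∪L₂|. Sessions are clustered with complete linkage (inter-cluster
distance = maximum pairwise D) over percepts that are tactile and/or
proprioceptive and not painful; mixed painful percepts are excluded by
this strict reading, and the predicate is configurable. The agglomerator
is written in-package with a deterministic tie-break (lexicographically
smallest cluster-index pair merges first) so results are platform-stable;
tests verify its merge heights against scipy's implementation and a naive
O(n³) oracle.

Cutting the dendrogram uses *inclusive* semantics: a merge at exactly the
cutoff height is kept, i.e. two percepts at D = cutoff count as the same
percept. The cutoff grid is 0.01…1.00 in steps of 0.01, with 0.7 and 0.9
reported as reference cutoffs. Session summaries are mean ± SE (sample
SD/√k; SE = 0 for a single session).

Only hand-clipped masks are clustered. Percepts referred entirely to the
residual limb (proximal to the wrist) therefore never enter the
clustering, which matches their exclusion from hand-coverage statistics.

## EMG features and training data

WFL of a 1 kHz signal is the mean absolute successive-sample difference
over a 100 ms window, updated every 50 ms (20 Hz frames). Windows are
causal, ending at each 50 ms boundary; early frames whose full window
would precede the signal use the available truncated window. This keeps
the closed forms exact in every frame (constant → 0, ramp of slope d →
d, ±A alternation → 2A) and yields exactly 100 frames for a 5 s trial.
A 10-bit quantizer (`quantize_10bit`) models the sense-lead coding; its
full scale is configuration, not a measured constant.

Trials follow the prompted-posture protocol: 32 postures (all single and
paired movements over 4 DOFs, directions in {−1,0,+1}) × 10 repetitions,
each 5 s = 2 s rest, 2 s move, 1 s rest. Data hygiene:

* **Outlier repetition**: per posture, each repetition's signature is its
  channelwise mean WFL over the movement window (frames 41–80); the
  repetition with the lowest mean Pearson correlation to the others is
  dropped (ties → lowest repetition index). The similarity metric is not
  documented in the source protocol; mean pairwise correlation is this
  package's choice.
* **Non-responsive channels**: a channel is flagged when its mean
  movement/rest WFL ratio over all trials falls below 1.2 — a threshold
  chosen to sit well between the ratio of a dead channel (≈1) and of any
  weakly driven channel (≥2 under the default generator).

Training pairs use the middle 3 s of each trial (60 frames). Scalar user
effort is the mean WFL over the controller's channel subset divided by a
normalizer — by default the 95th percentile of movement-window mean WFL,
so peak efforts map near 1 — and clipped to [0,1]; the label is effort ×
posture vector. Frames pool over trials and split 70/15/15, frame-wise
i.i.d. under a fixed seed (a trial-wise split is available for
leakage-aware evaluation; frame-wise matches common toolbox defaults).

Channel subsets mirror the anatomical table: 16 recorded channels; the
14-channel subset drops the two noise-only FDS channels; the 10-channel
subset additionally keeps only one channel per multi-channel muscle
(drops one FDS and three EDC); the 8-channel subset additionally drops
FPL and ECRB.

DOF sign convention (fixed, arbitrary): +1 = supination, wrist extension,
thumb abduction/extension, finger extension.

## ANN controller

The regressor has one hidden layer with the same number of tanh units as
inputs, linear outputs, MSE loss, Adam (learning rate 10⁻³), inputs
z-scored with training-split statistics. Training runs full-batch epochs
with early stopping on the validation split (patience 10 epochs,
best-validation weights restored, cap 200 epochs) and reports per-DOF R²
on the test split (NaN with a warning for constant targets). Optimizer,
activation and epoch budget are not documented in the source protocol;
these are this package's defaults. Training is deterministic given the
seed.

The controller maps a WFL frame to joint velocity per DOF: zero inside a
deadzone |raw| < θ (default θ = 0.1), otherwise g·raw (default g = 1.0
normalized range/s per unit effort), updated every 50 ms; joint angles
integrate with clamping to [−1,1]. The participant-tuned gains and
thresholds are unpublished; both are parameters here.

## Posture-matching task

Targets are uniform over [−1,1]⁴, rejecting candidates already satisfied
at the start state; 80 targets per session, regenerated per session
(whether the original task reused targets across sessions is not stated).
Success requires all four joints within 15% *of each DOF's full range*
(0.15 × 2.0 = 0.3 normalized units) of the target for 20 consecutive
frames (1 s) within 30 s. A per-angle percentage of the target value
would be undefined at target 0, hence the range reading.

Time-to-target is the entry time of the successful hold window.
Path efficiency is ‖end − start‖₂ divided by the summed segment lengths
of the trajectory up to the hold entry; unmatched trials contribute no
metric, which biases low-match controllers' efficiency upward (their hard
trials are excluded) — visible in the worked example, where the 8-channel
controller's efficiency is computed only over its easy matched trials.

Summaries average within target posture across sessions first (matched
trials only), then report mean ± SE across postures. Match percentage is
matched/total over all sessions.

## Group statistics

Match percentages: two-sided Fisher's exact test (probability-mass rule —
the sum of hypergeometric probabilities no larger than the observed
table's; definitions of "two-sided" differ between toolboxes, so this is
stated explicitly). Time-to-target and path efficiency: one-way ANOVA
over per-posture session-averaged means with Tukey HSD pairwise
adjustment, α = 0.05, unbalanced groups accepted (postures unmatched
under a controller simply drop out of that controller's group). Summaries
are mean ± SE.

## Synthetic-data generators

The generators define the study conditions under which the pipeline is
exercised; they are statistical stand-ins, not biophysical models.

**Percepts.** Each nerve has a 1-D somatotopic anchor polyline on the
template (median → thumb/index/middle palmar, ulnar → ring/little and
hypothenar, radial → dorsum); a contact's position along its electrode
maps to arc-length along that polyline. Per session a contact evokes a
hand percept with probability 1 − p_no_percept (per nerve; the radial
cuff mostly evokes residual-limb percepts, modeled as a high
no-hand-percept probability), as an elliptical blob with log-normal area
(median `area_fraction_mean`), per-contact fixed aspect ratio and
orientation (so zero-jitter sessions are identical), and Gaussian
session-to-session center jitter (default 0.02 panel units). The blob is
rescaled by bisection so its hand-clipped pixel area matches the sampled
area even at the silhouette boundary; geometry is defined in normalized
coordinates, making coverage resolution-stable (tested at 128² vs 512²
panels). Two factory models set the study conditions: sparse
(16 contacts: 8 median + 8 ulnar, median area 3% of hand) and dense
(60 contacts: 2×15 median + 15 ulnar + 15 radial, median area 8%,
~75–90% of contacts evoking hand percepts). Blob shape is a modeling
choice — nothing is known about real percept shapes beyond areas and
categories.

**EMG.** Raw EMG is amplitude-modulated white noise: the WFL of
amplitude-a white noise is (2/√π)·a in expectation, so WFL rises linearly
with drive by construction, with none of the spectral structure of real
EMG. Channel drive is a rectified synergy map — two non-negative
(channels × 4) matrices for the positive and negative direction of each
DOF — plus nearest-neighbour crosstalk (5%) and a noise floor (0.05);
dead channels (defaults: the two excluded FDS channels, indices 5 and 7)
emit floor noise only. The default layout assigns each muscle its broad
functional role, with one stylization: ECRB carries the dominant
thumb-extension drive (plus a secondary wrist-extension role) so that the
8-channel subset — which drops FPL and ECRB — loses both thumb
directions. This reproduces mechanistically the observed pattern that
removing those two inputs degrades 4-DOF control. Per-trial effort ramps
0→1 over the movement window; repetition variability is a log-normal
per-channel gain wobble (σ = 0.1).

**Closed-loop user.** Intended effort is clip(k_p·(target − state), −1, 1)
with k_p = 2, pushed through the same synergy forward model with
multiplicative log-normal WFL noise (σ = 0.1). This closes the loop
without modeling human learning, reaction time, or fatigue — so absolute
task outcomes are near-ceiling for any controller whose DOFs are
decodable, and only contrasts between controllers are meaningful. Passing
tests show the pipeline recovers the direction of channel-count effects
under these conditions; they do not certify effect sizes on real data.

**Threshold search.** The observer detects a stimulus iff charge
(amplitude × pulse width) reaches its threshold. The search raises
amplitude in fixed steps (0.1 mA default) at maximum pulse width until
detection (no detection at maximum amplitude → "no percept"), then
bisects pulse width — up halfway on a miss, down halfway on a hit — until
the bracket is within the resolution (5 or 10 μs), returning the lowest
detected pulse width, provably within one resolution of the observer's
true minimum.

## Problem sizes and numerical choices

Tests and the acceptance script run at the protocol's native sizes where
those are cheap (32 postures × 10 reps; 80 targets per session; 2/3/3
sessions per controller; 0.01-step cutoff grid) and use 1–10 seeds for
trend checks (10 seeds for the channel-count trend, 5 for the electrode
density trend) — sizes chosen so the full suite runs in minutes on one
CPU. Mask comparisons use exact pixel counts; dissimilarity matrices are
validated (symmetry, zero diagonal, finiteness) on construction; merge
heights use a 10⁻¹² tolerance for the non-decreasing invariant;
degenerate cases (empty mask pairs, constant regression targets,
single-session SE, zero-net-displacement trajectories) raise or warn
explicitly rather than returning silent NaNs.

## Known limitations

* Elliptical blobs and a 1-D somatotopic map cannot produce multi-lobed
  or discontiguous percepts; real drawings can be both.
* The synthetic user's proportional policy makes absolute closed-loop
  metrics optimistic by an order of magnitude relative to human
  operation.
* The white-noise EMG model has a flat spectrum; features other than WFL
  (e.g. zero crossings, AR coefficients) would not behave realistically.
* Statistical comparisons assume independent per-posture means, as the
  originating analyses did; no repeated-measures structure is modeled.
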