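# Methods

`gaitstage` implements a complete pipeline for detecting Parkinsonian gait
and grading it on the Hoehn–Yahr (H-Y) scale from marker-based gait
analysis.  This note records the models, the tunable parameters, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## The feature space

Eighteen per-subject gait features are used throughout: nine spatio-temporal
parameters — walking speed (m/s), cadence (steps/s), stance/swing and first/
second double-support durations (% of the gait cycle), step length, step
width and stride length (normalized to limb length) — and nine ranges of
motion (RoMs, degrees): hip, knee and ankle in the sagittal plane, and
trunk and pelvis in the frontal (lateral bending / obliquity), sagittal
(flexion-extension / tilt) and transverse (rotation) planes.  Published
population values report gait speed in km/h; the pipeline standardizes on
m/s everywhere (conversion /3.6 at the generator boundary).

Two feature conventions in the published population table are known
oddities and are carried as-is: a pelvis-tilt spread far larger than any
plausible cyclic RoM (we implement pelvis tilt as the RoM of the tilt curve
and do not attempt to match that row), and a cadence near 0.9 "step/s"
that is more typical of stride rates (we implement cadence as steps per
second: two steps per stride).

## Kinematics

* **Events.**  Heel strike and toe-off are the maxima and minima of the
  *limb angle* — the sagittal-plane angle between the vertical through the
  greater trochanter and the trochanter→lateral-malleolus vector (0° with
  the malleolus under the trochanter, positive in front).  Marker
  trajectories are low-pass filtered with a zero-phase Butterworth
  (effective 4th order, 6 Hz cutoff — the standard choice in clinical gait
  analysis) before peak picking; strict heel-strike/toe-off alternation is
  enforced by keeping the more extreme of two consecutive same-type
  extrema, and flat extrema resolve to the first frame of the plateau.
* **Cycles.**  A gait cycle runs between successive heel strikes of the
  same leg; angle curves are time-normalized to 101 samples with a
  piecewise-cubic spline.
* **Time-distance parameters.**  Speed from the sacrum's progression over a
  cycle; cadence as steps/s; step and stride geometry from malleolus
  positions at the respective heel strikes, normalized to limb length
  (defined here as the mean trochanter-to-malleolus distance over the
  trial); phase durations from the bilateral event interleaving.
* **Segment frames.**  Simplified frames replace a full anthropometric
  calibration protocol: pelvis from the ASIS pair and sacrum, trunk from C7
  and the acromia expressed relative to the pelvis, thigh/shank/foot from
  their marker pairs.  Orientations are decomposed intrinsically Z-X-Y
  (rotation, frontal angle, sagittal angle), which is exact for the small
  trunk/pelvis excursions of gait and matches the generator's composition.

## The classifier protocol

Feedforward networks with tanh hidden units and linear outputs map the
z-scored features to one-hot class codes (2 classes for diagnosis, 4 for
staging; decoding by arg-max with ties to the lowest class).  Six
architectures form the topology grid: 1–3 hidden layers crossed with first
layer widths of 20 or 50 neurons, deeper layers 1/2 and 1/3 of the first
(floored: 50 → 25 → 16, 20 → 10 → 6).

Training is Levenberg–Marquardt on the full residual Jacobian (computed
analytically and verified against central finite differences): a step
solving the damped normal equations is accepted when the training MSE
drops, dividing the damping by 10, otherwise the damping is multiplied by
10 and the step retried up to a cap of 1e10.  When the residual count is
below the parameter count the dual (Woodbury) form of the normal equations
is solved instead, which keeps large-width topologies cheap.  Training
stops at 1000 iterations, a training MSE of 1e-6, or six consecutive
validation failures — a failure being an accepted iteration whose
validation MSE exceeds its running minimum — and the weights at the
validation minimum are returned.  MSE on one-hot targets (not
cross-entropy) is deliberate: the stopping criteria are defined on it.
Weight initialization is uniform in ±1/√fan-in and fully seed-determined.

Each topology is trained `reps` times (default 10) on fresh 80/10/10
train/validation/test splits.  Splits are *stratified* by class even though
the protocol's description says only "random 10%": with only 12 subjects in
the smallest stage group, unstratified splits frequently produce test sets
missing a class, leaving per-class metrics undefined.  The per-repetition
test confusion matrices are row-normalized to percentages and averaged;
the performance statistic P is the mean of the diagonal of that mean
matrix (100 = no misclassification).  Percentage averaging (rather than
count pooling) is used because P is defined on the mean matrix; with
equal-size stratified test splits the two commute (tested).  Per-class
sensitivity and specificity are one-vs-rest; their "mean" columns are
unweighted macro averages.  Topology effects are assessed with a two-way
fixed-effects ANOVA with hidden-layer count and first-layer width as
factors (interaction included when every cell has ≥ 2 repetitions,
reported separately), with Bonferroni-corrected pairwise post-hocs.

## Feature pooling and subset search

PCA on z-scored features retains the smallest number of components whose
cumulative explained variance reaches 98%; for each retained component (in
variance order) the original feature with the largest absolute loading is
selected, skipping duplicates.  Z-scoring is a design choice the source
description leaves open; without it the degree-valued RoMs would dominate
the phase-percentage and metre-valued features.  For staging, walking
speed is force-included in the pool.

The minimal-subset search is exhaustive: all feature combinations of size
2, then 3, and so on, each run through the full repeated-training protocol,
stopping at the first size containing at least one *equivalent* subset.
Equivalence is a two-part rule: a two-sided Welch t-test between the
subset's and the full pool's per-repetition P values must be
non-significant at `alpha` (default 0.05), **and** the subset's mean P must
be within a non-inferiority margin (default 2 percentage points) below the
full pool's.  The margin exists because a bare non-significant t-test would
accept underpowered garbage.  `alpha <= 0` is a sentinel that disables
equivalence entirely, so the search enumerates every size and falls back to
the full pool.  No multiplicity correction is applied across combinations,
as none is part of the protocol being reproduced.  Every combination
derives its protocol seed from the master seed plus a CRC32 hash of its
feature names, so enlarging the pool never changes another combination's
results.

## Cumulative-index diagnostics

For a chosen feature set the *cumulative index* is the plain arithmetic sum
of the raw feature values (mixed units summed deliberately).  Disease or
the worse stage is called at **low** index values (`index ≤ cutoff`),
matching the direction of all published cutoffs.  The empirical ROC scans
midpoints between sorted unique index values; AUC is trapezoidal (and
equals the Mann–Whitney U statistic divided by n₁n₂, a tested identity).
The optimal cutoff maximizes Se + Sp (Youden), ties broken toward higher
sensitivity.  Likelihood ratios are LR+ = Se/(1−Sp), LR− = (1−Se)/Sp, with
division by zero flagged as +∞.  Post-test probabilities follow the Fagan
nomogram: post-odds = pretest-odds × LR.  The pretest probability is the
group-size prevalence within each pairwise comparison — the only choice
that reproduces every published post-test probability from the printed
sensitivities and specificities.  Report rounding follows the published
table: LRs to 2 decimals, probabilities to whole percent.

Group-difference confirmation uses Shapiro–Wilk (α = 0.05) to gate an
unpaired t-test (both groups normal) versus a two-tailed Mann–Whitney
test; three or more groups use one-way ANOVA with Bonferroni post-hocs.

## The synthetic cohort generator

No participant data accompany the study this pipeline reproduces, so a
generator supplies cohorts with known ground truth.

* **Feature cohorts** are drawn group-wise from multivariate normals with
  the published healthy and pooled-patient means and SDs.  The publication
  reports no per-stage feature values, so stage means are a documented
  linear ramp applied to speed and the nine RoMs: stage 1 sits at the
  midpoint of the healthy and pooled-patient means, stage 4 at the pooled
  mean minus one pooled SD, stages 2–3 interpolated.  This matches the
  qualitative monotone decline across stages without inventing per-stage
  numbers as ground truth; all other features sit at the pooled-patient
  mean for every stage.  The true inter-feature correlation is unreported;
  the default is exchangeable ρ = 0.3 among the RoMs and 0 elsewhere — a
  stand-in.  Phase-percentage features are clipped to [0, 100] (plain
  clipping, not truncated sampling; it affects only those features).
  Default group sizes are the study's: 67 controls and 20/17/27/12
  patients across stages 1–4.
* **Marker walks** come from a planar-dominant forward-kinematic chain:
  the pelvis advances at the prescribed speed carrying ASIS/sacrum and
  trunk marker clusters driven by prescribed small-angle rotation
  waveforms, while each leg's thigh/shank/foot angles follow periodic
  Fourier waveforms (the thigh angle is solved so the trochanter→malleolus
  angle equals the prescribed limb-angle waveform exactly, making
  ground-truth events exact).  The right leg is half a stride out of
  phase.  Sampling is 340 Hz; marker noise is additive isotropic Gaussian,
  default SD 1 mm (a typical optoelectronic noise floor).  The default
  limb-angle waveform's second harmonic sets stance at ≈ 60% of the cycle.

**What the generator does not emulate:** the strong inter-feature
correlation structure of real gait (real cohorts compress into ~9 PCA
features at 98% variance; the weakly correlated synthetic cohort does
not), freezing of gait, tremor, stride-to-stride variability structure,
ground-reaction forces, and any physiological coupling between speed and
RoMs beyond the stage ramp.  Passing tests therefore demonstrate the
correctness of the machinery — event detection, training, selection,
diagnostics — not clinical performance on real cohorts, whose published
accuracy ranges are not reproduction targets.

## Problem sizes used in the shipped checks

The repeated protocol defaults to 10 repetitions per topology; the shipped
verification runs and the acceptance script use 3 repetitions per topology
and planted cohorts of 60 subjects per group, which the equivalence
statistics and chance-level calibrations tolerate comfortably.  Large-n
distributional checks use 4000–8000 subjects per group.

## Known limitations

* The limb-angle event definition assumes sagittal-plane walking along the
  lab's x axis; files with other conventions are remapped at read time.
* LR confidence intervals and AUC uncertainty are out of scope (not part
  of the reproduced analysis).
* The subset search is exhaustive by design; pools beyond ~12 features
  exceed the default combinatorial budget and raise an error suggesting
  pool reduction.
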