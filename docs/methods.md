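# Methods

`toolkin` re-implements, as a tested pipeline, the kinematic analysis of a
TMS "virtual lesion" experiment on novel tool use: healthy participants,
stimulated over the left anterior supramarginal gyrus (aSMG) or the ventral
precentral gyrus (vPreCG) with a verum or sham coil while planning the
movement, reach for an unfamiliar tool, bring it to a cylinder, and lift the
cylinder out of its socket. A single marker at the base of the left index
finger is tracked at 100 Hz. The analysis asks whether the movement's
kinematic fingerprint carries information about the stimulation received.

## Preprocessing

Raw marker positions may contain occlusion dropouts. Gaps are filled per
coordinate with a cubic polynomial fitted by least squares to the 4 valid
samples on each side; gaps longer than 0.5 s (configurable) or touching the
first/last frame invalidate the trial, which is excluded with a logged
reason. Speed is the Euclidean forward difference times the sample rate,
assigned to the leading sample with the last value replicated — this keeps
the series length and makes `sum(v_raw) * dt` equal the polyline pathlength
exactly. The speed series is smoothed with a 0.42-s loess filter: a local
*quadratic* regression with tricube weights over the `round(0.42 * rate)`
nearest samples (degree 2 and full-width reading are the package's choices;
degree-2 loess is a common default and reproduces quadratic series exactly,
which the tests verify). Negative fitted values clip to zero.

## Phases and parameters

Annotated event times (from video, or from the simulator's ground truth)
split each trial into Go Cue `[signal, movement-onset)`, Reaching
`[movement-onset, tool-grasped)`, Preparing `[grasped, cylinder-contact)`
and Using `[cylinder-contact, lift]`. Boundaries snap to the nearest sample
(ties toward the earlier one); half-open intervals realize the "one frame
before" convention, and the short finger-contact-to-secure-grasp interval is
assigned to Reaching so every frame belongs to exactly one phase.

Per phase the package computes phase duration (PD, s), maximum smoothed
velocity (MV, m/s) with its relative peak time (TVP, % of phase duration,
earliest argmax on ties), 3D pathlength from the unsmoothed positions (PL,
m), velocity peaks per meter (NP; topographic prominence >= 0.05 m/s,
evaluated within the phase window), and relative activity (RA, % of samples
with smoothed speed strictly above 0.05 m/s). Five PDs (four phases plus
signal-to-lift total), three MV/TVP/PL (movement phases) and four NP/RA
(movement phases plus total) give the 22-parameter feature vector. PL uses
raw (gap-interpolated) positions so pathlength and speed-profile metrics are
not coupled through the smoother.

## Performance scoring and score ANOVAs

Tool selection scores 1 when the proper tool is taken (at most one
self-correction) or when the goal — the cylinder lifted out of its socket —
is achieved despite a wrong tool; otherwise 0. Production scores 3/2/1/0 for
complete execution / tool moved to the cylinder without attachment / tool
grasped only / nothing, resolved top-down. Unweighted Cohen's kappa with the
large-sample standard error quantifies inter-rater agreement.

Scores are averaged per participant and (stimulation type x binarized
timepoint) cell and analysed with a three-factor mixed ANOVA: site between
participants, type and timepoint within. Because every factor has two
levels, each effect is a participant-level contrast regressed on the
effect-coded site factor (Type III), yielding the classical
`F(1, n_participants - 2)` tests with partial eta squared. Participants
missing a cell are excluded listwise with a warning.

## Classification of stimulation type and site

Pulse-onset latency (uniform 0.1-0.3 s by design) is binarized at its
empirical median, computed once over the analysis set — never hard-coded.
Every kinematic parameter is z-scored within the analysis set and enters the
candidate design three ways: a main column and two per-timepoint slope
columns (`feature:early`, `feature:late`). This non-marginal coding is
deliberate: the scientific question is whether a feature predicts
stimulation *within* early- and *within* late-stimulated trials, possibly
with opposite signs, so both slopes must be estimable in one final model.
Selection and production scores and a late-timepoint indicator complete the
69 candidates.

Backward selection is deterministic and two-phase: first the highest-VIF
column is dropped while any VIF >= 5 (VIFs from the inverse correlation
matrix, equivalent to the classical auxiliary regressions; exact
dependencies — a main column equal to the sum of its slope columns, or a
total duration equal to the sum of its parts — are resolved by dropping the
column loading most on the correlation matrix's null space); then the
logistic model is refit and the highest-p term dropped while any Wald
p >= 0.10. Separated (non-converging) fits drop the column with the largest
ridge-stabilized coefficient, logged in the trace. Reported per term:
coefficient, SE, p, odds ratio (sham and early are reference categories) and
final VIF; per model: in-sample ROC/AUC with a DeLong 95% CI and the Youden
threshold, and a likelihood-ratio test against the intercept-only null with
df equal to the number of retained terms.

A sham-only model discriminating the two sites gates the analysis: when its
AUC confidence interval excludes 0.5, stimulation-type classification runs
per site (as in the study); otherwise pooled. Trial-level fits ignore the
participant clustering, matching the original analysis; this is a known
statistical limitation.

## Synthetic trials

No raw motion data are deposited, so a generator produces study-shaped
datasets: by default 37 participants alternating between sites, 14
tool-cylinder combinations per stimulation type in two counterbalanced runs,
pulse onsets uniform on 100-300 ms. Each trial is an analytic curve: a
Go-Cue dwell (mean 0.55 s, SD 0.22 s) with tapered sinusoidal jitter kept
below the 0.05 m/s activity threshold, then three minimum-jerk segments —
reach (~0.40 m, ~0.75 s), transport/prepare (~0.32 m, ~0.80 s, peak speed
~0.78 m/s) and attach/lift (~0.18 m, ~0.70 s) — sampled at 100 Hz with
0.15 mm Gaussian position noise and rare frame dropouts. Segment means and
dispersions follow the condition marginals reported for this task (reaching
pathlength 0.40 +/- 0.06 m, preparing MV 0.75 +/- 0.15 m/s, preparing and
using peak times near 51% and 33% of phase duration).

Real movements are not exact minimum-jerk curves, and a pure minimum-jerk
world would make MV a deterministic function of amplitude and duration
(MV = 1.875 A/T), collapsing the feature space. Three time-warps therefore
carry independent shape variance, each preserving the segment's endpoints,
duration and travelled distance:

- a power-law warp (gamma) moves the velocity peak earlier or later;
- a symmetric sharpening/flattening warp (lambda) changes the bell's width;
- an interior "boost" confined to the high-speed mid-profile scales the
  peak (kappa) without touching the sub-threshold tails, so maximum
  velocity varies independently of pathlength, duration and activity.

Corrective submovements (a small there-and-back displacement bump late in
the reach or use segment, 20% of segments) add secondary velocity peaks so
that peaks-per-meter is not just 1/PL. With all stochastic elements
disabled the trial is exactly analytic, and a dense reference evaluator
recomputes every feature from the continuous curve (independent
implementation: dense grid, direct weighted polynomial fits, brute-force
prominence) together with one-sample discretization tolerances — the oracle
for the end-to-end feature tests.

### Effect injection

Condition effects are injected by warping the *generating* parameters of
trials matching a (site, type, timepoint) selector, never by editing
computed features. Shifts are specified in SD units and converted with a
frozen table of the generator's own feature SDs, so "+1 SD" moves the
measured feature by about one pooled SD. Each feature family has an
orthogonalized mechanism: durations shift PD; amplitudes shift PL; a
plateau-translation warp (unit time rate across the peak, compression pushed
into the low-speed flanks) slides TVP; and the interior boost scales MV.
Because the 0.42-s smoother attenuates sharp peaks, drags asymmetric ones
toward mid-phase and mixes in neighbouring segments, the TVP and MV warp
targets are solved numerically against the *smoothed, in-context* profile
(bounded secant with a grid fallback), with a second sweep so adjacent
injections do not dilute each other. Peak-speed reductions saturate when
the flattened peak meets its shoulders; the solver then refuses boosts
that would split the profile into artificial double peaks, delivers a
bounded remainder by stretching the segment slightly (peak speed scales as
1/duration at fixed shape), and only then falls back to global flattening.
Extreme targets are still delivered partially: the realized shifts are
about 0.8-1.0 of the nominal SD, and small co-shifts of mechanically
related parameters remain (an earlier velocity peak, for instance, slightly
raises the measured maximum) — as they would in real movements. Per-trial ground truth records the segments,
boundaries, labels and applied shifts.

What the generator does **not** emulate: participant-level idiosyncrasies
(trials are exchangeable within condition), grip aperture or rotation (one
marker), task failures' kinematic signatures (scores are drawn from
study-like marginals independently of the trajectory), and any genuine
neural effect of stimulation. Passing tests therefore show that the
pipeline recovers what the generator encodes under realistic sampling,
noise and collinearity — not that the published biological effects are
reproducible.

## Numerical choices and problem sizes

Tolerances: event snapping ties go to the earlier sample; TVP ties to the
earliest maximum; zero pathlength yields NP = 0 with a warning; zero-variance
predictors are dropped before modeling; logistic fits run Newton with a BFGS
fallback and 50/200 iteration caps. Monte-Carlo checks use 200 effect-free
and 100 effect-carrying study replicates of ~500 trials (18 participants x
28 trials), sized so the full suite completes on a single CPU in well under
half an hour; the ANOVA calibration uses 500 replicates of a 20-participant
design.

## Known limitations

- In-sample AUC and LRT of a backward-selected model are optimistic: with
  ~45 candidate terms kept at p < 0.10, about alpha x 45 noise terms survive
  under the null, so the null distribution of the final-model AUC centers
  near 0.64 (not 0.5) and the post-selection LRT rejects far above the
  nominal rate. The package reports these quantities as the original
  analysis defines them; they should be read as in-sample descriptions of
  the selected model, not calibrated tests. The same optimism makes the
  sham-only site check branch per site in most replicates even without true
  site differences.
- Trial-level logistic models ignore participant clustering.
- The generator's nominal effect-SD table is calibrated to its own default
  presets; injections under heavily modified presets shift by a different
  number of pooled SDs.
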