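# Methods

This note documents the models, numerical choices and known limitations of
`seqreach`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task geometry

The task is an 8-movement sequence through a central via target: waypoints
`via–1–via–3–via–2–via–4–via` (9 waypoints, 8 movements, 7 transitions).
Targets 1 and 4 sit 10 cm from the via on the y-axis; targets 2 and 3 sit
at a 5-cm radius with a 126° angular split, placed symmetric about the +y
axis.  The coordinate frame (origin at the via, +y toward target 1, cm
units) is a package convention — only displacements are physically
meaningful, and every downstream metric is invariant under rigid motion of
the frame (tested).  The orientation of targets 2/3 (upper vs lower
half-plane) is not fixed by the task description and is configurable
(`mirror=`).

Radii: targets are 1 cm in diameter (`target_radius = 0.5`); segmentation
and transition windows use the 2-cm proximity radius.

## Velocity processing and segmentation

- Derivative: `numpy.gradient` central differences on the (possibly
  slightly nonuniform) timestamps, one-sided at the ends.  Speed is the
  tangential magnitude; the scalar speed is what the per-segment extrema
  operate on.
- Smoothing: Gaussian kernel with σ = 2 **samples** (the convention of
  fixed-rate motion-capture pipelines at 110 Hz), truncated at 4σ,
  reflected boundaries, applied to the speed series.  Constant-velocity
  motion is invariant under this smoothing (tested).
- Segmentation tie-break: segment k ends at the *first* sample strictly
  within 2 cm of waypoint k after segment k−1's end.  Transition window
  k is the maximal contiguous run of samples within 2 cm of intermediate
  waypoint k containing that boundary.  The minimum-speed search uses the
  2-cm window throughout; the 1-cm target disc is an alternative reading
  we did not adopt (the segmentation rule itself is defined at 2 cm, and
  a consistent radius keeps the transition window nonempty at all fusion
  levels).
- MT starts at start-box exit, defined as the first sample farther than
  2 cm from the trial's start position — the same threshold that ends the
  reaction-time window; the task description does not restate a separate
  MT start threshold, so one threshold serves both.
- Incomplete trials (a waypoint never approached within 2 cm) raise a
  diagnostic naming the missing waypoint and are excluded from all
  downstream metrics, mirroring the task's abort-and-repeat rule.

## Fusion index and spatial reorganization

FI per transition is `vmin / m` with `m` the mean of the adjacent peaks,
clamped to [0, 1] with a warning when noise pushes `vmin` above `m` (the
0–1 range is asserted by the measure's definition; clamping is the
package's handling choice).  The trial score sums 7 transitions.

RD% uses the **via point** as the reference: every included reach
(segments 2–7; the first and last are excluded) has the via at one end,
and fusion drags the speed peak toward it.  `RD% = 100·(1 − d/L)` with
`d` the centroid-to-via distance and `L` the reach's straight-line
length.  This normalization reproduces both definitional anchors: 100% at
zero distance, and 45–55% when each reach is executed individually with
its bell-shaped peak near mid-path.  The peak-location search skips
samples still inside the *start* waypoint's 2-cm region (the incoming
tail and dwell of the previous transition), so the location reflects the
reach proper.  The confidence ellipse is the principal-component ellipse
with axes scaled by √χ²₂(0.95); its centroid is the sample mean, which
coincides with the intersection of the ellipse axes under this
construction.  A degenerate scatter (identical points) yields zero axes
and a valid centroid.  The sliding window covers 10 trials with stride 1.

The FI–RD relation is summarized by a continuous two-segment linear fit
with three knots: outer knots at the data range, the interior breakpoint
found by a quantile grid search refined with bounded scalar minimization;
for a fixed knot the fit is ordinary least squares on {1, x, (x−knot)₊},
so the two-segment SSE never exceeds the single-line SSE.

### Expected shape of the FI–RD relation

RD% identifies the *final* stages of fusion: per-segment peak locations
stay near mid-reach (≈50%) until the transition speeds grow large enough
that the within-segment argmax jumps toward the via, after which RD%
rises steeply.  On the synthetic fusion grid the association of RD% with
generative fusion is therefore curvilinear — flat to slightly declining
at low fusion (the mid-reach peak moves marginally *outward* as the path
bows around the via with growing transverse velocity), then sharply
rising — while FI, model MSE and SPARC vary monotonically over the whole
grid.  The acceptance suite asserts global monotone rank correlations for
all four measures; the RD% assertion documents this structural
curvilinearity by failing at low-fusion levels, and a dedicated test
verifies the positive FI–RD association above drift onset.

## Minimum-jerk model

The reference trajectory minimizes `½∫(|x⃛|²+|y⃛|²) dt` subject to passing
through each via point, starting and ending at rest.  For fixed passage
times the optimum is an exact piecewise quintic per axis with position
prescribed and derivatives 1–4 continuous at each via (the first-order
optimality conditions); this is a square linear system solved directly.
Passage times are free parameters optimized by Nelder–Mead over a
softmax parameterization of segment durations (always positive, summing
to the total), initialized from chord-length-proportional times, with
relative function tolerance 1e-8.  The jerk cost integrates the squared
third-derivative polynomials in closed form.

Passage times are optimized rather than taken from data because the model
receives only the waypoints and the total movement time.  Two exact
scaling laws — cost ∝ L² under spatial dilation and ∝ T⁻⁵ under time
dilation — are used throughout: the optimal *relative* passage times are
duration-invariant, so the fused-pass optimization runs once per geometry
and is rescaled exactly per trial.  Degenerate problems (coincident
consecutive waypoints) are rejected.

Model MSE: both profiles are mapped to normalized time [0, 1], scaled to
unit peak amplitude (unit-integral normalization would be an
alternative; unit peak is the package default) and linearly interpolated
to N = 500 points before averaging squared differences.  Profiles are
cropped to the movement window (0.5-cm position thresholds at both ends)
first, so holds do not dilute the comparison.  Because the normalized
minimum-jerk speed shape is duration-invariant, one reference profile
serves every trial.

SPARC: magnitude FFT of the speed profile zero-padded to
2^(⌈log₂ n⌉+4), normalized by its maximum, restricted to ≤ 20 Hz and then
to the adaptive band where the normalized amplitude stays ≥ 0.05; the
score is the negative arc length over band-normalized frequency.  These
are the established defaults of the published measure; the score is
sampling-rate invariant for a fixed movement (tested at 110 vs 220 Hz).

## Synthetic data generator

The generator emulates the study conditions; its defaults are fixed once:

| parameter | default | rationale |
|---|---|---|
| sampling rate | 110 Hz | tracker rate of the task |
| movement time | 5.0 s | early-training group means |
| MT trend | 5.0 − 0.002·trial, participant SD 0.3 s, trial SD 0.2 s, floor 2.0 s | magnitude of reported learning curves |
| fusion trend | 0.1 + 0.0015·trial (clamped to [0,1]) | FI growth from ~0.7 to ~2.8 (sum) over 200 trials |
| dwell | 0.15 s | full-stop duration at zero fusion |
| position noise | 0.05 cm (isotropic Gaussian) | mm-scale tracker noise |
| corrected-trial probability | 0.087 | reported exclusion fraction |

Construction: at fusion 0 each reach is a rest-to-rest minimum-jerk
quintic with a dwell at every transition; at fusion 1 the trial is the
single optimized via-point pass; intermediate levels scale the dwell by
(1−f) and prescribe boundary velocity *and acceleration* at each
transition as f times the fused pass's values — since a quintic is fully
determined by its endpoint position/velocity/acceleration, f = 1
reproduces the fused pass segment by segment and the interpolation is
continuous in f.  The velocity discontinuity between a nonzero-speed via
passage and a zero-speed dwell at intermediate f is an accepted
idealization; sampling and smoothing blur it into a graded dip, which is
what makes measured FI increase smoothly with f.

The configured movement time refers to the *measured* MT (2-cm start-box
exit to 2-cm final entry).  Because every moving phase is time-scalable,
one rescaling pass after measuring the first draft matches the target
exactly (round-trip error below two sample periods, tested).

Corrected trials miss one outer target laterally — 2.8 cm from the
center, 85° off the reach direction, far enough that the first pass stays
outside the 2-cm region for both 5- and 10-cm reaches — pause 0.08 s, and
re-acquire the target with a corrective reach whose heading opposes the
approach.  The detector looks for a distance local minimum between 2.2
and 4 cm (in open space: candidates within 2.5 cm of *another* waypoint
are rejected, since hovering near a neighbouring target mimics a missed
pass under noise) followed by re-entry within the 0.5-cm target radius
with reversed heading.  On the generator it detects essentially all
injected corrections with no false positives at the default noise level
(tested against binomial bounds).

What the generator does **not** emulate: biomechanics (no arm model,
stiffness or signal-dependent noise), reaction-time cognition, trial-to-
trial motor variability beyond additive position noise, drift or sensor
dropout, and genuinely merged single-peak fused movements (the fused pass
retains distinct per-reach peaks with fast via passages).  Passing tests
therefore show the *measurement stack* is correct against known ground
truth, not that real behavior follows minimum-jerk interpolation.

## Reward schedule

Percentile = 100 × (fraction of the 20 reference MTs strictly slower than
the current trial); the current trial is ranked *against* the window, not
inserted into it (both readings reproduce the printed cut points at the
boundaries tested).  Ties count against the current trial; MTs are
continuous so exact ties are measure-zero in practice.  Payouts:
≥90 → 5p, [80,90) → 4p, [60,80) → 3p, [40,60) → 2p, [20,40) → 1p,
<20 → 0p.  The session replayer rolls the window forward one trial at a
time, seeded by the previous block's last 20 trials.

## Bootstrap inference

Each draw resamples participants with replacement to the original group
size, averages across participants per trial (NaN-aware, so excluded
trials are ignored in trial-wise means) and refits the family; 2.5/97.5
percentiles of 1,000 draws give CIs.  exp1 and power1 are initialized in
log space and refined by nonlinear least squares; a diverging draw is
retried from a jittered start, and more than 5% failures is an error.
Family comparison fits all families to the *same* draws.  Group contrasts
difference the draws pairwise; the difference-CI excluding zero is the
primary decision rule (strictly more powerful than requiring per-group
CIs not to overlap, which is also reported).  The intercept `p2` is the
fitted value at trial 0, reported as-is.

Percentile bootstrap CIs with 15 participants undercover slightly
(≈92–93% rather than 95% in the package's own coverage simulation); the
acceptance suite checks coverage within [90%, 99%] over 300 replicate
groups at 200 draws each.

## Problem sizes and determinism

The test suite exercises the pipeline at reduced sizes (2–6 participants,
12–60 trials, 40–500 bootstrap draws) and the coverage check at 300
replicates × 200 draws; these sizes were chosen to keep the suite fast
while leaving every statistical check well-powered.  The pipeline default
(15 participants × 200 trials, 1,000 draws) runs in well under a minute.
A single seeded `numpy` Generator threads through all stochastic steps;
reruns with the same config produce byte-identical tables, and the output
manifest records the config hash, seed and exclusion counts.
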