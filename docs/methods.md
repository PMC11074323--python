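# Methods

`dynseg` implements a dynamic functional-connectivity analysis of
feedback-driven learning: region-level BOLD time series are reduced to
windowed connectivity matrices, summarized as brain-state and modularity
trajectories, and related across subjects to drift-diffusion measures of
learning. A synthetic-cohort generator with known ground truth makes every
stage testable end to end.

## Preprocessing model

Task-evoked activity is removed with a GLM whose task regressors are 14
sine waves, `sin(pi * j * tau / 30)` for harmonics `j = 1..14` evaluated at
post-onset lag `tau` in `[0, 30)` seconds and summed over trial onsets.
Whether a mixed sine/cosine set would be preferable is an open choice; the
sine-only basis is the simplest reading of a "14 sine-wave regressors over
30 s" specification and the basis is configurable. Slow drifts are removed
by a discrete-cosine basis inside the same GLM (cutoff 128 s, the standard
high-pass convention for task fMRI), rather than by a separate filtering
pass, so that task and drift regressors are jointly orthogonalized against
the data. Arbitrary confound columns (motion parameters, tissue means,
their expansions, break regressors) can be appended; the regression is
agnostic to column meaning. Collinear columns are dropped by QR with
pivoting and logged.

Motion QC takes a frame-wise displacement (FD) trace as given (computing FD
from realignment parameters is volumetric preprocessing, out of scope) and
excludes a subject when FD > 0.2 mm in strictly more than 20% of scans.

## Windowed tapered connectivity

The scan axis is divided into exactly 20 windows, either non-overlapping
(window length `n_scans // 20`, remainder scans given one each to the
earliest windows — a deterministic, balanced rule) or half-overlapping
(length `2 * n_scans // 21`, step half a window, last window clamped).
Windows are always planned on the subject's own scan count, never a fixed
length shared across subjects.

Within a window of length `T`, scan `t` has weight

    w_t = w0 * exp((t - T) / theta),
    w0  = (1 - exp(-1/theta)) / (1 - exp(-T/theta)),  theta = T / 3,

a geometric series that sums to 1 exactly. Connectivity is the weighted
Pearson correlation of every node pair under these weights, with weighted
means `sum(w x) / sum(w)`, then Fisher z-transformed with `|r|` clipped at
`1 - 1e-7` (atanh diverges on degenerate pairs). Zero-variance nodes yield
flagged missing entries.

## Brain states

All subjects' windowed matrices (upper triangles, diagonal excluded) are
pooled and clustered with k-means under city-block distance, `k = 2`, 10
random restarts, best restart by total distance, ties to the lowest
restart index. Centroids are member means (the contract of the state
model), with the caveat that the city-block minimizer of a cluster is the
member median; with the well-separated states this package targets, the
mean-update iteration converges to an assignment fixed point, which is
asserted in tests. An empty cluster is re-seeded at the point farthest from
its centroid. A silhouette diagnostic over alternative k is provided but
not used in the main path.

Centroids are scored by system segregation,

    S = 1 - mean(between-network z) / mean(within-network z),

over the a-priori atlas (diagonal excluded); the higher-S centroid is
labelled *segregated*, the other *integrated*. Per-window prevalence is the
fraction of subjects assigned to each state; with two states the
frequencies sum to 1 by construction, and the pipeline asserts this.

## Signed modularity and cartography

Community detection runs per window on the signed weighted matrix with no
threshold. The quality function treats positive and negative weights
asymmetrically (positive-dominant):

    Q = Q+ / v+  -  Q- / (v+ + v-),

where `Q±` are Newman–Girvan modularity sums on the positive/negative
parts with resolution `gamma = 1` and `v±` the total positive/negative
weight. For purely positive matrices this reduces exactly to weighted
Newman–Girvan modularity (verified to 1e-12 in tests). Optimization is a
two-phase greedy Louvain on the dense modularity matrix with randomized
node order; a consensus option re-clusters the co-assignment matrix of
`n_runs` restarts thresholded at `tau = 0.5` (the canonical consensus
default) until all runs agree, falling back to the best single run after
100 iterations with a warning. Both community refinement (inside the
Louvain passes) and cross-run consensus are implemented, as the two
available readings of a consensus "fine-tuning" step. Exhaustive
enumeration on graphs of up to 8 nodes serves as the test oracle for the
optimizer.

Node roles use positive weights only (the standard convention; a signed
option exists but is off by default): participation coefficient
`PC_i = 1 - sum_s (k_is / k_i)^2` and module-degree Z, the within-module
strength z-scored within each module (zero-variance modules give 0).
Per-network means of PC and MDZ per window feed subject-level slopes.

## Trajectory features and cohort statistics

Each subject's 20 per-window Q values are regressed on the logarithm of
the cumulative trial count at each window midpoint (windows are defined on
scans, so the trial regressor maps each window to the trial nearest its
midpoint); the slope is the segregation transition rate, and the mean of
windows 1–3 is the early-segregation level. The same regressor produces
per-network PC and MDZ slopes.

The cohort battery: one-sample t on Q slopes; Pearson correlations of Q
slope and early Q with learning rate and habit strength (early-Q vs
learning rate one-tailed, other tests two-tailed); a paired t of
compatible vs incompatible drift; Welch t between cohorts where two are
supplied; a median split by learning rate (stable sort, groups differing
by at most one) with group mean Q curves; and per-network one-sample t
tests on PC/MDZ slopes with Bonferroni correction across
networks x {PC, MDZ} (the simplest valid family-wise control; Holm would
also be valid). Habit-strength outliers (|value − mean| > 3 sd) are
excluded before all cohort statistics and logged.

## Behavior: drift-diffusion model

Choices are accuracy-coded: a diffusion with drift `v`, boundary
separation `a` (correct at `a`, error at 0), relative start `z` (default
0.5) and non-decision time `t_er`, unit diffusion scale. The forward
simulator uses Euler–Maruyama steps of 1 ms with exact Brownian-bridge
within-step crossing detection, which removes the systematic
first-passage bias of endpoint-only checks; trials exceeding 10 s are
omissions. The closed-form hit probability
`(1 - exp(-2 v z a)) / (1 - exp(-2 v a))` is the simulator's test oracle.

Estimation replaces hierarchical Bayesian fitting with per-bin closed-form
moment inversion (EZ-diffusion style, unit scale): accuracy and the mean
and variance of correct response times give `(v, a, t_er)` per bin of 7
consecutive repetitions pooled across stimuli; edge accuracies use
`p* = (x + 0.5)/(n + 1)`. This is deterministic, desk-scale, and testable
by parameter recovery; the price is per-bin drift noise of roughly 0.2
evidence units at 56 trials per bin, which propagates into the learning-
rate estimate (see Limitations). Group-level variance parameters are not
estimated.

The learning rate is minus the exponent `b` of a one-term power fit
`v = alpha * x^b` with `x = log(k + 1)` over bin-centre repetitions `k`
(the `+1` keeps the first repetition from annihilating the power
function). The default fit is least absolute residuals via iteratively
reweighted least squares, matching robust curve-fitting practice for noisy
learning curves; plain least squares is available. Habit strength is the
compatible-minus-incompatible drift difference in the test phase.

## Synthetic cohort: what it emulates

Each subject's time series alternates between two zero-mean Gaussian
states with block correlation structure: integrated (within 0.25, between
0.20) and segregated (within 0.55, between −0.10; anticorrelation between
networks marks the segregated state). Block matrices are repaired to the
nearest positive semi-definite matrix by eigenvalue clipping at 1e-8 and
diagonal renormalization. State dwell segments are ~7 scans (14 s at
TR = 2 s, within the dwell range reported for sliding-window state
analyses); each segment is segregated with probability
`logistic(rate * (s/T - 0.5))` at its midpoint, so the segregated state's
prevalence rises across the session at a subject-specific rate. Isotropic
noise (sd 0.5) plays the role of measurement noise.

Behavior comes from the same DDM family the fitter assumes: drift
`v_k = v_max * min(1, alpha * log(k+1)^b)` with `v_max = 2.5`,
`alpha = 0.38`, per-subject exponent `b`, threshold `a ~ N(1.6, 0.1)` and
`t_er ~ N(0.3, 0.03)`. These place the accuracy curve in the informative
regime (`v * a` roughly 1.8–2.7), where trial outcomes constrain the drift
most strongly. The test phase draws compatible/incompatible drifts
differing by the subject's true habit effect around the end-of-learning
drift.

Across subjects, `(transition rate, learning rate, habit effect)` come
from a Gaussian with correlation `coupling_rho = -0.5` between transition
rate and learning rate and `habit_rho = 0` for habit — so the cohort
realizes one true brain–behavior coupling and one true null. The learning
rate is `-b`; a faster transition pairs with a smaller exponent (the
quickly saturating curve of a fast learner). Population values: transition
rate `N(4, 1.5)` (floored at 0.5; the logistic-to-slope mapping is
monotone and non-saturated in this range), learning rate `N(-0.38, 0.16)`
and habit `N(0.13, 0.28)` (cohort-scale location/spread of the quantities
in the studies this emulates). Default cohort size is 40 subjects, 60
nodes in 4 networks, 700 scans, 784 learning trials (8 stimuli x 98
repetitions) and 80 test trials per condition; node and network counts are
configurable up to atlas scale (hundreds of nodes), the formulas being
size-agnostic.

What the generator does **not** model: hemodynamic convolution, scanner
noise spectra, motion artifacts, voxel-level structure, subject-varying
scan counts, non-Gaussian states. Passing tests therefore demonstrate the
correctness and statistical behavior of the analysis chain under a clean
two-state generative model, not performance on real BOLD data.

## Numerical choices

- Fisher z clipping at `|r| = 1 - 1e-7`; taper sums checked to 1e-12.
- k-means ties broken by lowest restart index; centroid re-seeding on
  empty clusters; convergence = unchanged assignment.
- Louvain move tolerance 1e-12; module ids contiguous from 1; all
  stochastic steps draw from one seeded generator per run.
- Power fits: initialized from log-log least squares; bounded iteration
  (30 IRLS rounds, weight floor 1e-8); non-convergence falls back to
  log-log least squares with a warning.
- Every stage's randomness descends from one integer seed through
  `numpy.random.SeedSequence`; identical configuration and seed give
  bit-identical output files.

## Problem sizes used in tests

Unit tests run on 12–18-node graphs and 5–6-subject cohorts with 8
windows. The end-to-end recovery check replicates the full default cohort
over 20 seeds with 5 Louvain restarts per window and no consensus
(restart-to-restart Q variation at this scale is below 1e-2, so consensus
adds nothing but cost there); the pipeline default remains 10 restarts
with consensus.

## Known limitations

- The learning-rate estimator's noise floor (exponent sd ~0.23 at 56
  trials per bin) is comparable to realistic between-subject spread, so
  cohort correlations with behavior are attenuated by roughly 40% relative
  to the generating coupling; the end-to-end tests document this
  attenuation rather than hiding it. A hierarchical estimator would shrink
  per-bin drift noise and reduce the attenuation.
- City-block k-means with mean centroids is a fixed-point method, not a
  guaranteed descent method for the L1 objective.
- The signed-asymmetric quality function is one of several signed
  modularity conventions; results are not comparable across conventions.
- EZ-style inversion assumes the basic DDM (no inter-trial variability
  parameters); applying it to data generated with such variability biases
  parameters in known ways.
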