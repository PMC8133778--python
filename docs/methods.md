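# Methods

This note documents the models and procedures implemented in `pagstates`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## Signals and their assumptions

The pipeline assumes miniscope ΔF/F traces sampled at 7.5 Hz and keypoint
pose tables at 30 frames/s (an exact 4:1 ratio). Alignment onto the neural
clock block-averages continuous behavioral channels and applies
any-within-block to binary event labels; the trailing partial block is
dropped. All statistical stages consume z-scored traces, normalized once
over the whole session with the population SD (ddof 0), matching the
definition (x − μ)/σ with session-wide moments. Re-z-scoring is refused
rather than silently applied, so the normalization provenance of a matrix
is always unambiguous.

Per-frame activity samples are treated as exchangeable by the rank-sum
categorization test even though calcium traces are autocorrelated. This
inflates significance for cells with slow dynamics; it is retained because
it is the standard per-frame formulation, and the consequences are
quantified in the tests (at chance tuning, the open/closed false-positive
rate approaches the nominal α). Benjamini–Hochberg FDR correction is
available but off by default for categorization, which uses raw p < 0.05.

## Behavior detection

Speeds are computed from centered frame-to-frame displacement (np.gradient)
and smoothed with a **median filter of ~0.33 s** (9 frames at 30 fps,
nearest-edge padding) before thresholding. A moving average of the same
width was considered and rejected: the mean smears a sharp stop or launch
over half the window, biasing detected onsets by several frames, whereas
the median suppresses isolated tracker glitches equally well while keeping
transitions frame-sharp. This is what lets planted events be recovered
with ≤ 1 frame onset error.

Fixed rules (all thresholds exposed in the function signatures):

- freeze: head AND tailbase speed < 0.25 cm/s sustained ≥ 0.33 s;
- approach / escape: body speed > 3 cm/s with the distance-to-rat
  derivative negative / positive; minimum bout 0.33 s (the freeze duration
  scale, reused because no separate value is defined);
- rat movements: rat speed above its session 99.5th percentile; onsets
  within 5.33 s of a kept onset are dropped; each event is annotated with
  its direction angle relative to the mouse at onset (0° = toward);
- head dips: nose beyond the lateral open-arm edge while the body centroid
  is inside an open arm, ≥ 0.2 s. No kinematic definition of a head dip
  exists in the source methods; this geometric surrogate is configurable
  and flagged as such;
- zones: safe = leftmost 20% of the rat arena; threatening = distance to
  rat ≤ 14 cm (inclusive); EPM arms from the centroid against the arm
  polygons with the center square separate.

Direction toward/away from threat is the sign of the displacement of raw
distance-from-safety over a trailing 0.33 s window, with a 0.1 cm deadband
that holds the previous direction — a mouse dithering below tracker noise
keeps its last commitment rather than flickering.

The EPM distance-from-safety is **geodesic along the arm axes through the
center**, not Euclidean: retreating from an open-arm end to a closed arm
requires traversing the full path through the center, and the score should
reflect that travel. Distances are min–max normalized per session (to
[0, 1] in the rat arena, [0, 0.9] in the EPM), so the extremes are the
extremes actually visited.

## Trace conditioning

Artifact suppression computes PCA over cells and flags components carrying
≥ 5% of total variance. The original procedure identified artifact PCs by
eye; as a reproducible surrogate, a candidate is auto-flagged when > 60%
of its projected-signal power lies below 0.01 Hz — slow shared bleaching
passes this test, behavioral signal does not. A manual flag list always
wins. The step is optional per session (in the source data it was applied
to a single animal).

Variance thresholding sorts cell variances in decreasing order and places
the reference cell at the **elbow**: the point of maximum perpendicular
distance to the first-to-last chord, computed after normalizing both axes
to [0, 1] (in raw units the variance scale dominates and the chord
distance degenerates). If the curve is flat or too straight (maximum
distance < 2% of the normalized diagonal), the highest-variance cell is
used. Cells below 10% of the reference variance are discarded; the
reference itself always survives.

## Decoding

Interleaved splitting assigns [60 s train, 10 s gap, 60 s test, 10 s gap,
…] from the session start, so calcium tails cannot leak across roles. Arm
decoding uses a linear SVC with balanced class weights (C = 1, exposed);
center frames are excluded from train *and* test, since a center frame has
no arm label to score against. Significance is the empirical
p = (1 + #{null ≥ observed}) / (1 + N) over N = 100 refits with shuffled
training labels. One property worth knowing: when the two ensembles are
extremely separated, the max-margin boundary of a *shuffled-label* fit
still tends to fall in the low-density region between the clusters, making
the null bimodal at ±1 rather than concentrated at 0. The null remains
sign-symmetric, and the calibration tests therefore use moderate tuning.

Location-index regression is OLS on training rows with predictions clipped
to [−1, 1] (clipping can only reduce squared error since the target lives
in that interval); rank-deficient designs fall back to ridge with a
warning.

## Encoding GLM

The raised-cosine basis on log time uses J = 5, b = 0.25 s, ε = 10⁻³ s by
default, placing peaks near 0.4, 0.8, 1.5, 2.7 and 4.5 s. No basis count
or warp constants are given in the source; these defaults put the last
peak near the 5 s window edge. The j = 5 support formally extends past
5 s, so kernels are truncated at the window — the window is part of the
model definition. Binary behavior channels are convolved with a two-sided
kernel (mirrored copies on negative lags) covering 5 s before onset to 5 s
after offset; kinematic channels use the causal half only. The "eighth"
rat-assay variable not named in the source list is taken to be rat-movement
occurrence. Fitting is ordinary least squares for all cells
simultaneously; the per-behavior summary weight is the mean of that
channel's J coefficients (the reduction behind "average GLM weights" is
not defined in the source; the mean is the simplest symmetric choice).

## CoCA

The objective Σᵢⱼ corr(nᵢᵀX, bⱼᵀY) is maximized by Adam (lr 0.01,
β₁ = 0.9, β₂ = 0.999) on the analytic gradient, with 5 seeded
random-normal restarts keeping the best training objective; convergence is
a relative objective change < 10⁻⁷ over 50 iterations (cap 10 000). The
optimization is implemented directly in NumPy with closed-form correlation
gradients. Correlation is scale-invariant, so reported weights are
unit-norm; the sign indeterminacy is resolved by flipping per-mouse then
per-assay vectors until summed training correlations are non-negative
(exact per-session sign control is impossible because the weights are
shared). Behavioral variables: EPM (6) = normalized |x|, |y|, speed,
head-dip, freeze, location index; rat (9) = distance to rat, mouse speed,
rat speed, head-to-rat angle, approach, escape, freeze, rat movement,
distance from the safe wall. The source gives only the counts (6 and 9);
these lists are the package's interpretation and are config-driven.
Significance: test-set correlation against 1000 random unit-norm neural
projections, one-tailed.

## State models

k-means treats timepoints as samples and cells as dimensions; each K is
fit with 10 randomized initializations keeping the lowest within-cluster
sum of squares, and K is selected by AIC = RSS + 2MK (M = number of
cells). Note this AIC is RSS-dominated on long, weakly clustered sessions
and then favors the top of the K range; the model-selection property is
meaningful when the penalty is comparable to chance RSS gains (the tests
demonstrate it at small sample-to-dimension ratios, where AIC cleanly
picks the planted K and refuses to oversplit). Avoidance/approach
labeling takes the clusters with the minimum/maximum mean score (ties to
the lower index, logged). The permutation null permutes the score series
over timepoints (100 draws); the equivalent formulation "permuting the
neural data" produces the same exchangeable null, and score permutation is
the cheaper of the two. Cross-assay transfer restricts both sessions to
the co-registered cells, assigns test timepoints to the nearest training
centroid, and compares transferred approach vs avoidance scores by
rank-sum. The HMM alternative uses diagonal-covariance Gaussian emissions
on the smallest PC subspace reaching 60% variance, 4 states by default,
10 seeded EM restarts (500 iterations, tol 10⁻⁶), keeping the best
log-likelihood.

## Synthetic sessions

The generator's defaults are the study conditions: 20 min sessions,
30 frames/s pose, 7.5 Hz neural sampling, EPM arms 30 × 7 cm, rat arena
70 × 26 cm, ~44% of cells co-registered across assays, a quarter of cells
tuned to each arm type, SNR 5, and a GCaMP6s-like single-exponential
calcium kernel with τ = 2 s.

Trajectories are waypoint-biased reflective random walks whose wander
speed is confined to (0.8, 2.8) cm/s — strictly between the freeze and
approach thresholds — so the only threshold crossings are the planted,
scripted events (freeze bouts, 5 cm/s approaches, 8 cm/s escapes, head
dips with the nose pushed past the arm edge, and rat-movement bursts with
a deterministic decreasing speed ramp whose frames form the top tail of
the rat-speed distribution). Keypoint offsets around the body centroid sum
to zero, so heading rotation adds no spurious centroid speed. The planted
state sequence maps approach to open-arm/threat-zone occupancy and
approach bouts, avoid to closed-arm/safe-zone occupancy, freezes and
escapes; open-category cells follow the approach state and closed-category
cells the avoid state in both assays (the planted cross-assay shared
code), while TOY sessions carry no tuning at all and an immobile toy rat.
Calcium traces are state indicators passed through the exponential kernel
plus i.i.d. Gaussian noise of SD = tuning/SNR, with an optional
multiplicative bleaching ramp (exp decay, time constant one third of the
session) shared across cells.

What the generator does **not** emulate: tracker jitter and dropped
keypoints (kinematics are noiseless by default), spike-level calcium
transients and their nonlinearity, behavior-correlated motion artifacts,
within-category tuning diversity, drift in tuning over a session, and
realistic bout statistics (events are placed in evenly spaced jittered
slots). Passing tests therefore establish correctness of the *analysis
rules* and recoverability of planted structure under the stated noise
model — not performance on real recordings.

## Problem sizes and tolerances

The shared test sessions are 10 min, 40 cells (one seeded cohort reused
across the suite); decoder nulls use 100 refits, CoCA significance 200 to
1000 random projections, and the AIC demonstration uses 40 samples in 100
dimensions. The acceptance script evaluates the analytic score boundaries
on constructed tracks of ≤ 3600 frames. Numerical tolerances: exact
formula evaluations are asserted to 10⁻⁶ or tighter; GLM weight recovery
to 10⁻⁶ max abs error on noiseless data; null means to 0.05 (decoder) and
0.02 (CoCA); onset recovery to 1 frame.

## Known limitations

- The per-frame rank-sum categorization ignores autocorrelation (see
  above); a block-bootstrap variant is the natural extension.
- CoCA's objective is non-convex; restarts mitigate but do not eliminate
  local optima, and the reported weights are unit-norm representatives of
  a scale-invariant family.
- The AIC = RSS + 2MK criterion has no noise-variance scale; on long
  sessions it tracks RSS and the selected K should be read as an upper
  bound of the supported range.
- Min–max normalization of distance-from-safety makes the
  avoidance/approach score session-relative; sessions that never span the
  arena compress the score range.
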