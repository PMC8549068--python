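# Methods

This note records the models implemented in `mdsegclust`, the defaults
and why they were chosen, the numerical decisions that were genuinely
open, and what the synthetic benchmark does and does not demonstrate.

## Trajectory model and preprocessing

A trajectory is a T×d matrix of observables sampled at a fixed interval
`dt`.  Angular observables (dihedrals in degrees, period 360) are
*unwrapped* before anything else: whenever two consecutive values differ
by more than half a period, the later value is shifted by whole periods
so that every consecutive difference lies in (−P/2, P/2].  A difference
of exactly P/2 is kept at +P/2, a deterministic tie rule.  Unwrapping
prevents boundary crossings (179° → −179°) from being detected as
changes; it is the package's only periodicity treatment — downstream
distances are Euclidean on unwrapped coordinates, not geodesic.
Subsampling (every k-th frame, `dt` scaled by k) is applied after
unwrapping, since subsampling a wrapped series can manufacture spurious
crossings.  Non-finite input values are rejected at read time rather
than imputed; the segmentation model assumes complete trajectories.

## Change detection

The detector maximizes `Σ_j Σ_seg loglik_Laplace(seg) − λ Σ_i |S_i|^α`
over change-point sets S, where j runs over dimensions, segments are
the maximal runs between a dimension's changes, and |S_i| counts the
dimensions changing at union time i.

*Likelihood.*  Each segment is scored at its Laplace maximum-likelihood
fit: location = median (the Laplace ML location; the distribution's
mean coincides with it by symmetry), scale = mean absolute deviation,
floored at `scale_floor` (default 1e−8 in observable units) so constant
segments score finitely.  Fitting a location–scale family makes the
detector invariant to affine transforms of the data (when the floor is
scaled along).

*Penalty.*  λ (default 20) controls the change budget; α (default 0.7)
makes k simultaneous changes cost λ·k^α < λ·k, encoding that coupled
motions across observables are the norm in conformational changes.
α = 1 decouples the dimensions entirely.  For exploratory work the
recommended workflow starts with a large λ and walks it down a
logarithmic ladder (`lambda_ladder`) until the change time scale of
interest appears; over-segmentation is benign because clustering
reabsorbs false splits, while missed changes cannot be recovered.

*Optimization.*  Three regimes, chosen automatically:

- d = 1: PELT-style exact dynamic programming.  The penalty per change
  is the constant λ.  Candidate pruning uses likelihood subadditivity
  (splitting a segment never lowers its total likelihood); because a
  route through the pruning time t is only admissible `min_seg_len`
  frames later, a pruned candidate is retired with that delay, keeping
  the program exact under the minimum-segment-length constraint.  The
  inner segment-cost loop is numba-compiled.
- small multivariate instances (T^(d+1)·2^d ≤ 2·10⁶): an exact joint
  dynamic program whose state is the vector of current per-dimension
  segment starts and whose transitions close a non-empty subset of
  dimensions at the current time, paying λ|A|^α.  Exponential in d but
  globally optimal for any α — pure per-dimension updates can miss
  change points that are only profitable *jointly* (each dimension's
  own gain below λ, combined gain above λ·2^α).
- large multivariate instances: coordinate ascent over dimensions.
  Each sweep re-segments one dimension exactly (the PELT program) under
  the position-dependent marginal penalty λ((m_i+1)^α − m_i^α), where
  m_i counts the other dimensions currently changing at time i.
  Concavity of k^α makes marginal penalties decrease in k, so changes
  co-locate; each sweep cannot decrease the objective, and iteration
  stops when the change sets stabilize (cap: 25 sweeps).

Ties among equal-objective optima resolve toward fewer change points
(the no-split candidate is examined first and only strict improvements
replace it).  `min_seg_len` defaults to 2 — the smallest segment a
location/scale fit can use; the synthetic generator's minimum of 5 is a
property of that data, not of the detector.

## Segment signatures and earth mover's distance

Segments are cut at the union of per-dimension change times (boundaries
{0} ∪ union ∪ {T}); a change detected in any observable starts a new
segment for the whole frame vector.  Each segment is represented by a
unit-mass signature.  The default signature uses the raw frames with
mass 1/n, deterministically thinned in time order to at most
`max_support` points (default 256).  A sparse-histogram mode (occupied
bin centers, occupancy mass; bin width ~5° for angular data) is offered
for very long segments; both converge to the same transport cost at
fine resolution, and raw points avoid an arbitrary binning choice.

The EMD between signatures is the exact optimal-transport cost with
Euclidean ground distance.  In one dimension the quantile coupling is
the exact optimum and is evaluated in closed form
(`scipy.stats.wasserstein_distance`); in d ≥ 2 the transportation LP is
solved by HiGHS via `scipy.optimize.linprog`.  Both routes are
cross-checked in the tests against independent solvers (an assignment
oracle for uniform equal-count signatures; the CDF-area closed form in
1-D) and against the shift identity EMD(P₀, P_θ) = |θ|.  The metric is
genuinely a metric (symmetry, triangle inequality), which the density
cutoff rule below implicitly relies on.

## Density-peak clustering of segments

Given the N×N distance matrix D and per-segment weights w (segment
lengths in frames):

- cutoff: d_c = mean over elements of the distance to the k-th nearest
  other element, k = round(ln N) clamped to [1, N−1].  k(N) = ln N
  grows without bound (no degeneracy) while k/N → 0 (locality), so
  small-population clusters are not drowned out.  The nearest-integer
  reading of "ln(N)-th neighbor" is the least surprising one.
- density: ρ_i = Σ_{j≠i} w_j exp(−(D_ij/d_c)²).  The element's own
  weight is excluded, matching the classical formulation; weighting by
  segment length makes a long dwell dominate the density field even
  when it is one element.
- separation: δ_i = min distance to any higher-density element (exact ρ
  ties break by index: the higher index counts as lower density, making
  everything downstream deterministic); the single global maximum takes
  its row maximum as δ with itself as sentinel neighbor.
- centroids: "auto" mode sorts γ = ρ·δ descending and cuts before the
  largest ratio γ_m/γ_{m+1} with m ≤ N/2 — an automation of the visual
  gap in the decision graph.  All-equal γ yields one centroid (no gap,
  no split).  "manual" mode takes ids verbatim and is the fidelity mode
  for reproducing human-verified selections; "threshold" is the
  classical rectangular ρ/δ cut.
- assignment: one pass in descending density; each non-centroid copies
  its higher-density neighbor's label.  If a manually chosen centroid
  set excludes the global density maximum, the maximum joins its
  nearest centroid — otherwise its chain has no terminus.
- halo: an element is a border element if an element of another cluster
  lies within d_c; members below their cluster's maximum border density
  are halo and may be treated as noise.  Off by default: on segment
  data the slope test (below) is the sharper instrument for transition
  regions.

Point-based clustering (the control mode) runs the same machinery with
every frame an element of weight 1.  Distances are produced blockwise
on demand — the N×N matrix is never allocated — and the cutoff comes
from either the same ln(N) rule or the classical second percentile of
the pooled distance list of a subsampled trajectory.  Segment mode with
unit-length segments reduces exactly to point mode; this equality is
tested, which pins both implementations to the same tie conventions.

## Slope test for transition segments

Under the flat null (i.i.d. normal around a constant mean), the OLS
slope of a segment of length n is normal with mean 0 and standard
deviation σ_slope = σ_resid/√Σ(i−ī)², with σ_resid the residual
standard deviation on n−2 degrees of freedom.  A segment is *sloped*
when |slope| > 1.96·σ_slope in any dimension.  Two deliberate
consequences of taking the rule literally:

- the statistic is really Student-t with n−2 df, so the normal 1.96
  threshold rejects slightly more than 5% of flat segments (≈5.6% at
  n = 50, within the ±0.01 Monte-Carlo band the calibration test
  allows).  The calibration is reported, not corrected.
- no multiple-testing correction across dimensions: the per-segment
  false-positive rate inflates toward 1 − 0.95^d.  The per-dimension
  statistics are all in the report so users can post-correct.

Segments shorter than 3 frames are untestable and reported as such,
never as sloped.  Zero-residual perfect ramps have σ_slope = 0 and are
sloped whenever the slope is nonzero; constant segments are not.  The
pipeline can drop flagged segments and re-cluster the remainder, after
which clusters consist only of unflagged segments and dropped frames
are left unassigned.

## Synthetic benchmark

`generate_dataset` emulates a 1-D observable hopping between two
metastable states: 25,000 points, 50 segments strictly alternating
major/minor (the only arrangement that guarantees 25 segments per state
under the population bookkeeping), major mean I₁ = 100, minor mean
ratio·I₁, both σ = 20.  The minor state's point budget is
round-half-up(pop2·n_points); each state's budget is partitioned into
25 segment lengths ≥ 5 by an exact stars-and-bars uniform composition
(minimums reserved, free mass cut at sorted distinct positions,
minimums added back), so the per-state sums are exact by construction.
Everything is driven by one `numpy` Generator; fixed seed ⇒
bit-identical data.

Minor-state accuracy maps each predicted cluster to the true state
contributing the majority of its frames (ties to the major state,
unassigned frames never correct) and reports the percentage of
truly-minor frames recovered.  `run_batch` sweeps the
(ratio × population) grid — 1.02–1.05 step 0.01 then step 0.05 to 2.00,
populations 0.05–0.50 step 0.05 — with per-cell seeds spawned from a
single `SeedSequence`.  The batch defaults to the clustering-only
ablation (ground-truth change points supplied), which isolates the
segment-clustering question from detection quality; the full-detection
variant is a flag away.

What passing benchmark tests shows: the segment pipeline separates two
overlapping Gaussian states down to small intensity gaps and skewed
populations, with the expected accuracy collapse toward the
(ratio → 1, pop2 → 0) corner.  What it does not show: behavior on
multivariate, autocorrelated, non-Gaussian real MD data with unequal
state variances, nested time scales, or more than two states — the
i.i.d.-within-segment assumption of the generator is exactly the
detector's model, so real-data performance must be judged separately.

## Problem sizes used in the validation suite

Change-detection exactness is checked against literal enumeration of
all admissible change sets (feasible at T ≤ 24 in 1-D and T ≤ 12 at
d = 2, where the oracle enumerates both dimensions' sets jointly);
transport against oracles at ≤ 8 support points; density-peak oracle
equivalence at N ≤ 200; the accuracy surface on a 3×3 corner grid of
the full ladders with 10 replicates at the paper-scale 25,000-point
datasets; slope calibration with 10,000 replicates of n = 50.  These
sizes make the whole suite run in about a minute on one core while
keeping every contract at full strength — enumeration bounds are set by
the oracle's combinatorics, not the implementation's.

## Known limitations

- The coordinate-ascent regime for large multivariate inputs is exact
  per sweep but not globally optimal in general; the exact joint DP is
  limited by its exponential state space to small d.
- Halo control in point mode materializes the distance matrix and is
  capped at 4,096 frames; segment mode has no such cap.
- The EMD LP scales as (support size)² variables per pair; pairwise
  matrices over many long segments should lower `max_support` or use
  the histogram signature mode.
- Auto centroid selection picks a single γ gap; hierarchies of gaps
  (clusters at several scales) need manual mode.
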