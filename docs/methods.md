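# Methods

This note records the models and procedures `flywalk` implements, the
defaults it ships with and why, and what its synthetic data can and
cannot establish.

## Observables

A trajectory is normalized so the arena wall is the unit circle (a
3.2 cm arena; the odor zone's effective radius of 1.5 cm is then
0.46875).  Raw centroid tracks can be denoised by soft-threshold
wavelet shrinkage (symlet-4, four levels, universal threshold with the
noise scale taken from the finest detail band) followed by a lowess
pass with a 7-frame span; both stages are linear-preserving, so
constant and uniform motion pass through unchanged.  The wavelet family
and span are configuration, not a claim about any particular published
pipeline.

Per frame, the displacement is decomposed against the previous frame's
displacement direction: v∥ is the along-heading component and v⊥ the
perpendicular one, with counterclockwise (left) turns negative.  When
the previous displacement is numerically zero (below 1e−12 arena
units) the last valid heading defines the axis; before any heading
exists, v∥ is the step length and v⊥ zero.  This avoids the 0/0 that a
literal application of the defining formulas produces on stationary
frames.  Curvature, v⊥/|d<sub>t−1</sub>|², is flagged undefined on such
frames instead.

Observable values beyond 4 SD of their series mean are replaced with
draws from a normal centered at the signed 4-SD mark whose SD is one
series SD (i.e. unit variance on the standardized scale).  The SD is
computed per fly and per observable over the whole track.  A fixed
raw-unit replacement variance would be two orders of magnitude larger
than the observables themselves (which are ~0.01 arena units/frame)
and would inject artificial states, so the standardized-scale reading
is the only workable one.

## The hierarchical model and its fit

Topology: N<sub>HL</sub> high-level states, each with N<sub>LL</sub>
low-level states carrying bivariate Gaussian emissions.  Each LL
transition row has an extra *exit* category (the terminal-state mass);
an HL transition can only happen through an exit, after which the
destination HL state's initial LL distribution applies.  Exit
probabilities are per-LL-row by default; a tied variant (pooled within
each HL state) and a no-exit variant (which makes
`HHMMSpec(1, K, exit_mode="none")` an exact flat HMM) are available.

Priors.  Transition rows are Dirichlet with total concentration 2 (the
equivalent of two observations), split 6:1 between the self-transition
and the pooled cross mass, the cross mass uniform over the other
destinations including the exit category.  Initial distributions are
symmetric Dirichlet(0.5).  Emissions are Normal-Wishart with mean 0,
unit scale, κ₀ = 1 and the minimal proper degrees of freedom
(dim + 2) — appropriate for z-scored observables.

Standardization.  When each fly is fit with its own model, observables
are z-scored per fly.  When one model is shared across flies (the
pooled cohort fit) a single global transform is used instead: per-fly
scaling would map a slow fly's fastest movement onto the same
standardized value as a fast fly's, destroying the common emission
space on which shared states — and every occupancy comparison across
flies — depend.

Inference.  Variational Bayesian EM with conjugate updates.  The
E-step runs scaled forward-backward on the flattened joint chain using
the exponentiated geometric means A*<sub>ij</sub> = exp E[log
A<sub>ij</sub>]; within-HL cells mix a stay channel and an
exit-and-re-enter channel, and expected counts are split between the
two in proportion to their geometric-mean weights.  All message
passing is scaled per frame, so six-minute tracks (10,800 frames) run
without underflow.  The ELBO is the sum of per-sequence log normalizers
minus the Dirichlet and Normal-Wishart KL terms; it is non-decreasing
across iterations and is the quantity used for restarts, convergence
(relative change < 1e−6, at most 500 iterations by default) and model
comparison.

Initialization.  The first restart is informed: k-means on the pooled
observations proposes emission clusters, an empirical transition matrix
is counted from the hard labels, and clusters are grouped into HL
states by greedy agglomeration on the symmetrized transition mass —
putting clusters that frequently follow each other into the same HL
state, which is exactly the structure a hierarchy represents cheaply.
Remaining restarts are random (means drawn from data frames).  Without
the informed restart, random initializations regularly land in HL
partitions the true process does not use; VBEM cannot swap LL states
across HL groups, and the resulting fits lose to a flat HMM that has
no partition to get wrong.

Model comparison uses the ELBO as the evidence approximation:
log K = ELBO(HHMM) − ELBO(HMM) and P(HHMM|O) = 1/(1+e^{−log K}).
Matched comparisons pair a hierarchy with the flat model of equal
joint-state count, run through the same machinery as a one-level,
no-exit model.

## State post-processing

MAP decoding takes the HL label as the argmax of the per-frame HL
marginal, the confidence as that marginal's maximum, and the LL label
as the argmax within the chosen HL state.  Cleaning applies three
rules in order: frames at or below 0.85 confidence become unassigned;
a→b→a excursions shorter than 5 frames (~170 ms) are relabeled a
(iterated to a fixpoint, since relabeling can merge runs and expose new
short excursions; unassigned frames break adjacency); remaining
single-frame dwells are unassigned.  A 1-frame dwell at the end of a
track, or one followed by an unassigned gap, never "changes state" and
is kept — this is what makes the at-threshold worked example
(a 5-frame excursion flanked by single frames) pass through unchanged.
Removed dwells are excluded from occupancy denominators rather than
merged into neighbors.

States are then reordered by mean(speed)/var(curvature), ascending, so
state 1 is always the slowest, most turn-intensive feature; states
with fewer than two assigned frames sort last.  Track segments are
visualized by translating the first point to the origin and rotating
the prior-10-frame displacement onto +y (all available prior frames if
fewer than ten; the segment's own first displacement if none).

## Odor statistics

Frames are parsed into B_I/B_O/D_I/D_O by position (inside ⇔ radius ≤
0.46875, boundary inclusive) and the first zone entry at or after the
odor-onset frame (5400 = minute 3).  A fly that never enters after
onset keeps all frames "before" and is flagged.  Per-fly occupancy
vectors use assigned frames only; their per-state SD is
√(p(1−p)/(N−1)).  Cohort means carry BCa bootstrap confidence
intervals computed by resampling flies (scipy's BCa implementation).

The equal-means bootstrap test recenters both per-fly samples onto the
pooled mean, resamples each 10,000 times (2,000 in the scaled-down
calibration runs), and compares the Welch-type statistic against the
null distribution two-sidedly with add-one smoothing.  Holm–Bonferroni
corrects across the HL states at α = 0.05; a secondary uncorrected
flag is reported at α = 0.01.  Type-I error on null simulations is
checked to sit within [0.03, 0.07] at α = 0.05.

Spatial maps bin the arena into a 60×60 grid over [−1, 1]²,
conditioning state probabilities on the bin; bins with fewer than 20
assigned frames are masked.  A radial profile is derivable from the
same arrays.

## Fly clustering

X-means fits k-means for K = 1..k_max (spherical-Gaussian BIC,
−2 log L̂ + p ln n), and scores each increment with
t² = BIC<sub>K</sub> − BIC<sub>K+1</sub> + ln N (natural log).  Growth
stops at the first increment with t ≤ 3.86; the chosen K is the
largest significant K whose BIC lies within 5% of the minimum over the
models still in play.  Applying the 5% window to the global BIC
minimum instead lets an insignificant tail of the BIC curve veto — or,
without sequential gating, hallucinate — clusters: on flat-Dirichlet
nulls the gated rule returns K = 1 in ≥ 95/100 seeded draws, while the
ungated literal rule does not.  Permutation invariance comes from
running k-means on a canonically sorted copy of the points with a seed
mixed from the data bytes.

KL divergence from the average fly to each individual fly smooths zero
entries of the individual's distribution with 1/(2·n_frames) of
pseudo-mass before renormalizing.  The chance level of
nearest-centroid re-identification is Σ xᵢpᵢ with xᵢ the cluster size
fraction and pᵢ the centroid's Voronoi share of the uniform simplex,
estimated with 10⁵ flat-Dirichlet draws.

## Odor decoding

State usage in 1-s bins (30 frames; 0.33/0.66/3 s supported) is the
feature; unassigned frames stay in the denominator, so bins sum to at
most one and bins over 50% unassigned are dropped.  Classes are
balanced by seeded random removal, fixing chance at exactly 50%.  PCA
keeps the smallest number of components explaining over 90% of
variance; the logit fit carries a weak ridge (C = 10⁴) so perfectly
separable problems stay finite, and accuracy is evaluated in sample by
default (a cross-validation flag exists but is off, matching the
fit-based evaluation convention; note that in-sample evaluation is
optimistically biased by roughly k/n, which is why chance-level checks
use thousands of bins).  Decoder pairs are compared by the
perpendicular distance from the unity line, D = (M₁−M₂)/√2, with a
two-sided Wilcoxon signed-rank test.  Cluster reconfiguration moves at
most six flies out of clusters with more than ten members, worst
own-cluster accuracy first, greedily to whichever cluster decodes them
best.

## Mixture of HHMMs

Each fly is first fit individually; flies are grouped by a Gaussian
mixture (diagonal covariance, BIC-selected component count capped at
n/2, with component variances floored at 5% of the overall usage
spread so singletons cannot buy unbounded likelihood) on their
expected LL-state usage vectors, taken in canonical emission-sorted
state order because each per-fly model labels its states arbitrarily.
EM then alternates responsibility updates (softmax of per-fly
log-evidence plus log mixture weight, concentration 1) with
responsibility-weighted VBEM sweeps per cluster.  The perturbation
schedule — prune unused clusters down to at most two, split a
size-weighted random cluster by k-means on usage, seed empty clusters
with the worst-fit flies, ten EM iterations after each step, ten
rounds, then EM to convergence — guards against local optima.  Pruning
never removes any fly's argmax cluster.

One addition proved necessary: a merge pass before the final EM that
greedily joins cluster pairs while the total objective (mixture
evidence minus each cluster's parameter KL) improves.  Per-fly
log-evidences are large numbers, so a duplicate cluster specialized to
its few flies always wins the responsibility competition by a margin
the mixture weights cannot overcome; without charging clusters for
their parameters, split-produced duplicates persist forever, and a
cohort generated from a single model would never end with a single
occupied cluster.

## Synthetic data

Three generators with different jobs:

- An HL-only Markov-chain fly (occupancy start, transition-matrix
  dynamics), including scenario-wise generation, used for distance
  nulls.  Under scenario-wise generation the configured occupancy shift
  is recovered by construction in essentially every fly.
- A full hierarchical simulator (LL chains, exit events, Gaussian
  emissions) with known labels, used for parameter-recovery checks.
- A whole-arena cohort: 34 flies, 6 min at 30 Hz, four locomotor-type
  clusters.  Emissions follow a catalog of 10 HL × 5 LL Gaussians —
  three slow states (a meander, a wide-variance stop-and-go, a sharp
  turner), four medium states separated in v∥, three fast states with
  signed v⊥ for turn direction; speeds span roughly 0.1–2.1 cm/s.
  Baseline HL transitions are sticky (mean dwell 0.5 s) with
  band-limited cross mass, so transitions favor kinematically
  neighboring states.  The (v∥, v⊥) stream is integrated into an (x, y)
  track by heading propagation with reflection of the radial component
  at the wall, and recomputing observables from the integrated track
  returns the generating emissions exactly except at reflection frames.

From odor onset, HL transitions drawn while the fly is inside the zone
follow an inside-shifted matrix (slow states 1 and 3 up 6-fold, fast
states 7–10 down 10-fold, renormalized); once the fly has entered the
zone after onset, outside transitions follow an outside-shifted matrix
(stopping down, fast states up 3-fold).  The shifted matrices target
their shifted occupancy directly, without band damping, so short zone
visits still move occupancy.  These magnitudes are set so
that the configured effect is statistically recoverable from a single
6-minute trial per fly at a 34-fly sample — the regime the analysis
pipeline is meant to operate in: track integration couples position to
state (fast flies cross the zone mostly in fast states) and zone
visits begin with an entry transient, both of which dilute the
realized occupancy change relative to the configured stationary
shift.  Under the defaults, roughly 19 of 20 flies individually show
the inside-zone slow-state increase, and the cohort-level bootstrap
test detects it comfortably.

What passing tests on this cohort do and do not show: they establish
that the inference machinery recovers planted structure (states,
clusters, occupancy shifts) through the complete pipeline under
realistic dynamics, sample sizes and trial lengths.  They do not
establish anything about real flies — the generator has no posture,
no tracking noise beyond what smoothing targets, no odor-plume
physics, a single behavioral timescale per level, and cluster
structure that is planted rather than discovered.

## Scaled problem sizes

The end-to-end checks fit a 6 HL × 3 LL model to the 34-fly cohort
(two restarts, up to 50 iterations), use 2,000 bootstrap draws in the
1,000-replicate calibration run and 5,000 in single tests, and
estimate Voronoi weights with 10⁵ simplex draws.  These sizes keep the
whole suite in the tens of minutes on one core while leaving every
statistical conclusion comfortably resolved; all of them are plain
arguments that can be raised.

## Known limitations

- The variational posterior factorizes parameters from states; the
  ELBO comparison therefore shares the usual caveat that bounds, not
  marginal likelihoods, are compared.
- Exit-driven HL dwell times are geometric per LL row; empirical dwell
  distributions with heavier tails would need duration modelling the
  hierarchy does not provide.
- X-means inherits k-means' spherical bias; occupancy vectors live on
  a simplex, and small-sample anisotropy occasionally splits a tight
  cluster (the selection rule's sequential gate mitigates but cannot
  eliminate this).
- In-sample decoding accuracy is optimistically biased for small bin
  counts; cross-validation is available behind a flag.
- The mixture's evidence-guided merge uses a greedy pass with short
  refits; it can in principle merge clusters a longer refit would have
  kept distinct.
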