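# Methods

## The model

`threemode` decomposes a complete persons × symptom-items × time-points
score cube `x_ijk` (I × J × K) with the Tucker3 / three-mode PCA model

    x_ijk  ≈  Σ_p Σ_q Σ_r  a_ip · b_jq · c_kr · g_pqr

where `A` (I × P), `B` (J × Q) and `C` (K × R) have orthonormal columns
— person, symptom and time components — and the core array `G`
(P × Q × R) weighs every triple interaction of components.  Because the
factors are orthonormal, the fitted array is an orthogonal projection
of the data: the explained sum of squares equals `‖G‖²` exactly, and
each core element `g_pqr` contributes `g²_pqr` of explained SS, which
is what the per-element explained-variance table reports.

The decomposition is applied not to the raw scores but to the
*heterogeneity* around the cohort's shared course: preprocessing first
removes the general trend (the per-(item, time) mean over persons) and
then rescales every item slab to root-mean-square 1, so each item
contributes equal SS to the least-squares fit.  Both steps are exactly
invertible (`PreprocessingState` stores trend `M` and scales `s`).

Why RMS-1 slab normalization rather than SS = 1: the two conventions
differ only by the constant `√(I·K)` per item, produce identical
components and fit percentages, and RMS-1 keeps the preprocessed total
SS at the convenient `I·J·K` independent of cube shape.

## Fitting

`tucker3_als` uses higher-order orthogonal iteration (TUCKALS-type
ALS): each mode's matrix is replaced by the leading left singular
vectors of the cube matricized against the other two modes' current
projections.  Each update is an exact partial least-squares optimum, so
the recorded residual-SS history is non-increasing; the iteration stops
when the relative fit change drops below `tol` (default 1e-8, max 1000
iterations).  Initialisation is truncated HOSVD (deterministic);
optional extra random restarts are seeded and the best fit wins.
Component columns are sign-fixed (largest-magnitude entry positive,
compensated in the core) so repeated runs are bit-identical.

Rank admissibility (P ≤ QR, Q ≤ PR, R ≤ PQ) is enforced everywhere a
rank triple enters.

### Fit percentages

Two fits are reported.  The *heterogeneity fit* is
`100·(1 − SS(resid)/SS(cube))` against the preprocessed cube.  The
*total fit* additionally credits the general trend: on the
symptom-normalized scale the prediction is `M_jk/s_j + x̂_ijk` and the
fit is taken against `x_ijk/s_j`.  This is the unique accounting in
which trend and model SS live on a common scale; since the trend is an
exact person-mean, the residual is identical in both accounts and
total fit ≥ heterogeneity fit whenever the trend carries any SS.

## Rotation and pooling

A Tucker3 solution is identified only up to orthogonal rotations per
mode (compensated in the core).  `joint_orthomax` rotates toward
interpretability by maximizing

    w_core · Σ_modes orthomax(G_(m)ᵀ, γ)  +  Σ_m w_m · orthomax(M_m, γ)

with γ = 1 (varimax flavour) by default.  The "standard" weight preset
puts weight 1 on the core per matricization and weight
(core elements)/(matrix elements) on each component matrix, with the
person-mode matrix weight forced to 0 — simplicity of individual
person scores is not a goal.  Optimization is by pairwise Jacobi plane
rotations swept in the fixed order (symptom, time, person).  For any
plane, every criterion term is a quartic in (cos θ, sin θ) invariant
under quarter-turns (which act as signed column or row permutations),
so the restricted criterion is exactly `a + d·cos 4θ + e·sin 4θ`;
three evaluations at θ = 0, π/8, π/4 give the optimal angle in closed
form and the criterion is monotone by construction.

`align_solution` matches one solution's columns to a reference by
maximizing total |Tucker congruence| per mode (Hungarian assignment,
signs fixed positive).  `generalized_procrustes` aligns the
per-imputation solutions, then iteratively rotates each toward the
running mean by orthogonal Procrustes per mode (cores counter-rotated)
and averages; the averaged component matrices are re-orthonormalized
by polar decomposition with the nearness correction folded into the
core.  Element-wise across-imputation standard deviations and
per-column congruences with the mean are reported.

## Missing data

The cube is flattened to persons × (J·K [+ covariates]) and modelled
as multivariate normal.  Each of the m imputations bootstrap-resamples
persons, runs EM to a (μ, Σ) point estimate on the resample — the
bootstrap supplies parameter uncertainty — and draws every original
person's missing block from its conditional normal.  Because J·K can
rival I, each M-step shrinks Σ toward its own diagonal:
`Σ ← (n·Σ̂ + λ·diag(Σ̂)) / (n + λ)` with prior weight λ = ridge · I
(ridge default 0.005, i.e. 0.5% of the person count).  EM convergence
is declared at relative parameter change < `tol` (default 1e-5, max
100 iterations); non-convergence is recorded per imputation and the
last iterate used.  Observed cells are copied back verbatim into every
completion.

A draw-based imputer's error floor is `√2 ×` the true conditional
standard deviation (the truth and the draw each deviate from the
conditional mean independently); the test suite checks the imputer
against an exact conditional-variance oracle under the generator's
known covariance rather than against the noise sd alone.

## Variance screening

The three-way ANOVA uses the classical balanced single-observation
decomposition of the grand-mean-centered completed cube into three
main effects, three pairwise interactions, and a three-way-plus-error
remainder (the three-way term is confounded with error, so no tests
are computed — the shares only answer whether a three-way interaction
is worth modelling).  It runs on the raw-scale completed cubes, not
the preprocessed ones: person-mode centering would annihilate the
persons main effect the screen is supposed to show.

## Model complexity and stability

All admissible rank triples up to a ceiling are fitted on every
imputed cube; mean fit is plotted against total components
S = P + Q + R, and triples on the upper convex hull are candidates.
The elbow is the hull entry with the largest drop ratio
(gain from previous hull entry)/(gain to next); candidates whose
cross-imputation component congruence falls below 0.85 are vetoed, and
ties go to fewer components.  The 0.85 default sits just above
congruence levels conventionally read as "fair" similarity;
it is configurable.

Split-half stability halves the persons at random, preprocesses each
half independently (centering is part of the estimator), fits and
rotates at the chosen ranks, aligns symptom/time components across
halves, and records per-column congruences over `n_splits` (default
10) random halvings.  Person components are excluded — the halves
share no persons.

## The synthetic generator

`generate_tucker3_dataset` inverts the analysis model:
trend + planted structure + i.i.d. Gaussian noise, with optional
integer rounding/clipping (0–3 item range), exact-count missingness
(MCAR, or MAR-by-time with masking odds × 1.5 per later assessment),
and person-level covariates whose loadings on the standardized person
scores are their implied correlations.  Two constructions make the
planted truth exactly recoverable through preprocessing:

* person components have exactly zero column means, so person-mode
  centering leaves the structure untouched;
* item loadings are iterated (row rescale + re-orthonormalize) until
  every item slab carries equal planted SS, so symptom-mode
  normalization rescales all items identically.

The study-shaped preset (219 × 21 × 9, ranks (3,2,2)) plants three
core elements with pairwise-disjoint per-mode supports — every
matricization of the core has orthogonal rows, making the planted
columns identified up to sign and order.  Core magnitudes (28, 57, 30)
and noise sd 0.568 were calibrated by Monte Carlo so the planted
structure carries ≈28% of post-preprocessing SS; the declining trend
(per-item severity × shared recovery curve, scale 1.34) is sized so
trend + structure explain ≈65% on the normalized scale.  Default
missingness is 7.8% MCAR.

What the generator does *not* emulate: ordinal/graded item measurement
(noise is Gaussian; clipping is off in recovery tests because it
breaks exactness), a person-severity main effect outside the planted
components (so raw-scale ANOVA shares differ from a clinical cohort's
profile), treatment arms, and non-random dropout beyond the geometric
MAR-by-time option.  Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to
ordinal measurement or informative missingness.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 219 × 21 × 9 shape but
with m = 5 imputations and EM capped at 30 iterations (tol 1e-4); the
library defaults are m = 20 and 100 iterations.  These run sizes are
the package's choice of desk-scale verification: m = 5 already pins
pooled quantities to within a few hundredths of a point on synthetic
data.  Degenerate inputs are rejected with specific errors
(zero-variance item slabs, constant external variables, zero-SS cubes,
empty selections, unimputable columns); a numerically constant cube
reports ANOVA shares of 0 with an explicit flag rather than NaN.

Known limitations: no oblique rotations (orthogonal components may be
too strict for real psychopathology data); no missing-data-aware ALS
(missingness is handled entirely by imputation); Tucker3 only (no
Tucker2/PARAFAC); clinical labels for components are user-supplied
strings, never inferred.
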