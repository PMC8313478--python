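# Methods

## Model and estimator

`miivkit` estimates structural equation models

    y* = Λ η + ε,        η = B η + ζ,     var(ε) = Θ,  var(ζ) = Ψ,

whose endogenous indicators may be continuous, ordinal, or binary.  A
discrete indicator is the thresholded version of a standard-normal
underlying variable; its implied variance is fixed at 1, so the
corresponding Θ diagonal is identification-constrained rather than free.
Zero means are assumed throughout (continuous data are internally
mean-deviated; underlying variables of discrete indicators have zero means
by convention).

Each latent variable receives its metric from a scaling indicator whose
loading is fixed at 1.  Substituting `η_f = y*_{s(f)} − ε_{s(f)}` turns the
system into regressions among observed/underlying variables only — the
latent-to-observed (L2O) transformation.  One equation arises per
nonscaling indicator and one per endogenous latent variable; each carries a
composite error that is a known linear form in (ε, ζ), generally correlated
with the regressors.  Model-implied instrumental variables (MIIVs) are the
observed variables whose model-implied covariance with that composite error
is structurally zero; coefficients are then estimated equation by equation
from moment blocks of S by the 2SLS functional

    γ_j(s) = (S_vz' S_vv⁻¹ S_vz)⁻¹ S_vz' S_vv⁻¹ S_vy ,

a closed form with no convergence concept.  Variance parameters (free Ψ and
Θ entries) are recovered in a second stage by minimizing the weighted
least-squares discrepancy (s − σ(θ))' W (s − σ(θ)) with the first-stage
coefficients held fixed.

### Structural-zero detection

Instrument eligibility is decided numerically rather than symbolically: the
model-implied covariance between every observed variable and an equation's
composite error is evaluated at five independent random admissible
parameter points (free parameters drawn uniform on (0.2, 0.8), variances
positive, covariances scaled to be admissible) and a candidate must satisfy
|cov| < 1e-10 at all draws.  A coefficient that vanishes at five generic
points vanishes identically up to float noise, so this matches a symbolic
zero without a computer-algebra dependency.  The draw seed is fixed, making
candidate sets deterministic.  A regressor that is itself uncorrelated with
the composite error may serve as its own instrument; only regressors
correlated with the error are excluded.

### Instrument selection

`all` uses the full candidate set.  `n_extra(k)` keeps K_j + k candidates
(K_j = number of regressors) chosen to maximize the minimum Shea partial R²
over the regressors — an exhaustive subset search up to 100 000
combinations, greedy forward selection beyond that — with ties broken by
data-column order for determinism.  Subsets whose projected-regressor
moment block is numerically singular are skipped.  Shea's partial R² is
computed entirely from moment blocks (squared correlation of the doubly
residualized regressor and its doubly residualized first-stage projection),
so it is available for polychoric entries where no raw underlying data
exist.

## Moment matrix and its asymptotic covariance

S mixes Pearson covariances (continuous pairs, divisor n), polychoric
correlations (discrete pairs), and polyserial correlations scaled by the
continuous member's standard deviation (mixed pairs).  Discrete diagonals
are fixed at 1.  All correlations use the two-step convention: thresholds
from the univariate margins (standard-normal quantiles of cumulative
proportions; zero-count categories merged with a warning), then a bounded
one-dimensional likelihood maximization for ρ on (−1+1e−6, 1−1e−6) with
tolerance 1e−9; boundary solutions are clipped and flagged.  Bivariate
normal rectangle probabilities use the Owen's-T representation
(vectorized, ~1e−14 absolute accuracy against quadrature).  Missing data
are handled by listwise deletion (the only rule the estimators support).

The free-entry vector s stacks all below-diagonal entries plus the
diagonal entries of continuous variables in column-major lower-triangle
order.  Υ, the asymptotic covariance of √n(s − σ), has four estimators:

* `normal` — normal-theory 2D⁺(S⊗S)D⁺ᵀ, i.e. Υ[ij,kl] = S_ik S_jl + S_il S_jk
  (all-continuous only).  This exact form is what makes the finite-sample
  equivalences below hold to machine precision.
* `adf` — centered fourth-moment estimator (all-continuous only).
* `score_sandwich` — default for any data containing discrete variables.
  Every entry of s is a two-step M-estimator; its per-observation influence
  function is assembled from the analytic estimating-function score and
  finite-difference derivatives of the mean score with respect to the
  nuisance parameters (thresholds, and for polyserial entries the
  continuous mean and SD), combined with the closed-form influences of
  those nuisances.  Υ is the empirical covariance of the stacked influence
  rows, so cross-entry covariances come for free.  On mixed data it agrees
  with the nonparametric bootstrap within Monte Carlo error (median
  relative difference of SDs ≈ 2–3% at n = 600–800).
* `bootstrap(B)` — nonparametric resampling of the whole moment vector
  (B ≥ 50 enforced); retained as a fallback for ill-conditioned sandwiches.

Any estimated Υ is symmetrized; eigenvalues below −1e−8·λmax raise an
error, smaller negative ones are clipped to zero.

## First-stage inference

Two SE estimators are exposed.  The *general* form uses the full jacobian
K_j = ∂γ_j/∂σ' (analytic, via 0/1 selection derivatives of the S blocks;
identification-fixed discrete diagonals carry no derivative):
SE = sqrt(diag(K_j Υ K_j')/n).  It is valid even when instruments are
invalid.  The *valid* form is the sandwich built from Ω_j, the asymptotic
covariance of the instrument-residual moment g_j = S_vy − S_vz θ̂, with
three variants: Ω̂ (delta method through Υ), Ω̃ = Ω̂ − g g', and the classic
φ̂² S_vv.  Division is by n, matching the √n scaling of the asymptotic
results.  With all-continuous data and the normal-theory Υ, Ω̂ = φ̂²S_vv +
g g' holds exactly in finite samples, so the valid SEs coincide with the
classic 2SLS SEs and Ω̃ equals the classic form — these identities are
asserted at 1e−10 in the tests.  The default Ω variant is Ω̂ (recorded in
output); Ω̃ and classic are selectable, since the three differ only in
finite samples and each anchors a different known special case.

## Second stage and model tests

Given θ̂1, σ(θ) is exactly linear and homogeneous in θ2 (the solved ordinal
Θ diagonals affect only moment entries excluded from s), so the
fit-function minimizer is the closed generalized-least-squares solution.
The package computes it directly — the second stage can therefore never
fail to converge, and the optimizer-monotonicity property holds by
construction.  Variance parameters are unconstrained; solutions with
non-positive-definite Ψ̂ or Θ̂ (including Heywood cases from the solved
ordinal diagonals) are flagged *improper* rather than prevented, matching
the outcome-measure convention (proper = converged AND PD).  θ2 standard
errors use the delta form C = H(I − J1 K), H = (J2'WJ2)⁻¹J2'W, with σ(θ)
jacobians computed analytically; SEs are invariant to scalar rescaling of
W.

The systemwide DWLS comparison estimator minimizes the same discrepancy
over the full θ by trust-region least squares with the analytic jacobian
(max 500 residual evaluations, ftol/xtol 1e−12), started from
scale-aware heuristics: free loadings from moment ratios against the
scaling indicator, structural coefficients from OLS among scaling
indicators, exogenous factor (co)variances from scaling-indicator moments,
residual-variance starts clipped below at 0.05.  Non-convergence is
flagged, not repaired.

Model fit uses the weighted-sum-of-chi-squares characterization of
nT(θ̂): the mean-scaled statistic T_m = n·r·T/tr(M̂) (df r = free moment
entries − free parameters) and the mean-variance adjusted T_mv =
n·tr(M̂)/tr(M̂²)·T (df tr(M̂)²/tr(M̂²), generally non-integer).  For the MIIV
estimator M̂ stacks the first-stage K and second-stage C influence
matrices; for systemwide DWLS the same machinery uses the one-step
influence (J'WJ)⁻¹J'W — the paper-level reference does not spell out the
DWLS correction matrix, and this full-θ delta form is the package's
documented choice.

Equation-level overidentification tests (df L_j − K_j): the naive Sargan
chi-square in moment form; the generalized-Wald statistics F and F̃
(Ω̂/Ω̃-weighted, with the Moore–Penrose inverse of the idempotent QQ',
singular values below 1e−10·max discarded); and Satorra–Bentler mean and
mean-variance adjusted versions F_m/F_mv/F̃_m/F̃_mv driven by trace
functions of Π̂.  Matrix square roots clip sampling-noise negative
eigenvalues at zero.  Just-identified equations are reported as not
testable.  Reports apply a Bonferroni correction across overidentified
equations by default (α/m), selectable off.

## Synthetic-data generator

The generator emulates the study's design: five latent variables — two
correlated exogenous, three endogenous in a recursive standardized
structural model — each measured by three indicators with standardized
loadings 0.8/0.65/0.5 (indicator error variances 1 − λ², unit total
variances); indicators of the second and fourth factors are ordinal with
five categories cut at the standard-normal quantiles of cumulative response
probabilities 0.04/0.05/0.21/0.46/0.24.  The structural coefficients and
the exogenous correlation are not printed in the source text; the values in
`data/sim_truth.json` (corr 0.3; paths 0.4/0.4; 0.25/0.25/0.35;
0.2/0.2/0.25/0.25) were fixed once as realistic standardized magnitudes for
a recursive psychological mediation-style system, and residual latent
variances are solved so all latent variances are 1.  Under the omitted-path
misspecification these values reproduce the qualitative probability-limit
pattern expected of systemwide estimation — large bias in the directly
misspecified equation, bias spread into the correctly specified final
equation, exact robustness of the MIIV loading estimates — but magnitudes
tied to the unpublished figure values (e.g. exact proper-solution
percentages, exact bias levels) should not be read as replications.

What the generator does *not* emulate: non-normal continuous indicators,
missing data, unequal thresholds across indicators, cross-loadings or
correlated errors in the population.  Passing tests therefore certify the
estimator's behavior under clean multivariate-normal thresholded data, not
robustness to real-data pathologies.

Scaling conditions: `high` scales each factor by its loading-0.8 indicator,
`low` by its loading-0.5 indicator — the latter makes the instruments weak
(population maximum Shea partial R² ≈ 0.39 under `high`, ≈ 0.18 under
`low`, never above 0.5).

## Monte Carlo conventions

Replication seeds are base_seed + replication index; the runner is serial,
so a condition's summary is bitwise reproducible from its seed.  Outcome
measures follow the study conventions: percent proper solutions; 100 ×
median relative bias per parameter (zero-truth parameters excluded with a
warning) and mean absolute bias per parameter group (Λ, B, Ψ, Θ); SE
accuracy as the median relative deviation of estimated SEs from the
pseudo-true SE, defined as the SD of estimates surviving the Q1/Q3 ± 3·IQR
trim (trimmed fractions reported); rejection rates at α = 0.05.  Model
tests aggregate over proper solutions only; equation tests need only the
closed-form first stage and aggregate over all converged replications.

Problem sizes used by the test suite and acceptance script (chosen as
desk-scale analogues of the full study): null calibration at 2000
replications on small valid-instrument models (n = 800 continuous,
n = 1200 ordinal); parameter recovery at n = 2000 with 500 replications;
proper-solution cells at n = 200 with 400 replications (the full study
used 10 000).  Monte Carlo standard errors at these sizes are ≈ 0.5
percentage points on a 5% rate and ≈ 1 point on a 97% proper-solution
percentage.

## Numerical choices

* Singularity: reciprocal condition number < 1e−12 treats a moment block as
  singular; the affected equation is flagged and the rest proceed.
* PD checks: smallest eigenvalue > 1e−8 (diagonal Θ̂: all entries > 0).
* Moore–Penrose tolerance 1e−10·max singular value (QQ' is rank-deficient
  by construction, deficiency K_j).
* 1-D likelihoods: bounded Brent, xatol 1e−9.
* Finite differences inside the score sandwich: step 1e−4 on the mean
  score (second-derivative and cross terms), analytic per-observation
  scores.
* Degenerate inputs: constant continuous columns, single-category discrete
  columns, < 3 complete cases, and missing type declarations raise errors;
  zero-count categories merge with a warning.

## Known limitations

* No censored (tobit) indicators, mean structures, equality constraints,
  multi-group models, or pairwise-present estimation.
* The empirical-example dataset (138 observations, available with an R
  package distribution) cannot be shipped here; the reproduction workflow
  is implemented and documented but its reference values are not asserted
  without the data.
* The score sandwich assumes the two-step estimating equations are exactly
  the ones used for estimation; switching the moment estimators to joint
  ML would require new influence functions.
* DWLS comparison results depend on optimizer details (starts, tolerances)
  that the methodological literature leaves open; proper-solution
  percentages for DWLS are therefore approximate by nature.
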