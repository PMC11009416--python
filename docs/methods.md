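# Methods

## Model and estimation

The quasi-Poisson regression model specifies a count response by its
first two moments only: E(y_i) = μ_i = exp(x_i′β) and
Var(y_i) = γμ_i. No full likelihood is assumed; the coefficients
solve the quasi-score equations X′(y − μ) = 0, which we solve by
iteratively reweighted least squares (IWLS). Because the dispersion
γ enters the score only as a scalar factor, it cancels in the
coefficient update. We therefore carry the weights as W = diag(μ̂),
so the weighted cross-product is F = X′diag(μ̂)X and the coefficient
covariance is γ̂F⁻¹, with γ̂ the Pearson estimate
χ²/(n − p − 1) = [Σ (y_i − μ̂_i)²/μ̂_i]/(n − p − 1). This is the
standard quasi-likelihood convention and keeps every downstream
moment formula literal.

IWLS details: starting values from ordinary least squares on
log(y + 0.5); stopping when the maximum relative coefficient change
drops below 1e-8; at most 100 iterations, after which a convergence
error carrying the last iterate is raised. Fitted means are floored
at 1e-10 and linear predictors clipped at |η| ≤ 700 so the working
response and exp() stay finite on degenerate inputs; neither bound is
active on any realistic fit. Exact iteration counts depend on these
choices and are not meaningful outputs; the estimates themselves are
insensitive to them (verified against statsmodels' GLM fit to 1e-6).

## Ridge estimator and its exact moments

The ridge estimator β̂_k = (F + kI)⁻¹Fβ̂_QLE shrinks all p+1
coefficients, intercept included (an option excludes the intercept
from the penalty, but penalizing the full vector is the default).
Regressors are not standardized before shrinkage: the estimator is
applied to F as fitted, and the simulation generator already produces
unit-variance regressors.

In the canonical form — eigen-decomposition F = TΛT′, rotated
coefficients α = T′β — the moments are diagonal:

- bias(β̂_k) = −kTΛ_k⁻¹T′β,
- cov(β̂_k) = γTΛ_k⁻¹ΛΛ_k⁻¹T′,
- MMSE = cov + bias·bias′,
- scalar MSE(k) = M1(k) + M2(k)
  = γΣλ_j/(λ_j+k)² + k²Σα_j²/(λ_j+k)²,

with Λ_k = diag(λ_j + k). M1 is strictly decreasing in k and M2
strictly increasing (their derivatives are computed in closed form),
and dMSE/dk = −2Σλ_j(γ − kα_j²)/(λ_j+k)³ is strictly negative for
k < γ/max_j α_j², which guarantees some k > 0 beats k = 0. These
statements are verified numerically on random canonical systems in
the test suite.

The bias is evaluated at β̂_QLE for data fits (the truth is unknown)
and at the true β inside simulations. Eigenvalues are sorted
descending and each eigenvector's sign is fixed so its
largest-magnitude entry is positive; all reported quantities are
invariant to this convention (tested), it only makes runs
reproducible.

## Biasing-parameter rules

Sixteen rules map (α̂_j, λ̂_j, γ̂, p) to k. All use the same Pearson
γ̂; there are no per-rule dispersion variants. Conventions that the
formulas leave open:

- the median in k5 and k7 is the usual midpoint-of-two-central-values
  for an even number of terms;
- "α̂²_min" in k5 is min_j α̂_j²;
- k9's numerator dispersion symbol is read as γ̂, the only dispersion
  quantity in the model;
- k11 is implemented exactly as published for this estimator,
  Σ r_j(2 + r_j²) with r_j = γ̂/α̂_j². This grows like r³ and
  typically drives the fit to full shrinkage, which is consistent
  with its published simulation behaviour (MSE pinned at the
  full-shrinkage value β′β). The related literature rule with a
  square root, Σ r_j(1 + √(1 + r_j²)), is available as the opt-in
  name `k11_sqrt` and is never a default.

Rules dividing by α̂_j² (k3, k10, k11, k13, k14) reject inputs with a
zero rotated coefficient by name.

## Simulation design

The Monte-Carlo engine emulates the standard evaluation design for
ridge-type count estimators:

- **Regressors.** x_ij = (1 − ρ²)^{1/2} z_ij + ρ z_{i,p+1} with z iid
  standard normal and the extra column shared by all regressors; each
  column has unit variance and every pair has correlation ρ². An
  adjacent-column variant ((1 − ρ)^{1/2} z_ij + ρ z_{i,j+1},
  `scheme="adjacent"`) is provided for comparison; it has neither
  unit variance nor constant pairwise correlation and is not used by
  default.
- **Truth.** β is the equal-components vector 1/√(p+1), so
  Σβ_j² = 1 with the intercept included in the normalization — the
  most common convention in this literature. The alternative
  (eigenvector of the largest eigenvalue of X′X) is available via
  `gen_beta(..., scheme="max_eigenvector")`. Note that under unit
  norm the full-shrinkage MSE is exactly β′β = 1; published tables in
  this literature sometimes show full-shrinkage values near p+1,
  suggesting a normalization that excludes the intercept — both
  conventions are available, neither is asserted in tests.
- **Responses.** "Quasi-Poisson" fixes only two moments, so any
  sampler matching them is admissible. We draw negative binomial with
  per-observation size θ_i = μ_i/(γ−1), giving Var = γμ_i exactly and
  reducing to Poisson at γ = 1. Under-dispersion (γ < 1) is rejected.
- **Scoring.** MSE(β̂) = (1/V) Σ (β̂_i − β)′(β̂_i − β) over V
  replications. Replications where IWLS fails to converge (or where a
  rule cannot be evaluated) are dropped and counted per estimator
  rather than imputed; at the default settings this is rare except in
  the most extreme corner (small n, γ = 6, ρ = 0.99).
- **Randomness.** Each replication uses its own counter-based RNG
  substream (SeedSequence([cell_seed, rep])), so results do not
  depend on estimator evaluation order, and per-cell seeds are
  derived from the master seed by fixed hashing, so any sub-grid of a
  larger run reproduces identical numbers.

What passing the simulation tests shows — and does not show: the
generator produces exactly the stated moment structure with
unit-variance Gaussian regressors and a two-moment count sampler.
Real count data have skewed, discrete or clustered covariates,
zero-inflation, and dispersion that varies with the mean, none of
which the generator emulates; conclusions about estimator orderings
transfer to such data only qualitatively.

Problem sizes: the packaged checks run a reduced grid (p = 3, γ = 2,
ρ ∈ {0.90, 0.99}, n ∈ {50, 150}) at 200 replications per cell, which
is sufficient for the ordering and trend conclusions while keeping
the default run brief; the engine itself handles the full grid
(n up to 200, p up to 12, γ up to 6, four ρ levels, 2000
replications) unchanged via `run_grid`.

## Diagnostics

- **Condition index**: √(λ_max/λ_min) of X′X on the raw,
  intercept-augmented design, without centering or scaling (the
  orientation max/min makes CI ≥ 1; values above 30 indicate severe
  multicollinearity).
- **Hat matrix**: the model leaves the hat construction open for a
  weighted ridge fit; we use the standard
  H = W^{1/2}X(X′WX + kI)⁻¹X′W^{1/2} with W = diag(μ̂) at the fit's
  own means, which reduces to the familiar projection at W = I,
  k = 0 (trace p+1) and sends all leverages to zero as k → ∞.
- **PRESS**: (1/n) Σ χ_i²/(1 − h_ii)² with Pearson residuals
  χ_i = (y_i − μ̂_i)/√(γ̂μ̂_i) evaluated at the supplied fit's means
  (ridge means for a ridge fit) and leverages at the fit's k. The
  k = 0 case is the same code path, not a special case.
- **k-fold CV**: seeded shuffled partition (scikit-learn's KFold),
  refit of the chosen estimator on each training fold, and mean
  squared prediction error on the response scale over held-out
  observations. Fold count defaults to 5; both the count and the seed
  are free parameters, so externally published CV values that do not
  state them cannot be reproduced exactly and are not targeted.

## Known limitations

- No offsets/exposure, non-log links, user-supplied weights, or
  negative-binomial/Conway–Maxwell alternatives.
- No Liu-type or two-parameter shrinkage, and no generalized
  cross-validation for k.
- The analytic MSE of a data fit plugs in β̂_QLE for the unknown β;
  for nearly singular F that plug-in is itself noisy, which is
  precisely the regime where the ridge comparison matters — treat
  per-rule analytic MSEs on real data as relative, not absolute,
  measures.
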