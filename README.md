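# qpridge

Ridge regression for overdispersed count data.

When a count response has variance larger than its mean, the
quasi-Poisson model is the standard fix: it specifies only
E(y_i) = μ_i = exp(x_i′β) and Var(y_i) = γμ_i with overdispersion
γ ≥ 1, and estimates β by quasi-likelihood (IWLS). But when the
regressors are highly correlated, the weighted cross-product
F = X′ŴX is ill-conditioned and the quasi-likelihood estimator (QLE)
has enormous variance. `qpridge` implements the ridge (shrinkage)
remedy for this model:

    β̂_k = (F + kI)⁻¹ F β̂_QLE

together with

- sixteen data-driven rules (k1–k16) for choosing the biasing
  parameter k from the canonical form of the fit — the eigenvalues
  λ_j of F, the rotated coefficients α̂_j = T′β̂_QLE and the Pearson
  dispersion γ̂;
- the exact finite-sample bias, covariance, matrix MSE and scalar MSE
  of β̂_k, with the variance/squared-bias decomposition
  MSE(k) = M1(k) + M2(k);
- a Monte-Carlo engine that generates multicollinear regressors and
  quasi-Poisson counts and scores every estimator by
  MSE = (1/V) Σᵢ (β̂ᵢ − β)′(β̂ᵢ − β) against the truth;
- multicollinearity and prediction diagnostics: condition index
  √(λ_max/λ_min) of X′X, PRESS from Pearson residuals and ridge
  hat-matrix leverages, and k-fold cross-validation.

It is aimed at biostatisticians and epidemiologists modelling
overdispersed counts (disease counts, migration counts, event
frequencies) with correlated covariates.

## Worked example

Generate a synthetic dataset with severe multicollinearity
(pairwise regressor correlation 0.95² ≈ 0.90) and overdispersion
γ = 2, then compare all estimators:

```sh
qpridge fixtures --n 60 --p 3 --gamma 2 --rho 0.95 --seed 7 --out demo.csv
qpridge fit demo.csv --response y --all-rules
```

The table (abridged; analytic scalar MSE at each rule's k):

```
gamma_hat 1.78
 QLE k=    0.0000 mse=  0.4285
  k1 k=    2.1048 mse=  0.2845
  k5 k=   31.6171 mse=  0.0453
  k7 k=    9.3208 mse=  0.1216
 k12 k=   62.9041 mse=  0.0332
 k15 k=   41.6578 mse=  0.0383
```

Every ridge rule beats the unpenalized QLE's MSE of 0.43; here the
best is k12 at 0.033, a 13-fold reduction. The estimated dispersion
1.78 recovers the simulated γ = 2 up to sampling noise.

Diagnostics for one chosen rule:

```sh
qpridge diagnose demo.csv --response y --rule k7 --folds 5 --seed 1
# {"condition_index": 7.4429, "press": 1.0254, "cv": 4.8877, ...}
```

A Monte-Carlo comparison over a grid (CSV output, one row per cell
and estimator):

```sh
qpridge simulate --n 50 150 --p 3 --gamma 2 --rho 0.9 0.99 \
    --reps 200 --seed 42 --out results.csv
```

The same operations are available as library functions
(`fit_qle`, `fit_qprre`, `ridge_k`, `run_cell`, `run_grid`,
`diagnose`, ...); see the module docstrings.

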