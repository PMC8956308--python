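# Methods

`impovmap` measures the impoverishing effect of out-of-pocket (OOP)
health payments from household survey data and models its spatial
structure across districts. This note documents the statistical
machinery, the defaults and why they were chosen, and what the
synthetic-data tests do and do not establish.

## Impoverishment metrics

Each household carries a total annual consumption expenditure `E_i`, an
annual OOP health payment `O_i`, a size `s_i` and a survey weight
`w_i`. Per-capita expenditure is `x_i = E_i / s_i` before payments and
`x_i' = max(E_i - O_i, 0) / s_i` after; the floor keeps the poverty gap
bounded by the line when payments exceed consumption. Against a
per-person poverty line `z` (per-day lines are annualised once, by a
configurable factor defaulting to 365) the package reports the
Wagstaff–O'Donnell financial-protection measures:

* head count `H = 100 · Σ w_i s_i 1{x_i < z} / Σ w_i s_i`,
* poverty gap `G = Σ w_i s_i (z - x_i) 1{x_i < z} / Σ w_i s_i`,
* normalized gap `NG = 100 · G / z`,
* mean positive gap `MPG = 100 · NG / H` (undefined and reported as
  missing when `H = 0`).

Population-level ratios weight each household by `w_i · s_i` (the
persons it represents); with equal weights these reduce to the
unweighted person-level formulas, which the tests verify by brute
force. "Poor" uses the strict inequality `x < z` (ties count as
non-poor); this is arbitrary but fixed and configurable. A household is
flagged *impoverished by health payments* when `x_i >= z` and
`x_i' < z`; already-poor households pushed deeper are excluded from the
flag by default (an `include_deepening` switch exists) but their
deepening still shows in the gap measures. The head-count rise equals
the person-weighted share of flagged households exactly; the gap rise
additionally carries the deepening component.

Expenditure quintiles are cut at cumulative person-weight
20/40/60/80% on pre-payment per-capita expenditure, with tied
expenditures assigned to the lower quintile; the lower/higher
socio-economic dichotomy splits at a configurable cumulative share
(default 0.5).

**Reporting convention.** Published survey tables of this kind round
each metric to two decimals and derive the difference columns from the
rounded values; `to_report_frame()` follows that convention (round
first, then difference, then relative change) so its output matches
such tables cell-for-cell. Full-precision values remain available on
`ImpoverishmentTable` and are what every internal computation uses.

## Spatial weights and Moran's I

District contiguity is a binary symmetric matrix `W` (`w_ij = 1` iff
districts share a border) built from an edge list or a GAL
neighbour-list file; asymmetric GAL input is symmetrised with a
warning, and islands (`w_j+ = 0`) are permitted. Moran's I is

    I = (J / S0) · Σ_ij w*_ij (x_i - x̄)(x_j - x̄) / Σ_i (x_i - x̄)²

with `w*` either binary or (default) row-standardised — the dominant
convention for the test statistic, while the CAR prior below uses the
binary matrix as specified. Islands are dropped from the statistic
(their row-standardised weights are undefined) with a warning.
Inference is by random permutation of the values (default 9999 draws,
two-sided around the null expectation `-1/(J-1)`, with the `(extreme +
1)/(n + 1)` correction); when `J! ` is no larger than the requested
permutation count the permutation distribution is enumerated
exhaustively and the p-value is exact.

## The three outcome models

With `y_ij` the impoverishment flag of household `i` in district `j`:

* **single** — `logit π_ij = α + β'x_ij`;
* **multilevel** — adds `u_j ~ N(0, 1/τ²)` i.i.d.;
* **spatial** — `u` follows the Leroux CAR (LCAR) prior, the Gaussian
  Markov random field with precision
  `Ω = τ² (diag(1 - λ + λ w_j+) - λ W)`, equivalently full
  conditionals `u_j | u_-j ~ N(λ Σ_{i~j} u_i / (1 - λ + λ w_j+),
  1 / (τ² (1 - λ + λ w_j+)))`.

`λ ∈ [0, 1)` interpolates between independent effects (λ = 0, where the
spatial model reduces exactly to the multilevel one — verified at the
full-conditional level in the tests) and the intrinsic CAR (λ → 1,
excluded). An island's conditional precision is `τ²(1 - λ) > 0`, so
isolated districts need no special handling. Priors are the survey
defaults of this model family: `N(0, 100)` on every coefficient,
`Gamma(shape 1, rate 5e-5)` on the precision `τ²`, and `N(0, 100)` on
`logit λ`.

### Estimation

The original analysis family is usually fitted by integrated nested
Laplace approximation; this package instead targets the exact posterior
by MCMC, using Pólya-Gamma data augmentation: `ω_i ~ PG(1, ψ_i)` turns
each Bernoulli-logit term into a Gaussian in the linear predictor, so
`(α, β, u)` updates jointly from a single multivariate-normal full
conditional (block Cholesky, with the district cross-terms accumulated
by group sums), `τ²` has a conjugate Gamma update, and `logit λ` moves
by random-walk Metropolis with Robbins–Monro scale adaptation toward
0.44 acceptance during burn-in only (the adapted scale is frozen
afterwards, keeping the chain Markov). The `PG(1, z)` draws use the
exact Devroye alternating-series rejection sampler (numba-jitted,
~2.5M draws/s on one core), validated against the law's closed-form
mean `tanh(c/2)/(2c)` and variance. The logit-λ proposal is clipped to
±30 to keep the inverse logit off the floating-point 0/1 boundary; the
prior puts about 0.3% of its mass beyond the clip.

Defaults are 4 chains × 10,000 iterations with 2,000 burn-in, all
configurable; the tests and analysis scripts run far shorter chains
(stated in each) because the joint Gaussian coefficient update mixes
quickly — λ and τ² are the slow components, and R-hat above 1.05 on any
parameter is reported as a warning on the result, never an exception.
Survey weights are not used in the likelihood (an unweighted Bernoulli
fit, the standard Bayesian treatment); a weighted pseudo-likelihood is
deliberately out of scope. Identical seeds and configuration reproduce
draws bit-for-bit.

Summaries report posterior mean, sd and central 95% intervals;
odds-ratio intervals are the exponential of the coefficient interval
endpoints (exact under the monotone transform). DIC is `Dbar + pD` with
`pD = Dbar - D(θ̄)`, the deviance plugged in at the posterior means of
`(α, β, u)` on the linear-predictor scale (the Spiegelhalter
definition). `compare_dic` refuses to rank fits made on different model
frames. The district random-effect map exports per-district posterior
mean, sd and `P(u_j > 0)`.

### A note on the precision prior

`Gamma(1, 5e-5)` on `τ²` is nearly flat on the precision scale, and on
realistic survey sizes its posterior concentrates at very large `τ²`:
the district variance `σ²_u = 1/τ²` is driven toward zero and the
posterior for `λ` then reverts toward its diffuse prior (a 95% interval
spanning essentially (0, 1)). The analysis scripts reproduce exactly
this behaviour (`σ²_u ≈ 2e-4`, near-identical DICs across the three
models), which mirrors the published Malawi results. Because the
estimates of `σ²_u` under this prior are prior-dominated, the package
reports both `1/τ²` and the empirical variance of the posterior-mean
effects, and tests that need the field genuinely estimated (random-
effect-map recovery) use a weakly-informative `Gamma(1, 0.5)` instead —
stated where they do. The prior is a field on `LcarSpec` precisely so
users can make that choice consciously.

## Synthetic data

The generator emulates a stratified national household survey: 32
districts on a near-square rook-contiguity lattice (an optional
isolated district stands in for a lake island such as Likoma; the true
Malawi adjacency is not redistributable), household covariates drawn to
the 2016/17 survey margins (81% rural, 71% male-headed, mean household
size 4.29, mean facility distance 13.3 km, three regions assigned to
contiguous district blocks, …), lognormal per-capita expenditure with
`σ = 1.1` and the log-median placed so the national line sits at a
51.5% pre-payment head count (`Φ((log z - log m)/σ)` is then the exact
head-count oracle), a two-part OOP process (logit probability raised by
hospitalisation and chronic illness; conditional lognormal amount
scaled up ×4 and ×2 for those indicators, calibrated to a mean OOP in
the ~15k MWK range), survey weights lognormal around 1, and district
effects drawn exactly from the LCAR field at configured `(λ, τ²)`
(defaults λ = 0.5, τ² = 5000, matching the weak smooth field the study
reported).

Two modes trade realism for exactness of the ground truth. In
`outcome_first` (default) the binary outcome is drawn from the logistic
model and expenditures are then constructed consistently — flagged
households sit 2–10% above the line before payments and strictly below
after, unflagged households never cross — so the model-fitting truth is
exact and the recomputed crossing flag equals the simulated outcome
household-for-household. The socio-economic-status label is a covariate
in this mode and is not re-derived from the constructed expenditures.
In `expenditure_first` the money comes first and the flag is whatever
falls out, which is the mode for testing the poverty metrics against
the closed-form lognormal head count. The default intercept is
calibrated by root-finding so the mean outcome probability hits the
target rate (default 1.6%, the study's national-line figure); default
covariate effects are the study's adjusted odds ratios.

What passing the synthetic tests shows — and does not. The generator's
covariates are mutually independent given the margins, districts are
equally sized, the lattice is not the true Malawi adjacency, and
expenditure placement in `outcome_first` mode is stylised. Tests on
this data establish the *correctness of the estimators* (metrics match
closed forms and brute force; credible intervals cover known
coefficients at nominal rates; Moran's I matches exhaustive
enumeration and an independent R implementation), not the field
validity of any particular Malawi estimate, which would require the
original microdata and shapefile.

## Numerical choices and limitations

* Positive-definiteness of every LCAR precision is verified by Cholesky;
  `log|R(λ)|` in the λ-step reuses the graph-Laplacian eigenvalues
  (`R(λ) = (1-λ)I + λ(D-W)` shares the Laplacian's eigenvectors).
* Moran's I refuses constant vectors and all-island maps; the MPG of an
  empty poor set is missing, not zero; zero-OOP inputs skip the model
  stage of the pipeline with a logged warning rather than fitting a
  degenerate outcome.
* Perfect separation (a binary covariate level with a constant outcome)
  is detected and flagged on the result; under the `N(0,100)` prior the
  affected coefficient remains proper but drifts, and its R-hat warning
  will fire.
* The pipeline derives every stage seed from one top-level seed via
  spawned seed sequences, writes only plain CSV/JSON, and keeps wall
  time out of its outputs so reruns are byte-identical.
* Problem sizes in the analysis scripts (120 households per district,
  2 chains × 3,000 iterations) are the package's choice of a scale at
  which each script re-runs in about a minute; all are configurable up
  to the full survey scale.
* Not implemented by design: catastrophic-payment thresholds,
  design-based standard errors for the poverty measures, Laplace
  approximation, BYM/intrinsic CAR alternatives, WAIC/LOO, and any
  causal reading of the regression estimates.
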