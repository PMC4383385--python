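# Methods

## Model and assumptions

`medsem` works with a recursive three-equation linear system for a binary
exposure `X`, a continuous exposure-induced (intermediate) confounder `L`,
a continuous mediator `M`, a continuous outcome `Y`, and baseline
covariates `C`:

```
L = γ0 + γx X + γc'C + εl                                   Var εl = σl²
M = α0 + αx X + αl L + αc'C + αxl XL + εm                   Var εm = σm²
Y = β0 + βx X + βm M + βl L + βc'C
    + βmm M² + βll L² + βxl XL + βxm XM + εy                Var εy = σy²
```

Errors are mean-zero, homoscedastic, and uncorrelated with each other and
with the regressors of their own equation. Causal interpretation
additionally requires consistency, no interference, and conditional
exchangeability for `X` given `C` and for `M` given `(X, L, C)`. An `L·M`
product term in the outcome equation is rejected at specification time:
under either identification option below its coefficient would have to be
zero, so admitting it could only produce silently unidentified analyses.

Estimands (exposure contrast 1 vs 0, outcome units):

* `TCE  = E{Y(1)} − E{Y(0)}`
* `PNDE = E{Y(1, M(0))} − E{Y(0, M(0))}`
* `TNIE = TCE − PNDE`
* `CDE(m) = E{Y(1, m)} − E{Y(0, m)}`

Because `L` is caused by `X`, the natural effects are not nonparametrically
identified. Two parametric restrictions restore identification, and every
natural-effect computation is tagged with the one it uses:

* `robins_greenland` — no individual-level exposure–mediator interaction on
  the outcome; in this system it holds iff `βxm = 0`.
* `petersen` — the controlled direct effect does not vary with `M(0)`
  within covariate strata; here it holds iff `βll = βxl = 0`.

`CDE(m)` needs neither restriction and is always reported.

## Fitting

The system is recursive with uncorrelated errors, so each equation is fit
separately by OLS (`statsmodels`); this coincides asymptotically with full
information maximum likelihood while keeping the covariance structure
simple. The joint coefficient covariance is block-diagonal (cross-equation
blocks are zero under the independent-error assumption); where that matters
the case-resampling bootstrap is available for any estimator. Residual
variances use the unbiased `n − p` denominator — this matters because σ̂l²
enters the closed-form estimands through second moments. The fitter
refuses tables with missing values rather than dropping rows, so the
analysis `n` is always explicit, and reports rank-deficient designs by
naming the offending columns.

## Estimation by combination

The mediation-formula integrals average the fitted outcome mean
`E(Y | x, m, l, c)` over `l ~ f(l | x, c)`, independently `l′ ~ f(l | x′, c)`
and `m ~ f(m | x′, l′, c)`, then over the covariate distribution. Since the
outcome equation is quadratic with no `L·M` product and the `L` and `M`
laws are Gaussian, only the first two moments of `L(x) | c` and
`M(x′) | c` enter:

```
E[L(x)|c]   = μL(x,c) = γ0 + γx x + γc'c
E[L(x)²|c]  = μL² + σl²
E[M(x′)|c]  = α0 + αx x′ + (αl + αxl x′) μL(x′,c) + αc'c
Var[M(x′)|c]= (αl + αxl x′)² σl² + σm²
```

giving a closed form `η(x, x′, c)` for `E{Y(x, M(x′)) | c}`; the estimands
are contrasts of `η` averaged over covariates. This derivation is not
taken on trust: the test suite verifies it to 1e-6 against an independent
Gauss–Hermite quadrature oracle over a grid of 24 parameter sets, and to
within Monte Carlo error against g-computation by simulation. For the
minimal model it collapses exactly to the classical path-tracing products
`PNDE = CDE(m) = βx + βl γx` and `TNIE = βm(αx + αl γx)`.

Covariate standardization is empirical on a fit — the per-row closed form
is averaged over the observed covariate rows, which handles discrete and
continuous covariates uniformly. When evaluating the closed form at known
parameters against the truth oracle, standardization is instead
moment-based over the declared covariate distributions; this is exact for
independent covariates because `η` is quadratic in `c`. Whether a
moment-based or empirical average is used can move third-decimal digits on
any single sample; both are exact in their own terms.

Standard errors use the delta method: `SE = sqrt(g' V g)` with `g` the
gradient of the combination in the stacked coefficient vector (central
finite differences, relative step 1e-6 — the map is polynomial, so this is
accurate to ~1e-9) and `V` the block-diagonal OLS covariance. Uncertainty
in σ̂l² (which enters via `E[M(x′)²]` when `αxl ≠ 0`) is not propagated:
its contribution is `O(σ⁴/n)` and was invisible against the empirical
replicate SD in calibration tests; the bootstrap covers it when needed.
95% intervals are normal-approximation for delta SEs and percentile for
the bootstrap. The proportion mediated `TNIE/TCE` is always reported but
flagged unstable whenever the TCE interval covers zero.

## Monte Carlo g-computation

For each leg `(x, x′) ∈ {(1,1), (1,0), (0,0)}`, covariate rows are cycled
and `l`, `l′`, `m` drawn from the fitted Gaussian laws; the fitted
conditional outcome mean is accumulated rather than a simulated `Y`
(Rao–Blackwellization — unbiased for these estimands, which are means of
polynomial functions, and strictly lower Monte Carlo variance). Drawing
`l` and `l′` independently is valid because no `L·M` product exists; the
test suite confirms shared and independent draws agree within MC error.
`n_mc` counts total draws (default 100,000, at which the two estimation
routes agree to ~3 decimals); each leg has its own named child stream of
the mandatory seed, so legs are independent and runs are bit-reproducible.
`TNIE = TCE − PNDE` holds exactly by construction. Reported SEs for this
method are Monte Carlo integration errors; sampling uncertainty comes from
the bootstrap, which resamples raw rows (not residuals) and refits
everything per replicate, recording and excluding replicate failures
(warning above a 1% failure rate). Only Gaussian error models are
supported for the draws.

## Identification diagnostics

The unconstrained associational outcome model (all of `M²`, `L²`, `XL`,
`XM`) is fitted and two tests are run: a t test of `βxm = 0` and a 2-df
F test of `βxl = βll = 0` (per-term p-values are also reported, since
either may be of interest on its own). Rejecting the first excludes the
no-interaction assumption; rejecting the second excludes the constant-CDE
assumption; rejecting neither admits both (estimates can then be reported
under each); rejecting both means the natural effects are identified under
neither supported option, which triggers a warning. Classical OLS standard
errors are used (the model is fitted homoscedastic, matching the
generator). No multiple-testing correction is applied across the two
hypotheses: they choose between model parameterizations rather than flag
discoveries. α defaults to 0.05 and is configurable. Under Gaussian
errors both tests are exact in finite samples; the suite checks size
0.05 ± 0.02 and approximate uniformity of the p-values at n = 2,000.

## Sensitivity analysis (ρ′)

Unmeasured mediator–outcome confounding corresponds to `Corr(εm, εy) = ρ`.
In the outcome model that includes `M`, `βm` and `ρ` are collinear and
cannot be estimated jointly (the package refuses to try). The
identifiable quantity is `ρ′`: the correlation between the
mediator-equation residual and the residual of the reduced outcome
equation `Y ~ X + L (+ C)` that omits `M`. Since `ε′y = βm εm + εy`, its
population value is

```
ρ′ = (βm σm + ρ σy) / sqrt(βm² σm² + 2 βm ρ σm σy + σy²)
```

(`expected_rho_prime`; derived symbolically in the test suite and
recovered empirically within Monte Carlo error). A large `|ρ̂′|` means an
implausibly strong unmeasured confounder would be needed to nullify the
indirect effect, and the result object prints that interpretation rather
than a bare number. The confidence interval is a percentile bootstrap
(default B = 1,000). The construction assumes a mediator equation linear
in `(X, L, C)`, so a mediator-equation interaction term is rejected.
Baseline covariates are retained in both reduced equations by default
(making ρ′ conditional on `C` as well); `include_covariates=False` gives
the covariate-free variant.

## Synthetic data generator and truth oracle

The generator draws from the structural model above with defaults chosen
to emulate a birth-cohort mediation analysis on standardized scales:
exposure prevalence 0.19; two Bernoulli background covariates
(p = 0.55, 0.13); unit error variances; coefficient set γ0 = 0.1,
γx = 0.13, αx = 0.55, αl = 0.05, αxl = 0.1, βx = 0.07, βm = 0.31,
βmm = 0.04, βl = 0.03, βll = 0.03, βxl = 0.08, βxm = 0 (so the
no-interaction constraint holds in truth and the constant-CDE one does
not), with small covariate coefficients of matching magnitude. Options:

* `rho` — correlation of `(εm, εy)`, the unmeasured mediator–outcome
  confounding device (default 0);
* `u_config` — an unmeasured confounder `U ~ N(0, sd_u²)` of the L–Y edge,
  entering `L` with `lambda_l` and `Y` with `lambda_y`; `U` is excluded
  from the returned table and recorded only in the truth object;
* `x_logit_c` — optional logistic dependence of the exposure on
  covariates; by default `X` is marginally Bernoulli, independent of `C`,
  which keeps the truth integrals simple.

All randomness flows from one seeded generator in a fixed draw order, so a
config reproduces its table byte-for-byte.

The truth oracle computes exact estimands for any parameter set by tensor
Gauss–Hermite quadrature (default order 40; order-doubling changes results
by < 1e-8) over the Gaussian laws of `L(x)`, `L(x′)` and `M(x′)`, with
exact enumeration over Bernoulli covariates and quadrature over normal
ones. It is deterministic and shares no code path with the closed-form
moment algebra, so oracle and estimator errors are independent. With `U`
active, the truth uses the effective variance
`σl² + lambda_l² sd_u²` — valid because `U` shifts no conditional mean and
the outcome equation has no `L·M` product. With `ρ ≠ 0` the structural
truth is unchanged (error correlation biases estimation, not the
estimands), which is exactly the scenario the ρ′ analysis is meant to
flag.

What the generator does **not** emulate: non-Gaussian or heteroscedastic
errors, measurement error, missing data, binary/ordinal mediators or
outcomes, exposure misclassification, or model misspecification beyond the
declared term sets. Passing tests therefore demonstrate correctness of the
estimators under the assumed parametric model, not robustness to its
violation on real data.

## Numerical and design choices

* Exposure must be strictly 0/1 with both levels present; contrasts are
  1 vs 0.
* Error variances may be zero in the generator (degenerate draws collapse
  to conditional means); fitted designs built from noise-free endogenous
  variables are rank deficient and raise a collinearity error naming the
  columns rather than returning arbitrary coefficients.
* Delta gradients use relative step `1e-6·max(1, |θ|)`; tiny negative
  variances from finite-difference roundoff are clipped at zero; a
  non-finite covariance yields NaN SEs with a warning, never silent zeros.
* Monte Carlo settings require `n_mc ≥ 1000` and an explicit seed;
  bootstrap requires `B ≥ 199`.
* `assumption="auto"` on a fit resolves to whichever constraint set the
  fitted spec satisfies ("both" for the minimal model) and raises if
  neither holds; on raw data the diagnostics make the choice.

## Verified statistical properties

The test suite (see `tests/test_acceptance.py`) establishes, at the
generator's default conditions: exact path-tracing equivalence; agreement
of the two estimation routes within 3 MC-SEs at `n_mc = 100,000` under
both assumptions; closed form vs quadrature truth to 1e-6 over 24
parameter sets; mean bias of all four estimands within 2 MC-SEs of zero
and delta SEs within 15% of the empirical SD over 200 replicates at
n = 20,000; unbiasedness of PNDE/TNIE under an unmeasured L–Y confounder
(`lambda = 0.7`) even though β̂l is biased by far more than its Monte
Carlo uncertainty — the practical payoff of the parametric identification
argument, since "no omitted influences" on the L–Y edge turns out not to
be needed for the natural effects; recovery of the analytic ρ′ value (e.g.
0.4472 at βm = 0.5, unit variances) within 2 MC-SEs over 100 replicates at
n = 10⁴; and size 0.05 ± 0.02 for both identification tests under the
null over 500 replicates. Replication counts and sample sizes were fixed
a priori at these values as a balance of statistical resolution and desk
runtime.

## Known limitations

* Linear-Gaussian only; no binary/ordinal endogenous variables, latent
  variables, measurement models, or multigroup systems.
* Natural effects under intermediate confounding remain parametrically
  identified at best; the diagnostics can only say which restriction the
  data fail to reject, not that it is true.
* Cross-equation coefficient covariance is assumed zero in delta SEs
  (bootstrap otherwise), and σ̂² uncertainty is not in the delta gradient.
* The sensitivity analysis addresses unmeasured M–Y confounding only, not
  unmeasured X–Y or X–M confounding.
* Effect definitions are linear contrasts; ratio scales are out of scope.
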