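# Methods

`mltve` decomposes an exposure–outcome association in two-level (individuals
nested in groups) data into a direct effect and per-third-variable indirect
effects, separately at the individual (level 1) and group (level 2) scale.
"Third-variable" covers both mediators and confounders: the algebra of the
decomposition is the same; only the causal reading differs.

## The model system

Let `Y_ij` be a continuous level-1 outcome for individual `i` in group `j`,
`X_ij` / `X_.j` level-1 / level-2 exposures, `M_ijk` (k = 1..K) level-1 and
`M_.jl` (l = 1..L) level-2 third-variables, and `Z` optional covariates.
Three layers of generalized additive models are fitted, each predictor
entering through a transformation vector `f(.)` (identity, log, polynomial,
natural cubic spline, two-piece hinge, indicator coding, or user-supplied —
all first-order differentiable):

1. level-2 third-variables (one record per group, no random effects):
   `g_l(E[M_.jl]) = a_0l + sum_e a_2le' f(X_.je)`
2. level-1 third-variables (random intercept per group):
   `g_k(E[M_ijk]) = a_00k + r_0jk + sum_e a_1ke' f(X_ije) + sum_e a_2ke' f(X_.je)`
3. the outcome (random intercept per group):
   `E[Y_ij] = b_00 + r_0j + sum_e b_1e' f(X_ije) + sum_e b_2e' f(X_.je)
              + sum_k b_3k' f(M_ijk) + sum_l b_4l' f(M_.jl) + c' Z`

Links are identity for continuous targets and logit for binary ones; the
outcome link is identity in this version (the link abstraction is in place
for future extension). Random effects are intercepts only — no random
slopes, no crossed effects, at most two levels. Path legibility is
structural: a group-level variable may affect an individual-level one but
not vice versa, so level-2 third-variable models contain only level-2
exposures and a level-1 exposure can only act through level-1
third-variables.

## Effect definitions and closed forms

The total effect is the changing rate of the expected outcome in the
exposure — the exact derivative for a continuous exposure, the unit-step
difference quotient `(f(x + u*) - f(x))/u*` with minimum unit `u*` (default
1) for a discrete one; for a 0/1 exposure this is `f(1) - f(0)` regardless
of the observed value. On the additive system the decomposition has closed
forms (see the `effects` module docstring): each indirect effect is the
product of the exposure-to-third-variable changing rate (through the link's
inverse derivative) and the third-variable-to-outcome changing rate, and
`TE = DE + sum IE` holds identically. For a level-2 exposure acting through
a level-1 third-variable, the outcome-side factor is averaged over the
group's individuals before the product is taken. Averages (ATE/ADE/AIE) are
over level-1 records for level-1 effects and unweighted over groups for
level-2 effects; relative effects are component/ATE and are reported as
undefined when |ATE| < 1e-12.

Two conventions deserve note. First, the link inverse-derivative is
evaluated at the *fitted linear predictor* (random-intercept prediction
included), which is the chain-rule-exact choice; under the identity link
this is vacuous. Second, covariates `Z` are adjusted for in every fit but
contribute nothing to the effect formulas.

On a grid of exposure values (for effect-vs-exposure curves), factors that
depend on the data rather than the exposure value — the outcome-side
derivative of each third-variable and, for logistic third-variables, the
other predictors' contribution to the linear predictor — are held at their
observed averages. Under identity links the grid curves coincide with the
closed forms.

## Estimation

* Linear random-intercept models (the level-1 third-variable and outcome
  layers) are fitted by REML. Because the random effect is a single
  intercept, the marginal covariance is closed-form and both the fixed
  effects and the residual variance profile out, leaving a one-dimensional
  REML criterion in the variance ratio that is minimized by a coarse
  log-grid plus bounded refinement. This purpose-built solver is exact for
  this model class, runs in about a millisecond at the default study size
  (which is what makes bootstrap studies with tens of thousands of refits
  feasible), and is cross-checked against `statsmodels.MixedLM` (REML) in
  the test suite. A variance estimate below 1e-8 (as a ratio) is reported
  as exactly 0 with a boundary flag in the convergence report — a warning,
  not an error.
* Level-2 third-variable models are single-level GLMs via `statsmodels`
  (Gaussian or binomial); separation is detected by divergent coefficients
  (|coef| > 50) or a constant response and raised as a convergence error.
* Binary level-1 third-variables use a random-intercept logistic model
  fitted by maximum likelihood with adaptive Gauss–Hermite quadrature
  (15 nodes; per-group mode and curvature found by Newton's method,
  vectorized across groups), optimized by BFGS over the fixed effects and
  log standard deviation. It is cross-checked against `lme4::glmer`
  (nAGQ = 15) in the tests.
* Rank deficiency is detected by pivoted QR before fitting and reported
  with the offending column names.

## Design preparation

Transformations are fitted once on the analysis data: spline interior knots
at quantiles (df basis columns use df − 1 interior knots), boundary knots at
the data min/max, natural (linear) extrapolation beyond them; the hinge pair
`(min(x, t), max(x − t, 0))` takes its derivative from the left piece at
exactly `x = t`; categorical variables are reference-coded against the first
sorted level. Derivatives are analytic for every built-in transform; a
user-supplied transform without a derivative falls back to central finite
differences with step `1e-6 × max(|x|, 1)`. Rows with missing required
fields are dropped with a logged count. Variables are neither centered nor
scaled before transformation.

## Bootstrap inference

Confidence intervals come from a cluster bootstrap that keeps every group
and resamples, within group `j`, `n_j` records with replacement — group
sizes and all level-2 variables are preserved exactly. Each replicate is
refitted with the transformation fits (e.g. spline knots) frozen from the
original data, so the estimand does not drift across replicates. Defaults:
B = 500 replicates, 95% percentile intervals (linear interpolation of order
statistics), bootstrap SE = replicate standard deviation. Per-replicate
random streams are spawned from the master seed, making any subset of
replicates reproducible independently of execution order. Non-converged
replicates are dropped and logged, never redrawn; more than 20% failures
aborts with advice to simplify the model.

**Known limitation.** Because every group is kept, replicates cannot express
between-group sampling variability. Intervals for quantities driven by
coefficients of *group-level* predictors (the level-2 direct effect, and the
indirect effect through a level-2 third-variable) are therefore
anti-conservative: with group-level outcome variance `v2` and group size
`n`, the bootstrap understates the standard error of such coefficients by
roughly `sqrt((v2 + v1/n)/(v1/n))` — about a factor 2 at the default study-1
settings, giving a null exclusion rate near 40% instead of 5% for the
indirect effect through the binary group-level third-variable (measured over
200 null datasets; the corresponding acceptance test documents this and
fails by design). Indirect effects gated by level-1 coefficients (`ie1`,
`ie2.1` under a null mediator-outcome path) are not affected — their
measured null exclusion rates are 8–9%. Interpret level-2 direct effects and
`ie2.2`-type intervals with caution; a scheme that also resamples groups
would fix this but is outside the method as specified.

## Synthetic-data generators

`Sim1Config`/`gen_sim1` emulate a linear 2 → 1 → 1 design with variables at
both levels: binary level-1 exposure (Bernoulli 0.5), standard-normal
level-2 exposure, binary level-2 third-variable through
`logit P(m2 = 1) = 0.8 x2`, continuous level-1 third-variable
`m1 = u0 + 0.8 x2 + 0.8 x1 + e0` (`u0` variance 0.5, `e0` variance 1), and
outcome `y = u1 + b1 x1 + b2 x2 + b3 m1 + b4 m2 + e1` with `e1` variance
`v1` (1 or 5) and `u1` variance `v2 = v1/5`, fixing the outcome-error
intraclass correlation at 1/6 ≈ 0.17. Defaults: 600 records in 30 groups of
20 and `(b1, b2, b3, b4) = (0.39, 0.39, 0.59, 0.59)`.

`Sim2Config`/`gen_sim2` add nonlinearity: `x1 ~ N(0, 0.5)`,
`x2 ~ chi-square(2)` (group level),
`m = u0j1 + 1.2 x1^2 + 1.2 x1 + gamma x2 + e` and
`y = u0j + 0.98 x1 + 0.98 log(x2) + 0.98 m + e'`. This design targets a
constant level-2 indirect effect of 1.2 × 0.98 = 1.176, which requires the
`gamma x2` term in the third-variable model; the generator therefore
defaults to `gamma = 1.2` (realizing that target) while `gamma = 0` gives a
variant with a zero level-2 indirect path. Under the derivative-based definitions the level-1 indirect
effect of this design is `0.98 (1.2 + 2.4 x)` — linear in the exposure with
average 1.176 over `N(0, 0.5)` — and the level-2 direct effect is the curve
`0.98/x`, whose population average over a chi-square(2) exposure does not
exist; `true_effects` reports that average as NaN and the curve is exposed
through `true_system` + `effect_grid`.

`true_effects` evaluates the closed-form decomposition at the generating
coefficients (the expectation over the standard-normal exposure in the
logistic path is taken by 80-node Gauss–Hermite quadrature), and
`true_system` materializes a model system carrying the true coefficients so
the same effect code produces true curves. `run_operating_study` runs
generate → fit → bootstrap → interval cycles and tallies, per component, the
proportion of intervals excluding zero — a sensitivity when the true
component is nonzero, one-minus-specificity when it is zero (20 replicates
per cell by default).

What the generators do *not* emulate: unbalanced group sizes, missing data,
covariates, non-Gaussian outcomes, level-1/level-2 exposure correlation, and
model misspecification (the fitted transformations match the generating
ones). Passing tests therefore demonstrate correctness of the estimation and
decomposition machinery under the stated designs, not robustness of the
method on arbitrary real data.

## Problem sizes used by the test suite

Large-sample recovery uses one 2000-group × 20 study-1 dataset; the null
coverage study uses 200 datasets at the default size with B = 100; the
power-monotonicity study uses 20 replicates × B = 100 per
mediator-outcome-coefficient cell; slope-recovery checks use 50 replicates
of the default design. These sizes give Monte-Carlo error comfortably inside
the 3-standard-error acceptance margins while keeping the full suite at a
few minutes.

## Other limitations

* Two levels of nesting only; the outcome must be level 1.
* No automatic discovery of transformations — the analyst chooses `f(.)`.
* No counterfactual-framework natural direct/indirect effects and no
  time-to-event outcomes.
* Percentile intervals only (no BCa or studentized bootstrap).
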