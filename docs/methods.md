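# Methods

## Model and estimands

All development strategies fit the same logistic regression
`P(Y_i = 1) = expit(b0 + sum_p b_p x_ip)` to a development cohort of
`n` observations and `P` candidate predictor parameters.  The quantity
of interest is not the coefficients themselves but the model's
predictive performance in new data from the same population:

- **calibration slope** — the slope of a logistic regression of
  observed outcomes on the model's linear predictor (plus intercept) in
  validation data; 1 is ideal, below 1 indicates overfitting;
- **calibration-in-the-large (CITL)** — the intercept of the same
  regression with the slope fixed at 1; 0 is ideal, below 0 means
  overall risk is overestimated;
- **AUC** — pairwise concordance probability (ties count 1/2);
- **Cox–Snell R²** — `1 - exp((2/n)(LL_null - LL_model))`, bounded above
  by `max(R2) = 1 - (phi^phi (1-phi)^(1-phi))^2` at outcome proportion
  `phi`;
- **Brier score** — mean squared difference between predicted
  probability and outcome.

## Minimum sample size

Criterion 1 targets an expected uniform shrinkage factor `S` (default
0.9): `n = ceil(P / ((S-1) ln(1 - R2/S)))` with `R2` the anticipated
Cox–Snell R².  Two routes pre-specify `R2`: the conservative
`0.15 * max(R2)` rule, or the adjusted R² of a full model fit on
population-scale data, `R2 = (1 - P/LR)(1 - exp(-LR/n))` with `LR` the
likelihood-ratio statistic against the intercept-only model.  Criteria
2 (small apparent-vs-adjusted R² difference, re-expressed as
`S = R2/(R2 + 0.05 max R2)` in the same formula) and 3 (overall risk
within ±0.05: `n = (1.96/0.05)^2 phi(1-phi)`) follow the published
criteria they come from and are optional; under every setting used here
criterion 1 dominates by a wide margin.  All sizes are rounded up, since
a minimum must satisfy the inequality.

## Estimation strategies

- **MLE**: Newton/IRLS with step-halving; convergence at
  `max |score| < 1e-8`.  Separation is detected (coefficient blow-up
  during iteration, or converged scores with saturated and perfectly
  classifying probabilities) and reported as an error rather than
  returning huge finite coefficients.
- **Closed-form uniform shrinkage**: `S = 1 + P/(n log(1-(1-e^{-LR/n})))`.
  The inner logarithm equals `-LR/n` *exactly*; we evaluate it collapsed
  to avoid the `1-(1-x)` cancellation, so the implementation is
  literally `1 - P/LR`.  Slopes are multiplied by S and the intercept
  re-estimated by a one-parameter likelihood fit with the shrunken
  linear predictor as offset — its score equation forces the mean
  predicted probability to equal the observed outcome proportion.
  `LR <= P` yields `S <= 0` (warned, returned as-is).
- **Uniform bootstrap shrinkage**: for each of B (default 500) resamples
  with replacement, refit (replicating all modelling steps), compute the
  linear predictor on the original data, regress the original outcomes
  on it; S is the mean of the B slopes.  Resamples with a single outcome
  class are redrawn and logged; fit failures are skipped with the run
  failing above 10% skips.  With the default plain-MLE refit, the B fits
  are solved as one batched weighted Newton system (a resample is a
  multinomial weight vector on the original rows), drawing identical
  resamples to the sequential loop.
- **Firth**: modified-score Newton iterations — score augmented by
  `h_i(1/2 - p_i)` with `h_i` the working hat values — maximising
  `LL + 0.5 log|I(beta)|`, step-halving on the penalised likelihood,
  max 50 iterations at tolerance 1e-8.  The intercept is then re-fit
  with the penalised slopes as offset so the overall outcome proportion
  is preserved.
- **Lasso / ridge**: penalised likelihood with the intercept unpenalised
  and `lambda` on the per-observation average negative log-likelihood
  scale: the objective is `(1/n) sum nll_i + lam * sum |b_p|` (l1) or
  `+ lam * sum b_p^2` (l2); multiply `lam` by n for the summed form, and
  note the l2 quadratic is `lam * b^2`, not `lam/2 * b^2`.  Predictors
  are standardised (mean 0, sd 1) internally and coefficients returned
  on the original scale.  The l1 grid is 100 log-spaced points from
  1e-4 to `lambda_max = max_p |x_p'(y - ybar)|/n` (the smallest penalty
  zeroing every slope); the l2 grid uses the same construction anchored
  at 1000× the l1 `lambda_max` (no finite l2 penalty gives an all-zero
  fit; the multiplier matches common software convention).

## Cross-validation

`lambda` is selected by 10-fold CV minimising held-out binomial
deviance, folds stratified by outcome (preventing empty-event folds at
20% prevalence and n ≈ 900).  Repeated CV draws a fresh partition per
repeat and averages the deviance curves before minimising.  The one-SE
variant returns the largest lambda within one standard error (computed
across the fold-level deviances) of the minimum.

For speed, all folds × repeats are swept simultaneously down the
descending grid by proximal-Newton path tracking: the gradient is exact
at every grid point, while the weighted-curvature matrix is refreshed
only every 8 grid points or after a large step (l1 steps solve the
local quadratic by coordinate descent, O(P²) per sweep).  Against
exactly-converged per-fold fits this tracks the deviance curve to
~3e-4–6e-4 (cross-validation noise is orders of magnitude larger) and
selects the identical grid point in our checks; the model finally
refit at the selected lambda is always fully converged.  CV
standardises the predictors once on the full development data rather
than per training fold — folds are random subsets, so fold-wise moments
differ negligibly at the sample sizes involved, and a shared design
matrix is what makes the batched sweep possible.

## Data-generating mechanism

Populations have P = 10 predictors per row, i.i.d. multivariate normal
with unit variances and common pairwise correlation rho (0 by default;
0.5 reproduces the correlated sensitivity setting via a shared-factor
construction).  Outcomes are Bernoulli with log-odds `b0 + x'beta`,
with two slope patterns: all-true (six at log 1.1, two at log 1.5, two
at log 2) and five-noise (three at log 1.1, one each at log 1.5 and
log 2, five zeros).  `b0` is solved deterministically: the linear
predictor is univariate normal with variance
`(1-rho) sum b² + rho (sum b)²`, so the marginal prevalence is a 1-D
Gaussian integral, evaluated by 120-node Gauss–Hermite quadrature and
inverted with Brent's method to 1e-12 — no Monte-Carlo noise enters the
generating model.  Development cohorts are drawn without replacement;
the complement is the validation set.

What the generator does *not* emulate: non-linear or interaction
effects, missing data, measurement error, categorical predictors, or
covariate distributions with skew/outliers.  Passing tests therefore
demonstrate correctness of the estimation and validation machinery
under a well-specified linear-logistic world, not robustness of any
strategy to real-data pathologies.

## Simulation study

Eight scenarios cross prevalence (0.2/0.5), the R² pre-specification
route (population-R² vs 15%-of-max) and the slope pattern.  Each
iteration regenerates the population, recomputes the minimum n (the
population-R² route refits the full model on the fresh population),
splits, develops every strategy, and evaluates on the held-out
complement.  Randomness is organised as one root seed plus
(scenario, iteration, stream) spawn keys, so results are independent of
execution order and safely parallelisable.

The full-scale design is 500 iterations × 10⁶ population × 500 inner
bootstraps × 100 CV repeats.  Desk-scale runs shrink these through
`StudyConfig` (or `StudyConfig.scaled`), stamping the scale factor into
every output row.  The package's own reproduction runs use: scenario
medians at 200 iterations with a 101,000 population and validation
capped at 100,000; the all-scenario variability figure at 100
iterations, 100 inner bootstraps and 20 CV repeats.  Capping the
validation set (default 10⁵) leaves the estimands essentially
untouched: a random development sample plus capped complement from a
101k-row i.i.d. population is distributionally identical to the same
draw from 10⁶ rows, and the calibration-slope standard error at 10⁵
validation rows (~0.005) is negligible against the across-iteration
spread (~0.09).  The main cost of the smaller population is extra noise
in the population-R² route's estimated R² (and hence in the per-
iteration n), which slightly widens those scenarios' distributions.

## Bootstrap internal validation

Apparent performance is measured in-sample; each of B resamples (with
replacement, un-stratified; single-class resamples redrawn with
logging) replays the complete development procedure — including
re-estimating S or re-selecting lambda — and its optimism is the
in-resample performance minus its performance on the original data.
Adjusted draws are `apparent - optimism_b`; the point estimate is their
mean and the interval their 2.5/97.5 percentiles.  B defaults to 100
(the smaller illustrative setting); ≥ 500 is recommended when runtime
allows.  The variability report flags a strategy when more than 50% of
its adjusted calibration-slope draws leave the 0.9–1.1 band — an
explicit, configurable operationalisation of "commonly outside 0.9–1.1";
both the band and the fraction are parameters.

## Numerical conventions and edge cases

- Quantiles use linear interpolation between order statistics (numpy's
  default), so R/Python replications agree.
- Degenerate linear predictors (e.g. an l1 fit that zeroed every slope)
  yield NaN calibration slopes/AUCs, logged and excluded from summaries
  with counts recorded, rather than raising inside simulation loops.
- Validation-set Cox–Snell R² evaluates the Bernoulli likelihood of the
  predicted probabilities against the held-out outcomes; in-sample on
  an MLE fit this reduces exactly to `1 - exp(-LR/n)`.  Probabilities
  at exactly 0/1 discordant with the outcome are clipped at 1e-15 with
  a warning.
- Cohorts serialise to headered CSV (`x1..xP, y`); study configurations
  to YAML.

## Known limitations

- Only binary outcomes and linear predictor effects; no variable
  selection beyond the lasso's implicit one; no elastic-net mixtures or
  group penalties; no missing-data handling (complete cases assumed).
- The one-SE rule is provided for both penalties but, consistent with
  its known behaviour at these sample sizes, produces materially
  underfit (slope ≫ 1) models; it is not part of the default method
  set.
- Criteria 2 and 3 of the sample-size module implement the cited
  formulas but are not exercised by the headline analyses (criterion 1
  always drives).
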