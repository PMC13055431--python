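# Methods

## Problem

PS-weighted analyses of observational cohorts stand or fall with the
propensity model e(X) = P(A=1|X).  When e(X) is estimated with an
L1-penalized (LASSO) logistic regression tuned by cross-validation, the
penalty that predicts exposure best is usually *too strong* for causal
estimation: shrunken confounder coefficients leave residual imbalance and
bias the weighted effect estimate.  This package implements two remedies
studied jointly:

1. **Balance-metric undersmoothing** — scan the whole regularization path
   and pick the penalty whose weighted cohort best balances the
   covariates, instead of the deviance optimum;
2. **Synthetic negative-control-exposure (NCE) screening** — simulate
   exposures with no true outcome effect but the *fitted* confounding
   structure, and use them to measure whether a candidate analysis
   actually removes the measured confounding it claims to.

## Propensity model and path solver

The PS model is a linear-logit LASSO,
`minimize (1/n) * nll(b0, beta) + lambda * ||beta||_1`,
fitted over a descending log-spaced grid of 100 penalties from
lambda_max (the null-model entry point) down to `1e-4 * lambda_max`.
The solver is a pathwise IRLS/coordinate-descent scheme with warm starts,
active-set sweeps, sequential strong-rule screening, and a CSC sparse
kernel that engages automatically for mostly-zero designs (the sparse
binary covariates typical of healthcare-database studies).  Numerical
settings: inner convergence when every coordinate update moves the working
quadratic by less than 1e-8; at most 12 IRLS steps per grid point with an
early exit when the penalized objective stalls (coefficients can drift
along quasi-separated directions without changing the fit); the path
freezes once an additional grid point improves in-sample deviance by less
than 1e-5 of the null deviance (glmnet's `fdev` rule).  At `lambda = 0`
the solver reproduces the unpenalized logistic MLE to ~1e-8, and on
matched grids its penalized objective agrees with R's glmnet to ~1e-6 in
the region of the cross-validated penalty; both equivalences are enforced
in the test suite.

Cross-fitting uses K = 5 exposure-stratified folds.  The grid is computed
once on the full data and reused across folds, so each grid point has both
a full-data coefficient vector and an *out-of-fold* predicted probability
for every subject (each subject's propensity comes from a model that never
saw it).  All weighting — for tuning and for estimation — uses the
out-of-fold propensities, clipped into `[1e-6, 1 - 1e-6]`.  Binary designs
are not standardized (they share a scale, and coefficients stay in
log-odds units); continuous or mixed designs are scaled to unit variance
internally and coefficients are returned on the original scale.

## Balance metrics and tuning rules

For covariate k with weighted prevalences p1 (exposed) and p0 (unexposed),

    s_k = (p1 - p0) / sqrt((p1*(1-p1) + p0*(1-p0)) / 2),

with the denominator evaluated on the *unweighted* sample (the usual
convention: the scale stays fixed while the penalty varies; a fully
weighted denominator is available by option, since the convention used in
the original simulation study is not recoverable).  For non-binary
columns the same formula applies with arm variances in place of p(1-p).
Columns with zero variance in both arms contribute s_k = 0 and stay in
the denominator count d.

Two scalar metrics summarize a weighted cohort: `max_k |s_k|` and
`(1/d) sum_k |s_k|`.  The tuning rules are:

* `cv` — minimize mean out-of-fold binomial deviance (no 1-SE rule);
* `max-smd` / `mean-smd` — minimize the corresponding balance metric over
  the grid, ties within 1e-10 broken toward the largest penalty.

A caveat the test suite makes explicit: with ~900 spurious covariates the
max metric is dominated by their sampling noise (the max of ~1000 null
SMDs sits near its 3-sigma envelope regardless of the penalty), so on a
single replicate the max-SMD choice can sit *above* the CV optimum; the
undersmoothing behaviour is a statement about replicate averages, not
every draw.

## Weighting schemes and estimation

IPW `A/e + (1-A)/(1-e)`, matching weights `min(e,1-e)/e` resp.
`min(e,1-e)/(1-e)`, and overlap weights `A(1-e) + (1-A)e`.  Effects are
Hájek (normalized) weighted mean differences; normalization is required
for MW/OW and is the dominant applied convention for IPW.  Standard
errors come from an HC3 sandwich on a weighted least-squares regression
of the outcome on the exposure indicator (the original study does not
state its interval construction; coverage claims here are therefore
qualitative).  Kish effective sample sizes per arm accompany every
estimate.

## Synthetic negative-control exposures

Generation follows a fit → calibrate → restrict → oversample → regenerate
sequence:

1. fit a CV-tuned LASSO PS on the full cohort (*no* undersmoothing: the
   target here is e(X) itself, and undersmoothing does not improve
   convergence to e(X), only to the causal parameter);
2. choose the odds multiplier c so that g(X) with
   `logit g = logit ê + log c` has a target marginal prevalence among the
   unexposed — by default the original cohort's exposure prevalence, so
   synthetic arm sizes resemble the study (c = 1, i.e. no shift, is
   available by option; the constant used by the original authors is not
   recoverable);
3. keep only unexposed rows (their outcomes are unaffected by the real
   exposure under consistency);
4. bootstrap-oversample those rows with replacement up to the original
   study size;
5. draw Z_i ~ Bernoulli(g(X_i)) independently for every bootstrap row.

Exposure is *regenerated*, never resampled: resampling would both inherit
LASSO-on-bootstrap pathologies and create nonpositivity cells.  Because Z
depends on the data only through X, `Z ⫫ Y | X` holds exactly and the
true Z effect is zero in every synthetic cohort, so the mean Z-effect
estimate of a candidate analysis over B cohorts is that analysis's
*synthetic bias*.  Percent bias is taken relative to the unadjusted
contrast (exactly 100 by construction).  An analysis is flagged when its
|synthetic bias| exceeds 3 Monte-Carlo SEs *and* 10% of the unadjusted
magnitude.  The screen detects bias only — the synthetic cohorts carry the
confounding structure of the unexposed counterfactual population, not the
full study, so they must not be used to rank unbiased analyses by
efficiency.  A candidate that fails (e.g. single-class Z) on more than 10%
of cohorts is reported as failed rather than silently averaged.

## Simulated designs

**Design 1** (sparse high-dimensional, healthcare-database-like): 1000
i.i.d. Bernoulli(0.2) covariates; the first 100 enter both a logistic
exposure model and a logistic outcome model with coefficients drawn i.i.d.
uniform on [0, 0.693] (odds ratios 1 to 2); the other 900 are spurious.
Intercepts are calibrated by monotone root-finding on the realized linear
predictor so that exposure prevalence is 30% and outcome incidence 5% (the
design states the targets but not the intercepts).  The exposure effect is
null: the outcome model never sees A.  The coefficient draw and the data
draw use separate seeded streams, so changing n does not change the DGP;
by default one coefficient draw is shared across replicates (a per-
replicate redraw is available by flag — the original description is
ambiguous on this point, and under a null effect the choice does not
change the bias targets).

**Design 2** (low-dimensional nonlinear):
X1..X5 ~ uniform(-2,2), X6..X10 ~ Bernoulli(0.6);
`e(X) = expit(X2^2 - exp(0.5 X1) - X3 + X4 - exp(0.5 X5) + X6 + X7)`;
`Y = -2 X2^2 + 2 X1 + 2 E[X2^2] + X2 + X1 X2 + X3 + X4 + 2 X5^2
- 2 E[X5^2] + eps` with E[X2^2] = E[X5^2] = 4/3 (the two centering
constants cancel exactly) and eps ~ N(0, 0.1) read as *variance* 0.1
(SD ≈ 0.3162; an option flips the reading to SD — the N(mu, sigma^2)
convention is the more common one, and under the null the choice does not
affect bias targets).  X8–X10 are spurious.  For this design the PS model
is fitted on a zero-order indicator basis expansion (below).

What these generators deliberately do not emulate: covariate correlation
(design 1 draws covariates independently), treatment effect heterogeneity
or any non-null effect, measurement error, and unmeasured confounding.
Passing tests therefore demonstrate the estimators' behaviour under
measured confounding with known structure, not robustness to real-data
pathologies outside that scope — in particular, the NCE screen by
construction cannot detect confounding the PS model never observed.

## Indicator basis (zero-order HAL-style)

Continuous covariates contribute indicator columns `I(x >= knot)` at
empirical-quantile knots (default budget 25 per covariate), binary
covariates their identity column, plus all interaction products across
distinct covariates up to degree 2; duplicate and constant columns are
dropped, and stored column specs allow exact re-evaluation on new rows.
This is a deliberate simplification of the full HAL default basis (knots
at every observed value); the exact knot budget used in the original
study is not recoverable, so design-2 claims are exercised qualitatively
(estimator orderings), not at bit level.

## Replication experiments and problem sizes

`run_replication` draws replicate cohorts, fits one cross-fitted path per
replicate shared by all tuning rules and weight schemes, and (optionally)
screens the same candidates on synthetic cohorts built from each
replicate.  Percent bias aggregates as the ratio of mean biases — more
stable than averaging per-replicate ratios when the unadjusted bias of a
replicate passes near zero.  All seeds derive from a single master seed
via named SeedSequence spawns; reruns are bit-for-bit reproducible.

The test suite exercises scaled-down versions of the replication study,
chosen as desk-scale problem sizes: design-1 orderings over 6 replicates
at n = 5000 and 1 at n = 20 000, on a 40-point grid truncated at
`lambda_min_ratio = 1e-3` (the selected penalties sit well above that
floor); the synthetic screen over 2 replicates with B = 5 cohorts on a
25-point grid; fidelity-vs-n checks at n ∈ {1200, 4800}.  The
full-scale study (500 replicates × 500 bootstrap cohorts at n up to
40 000) is available through the same configuration object and the
`undersmooth replicate --scale full` command.  At these reduced scales
Monte-Carlo error is not negligible; orderings asserted on replicate
means are the ones the larger study resolves clearly, and near-zero-bias
estimators can sit inside their own Monte-Carlo noise.

## Known limitations

* Coefficient-level agreement with glmnet degrades deep in the path
  (quasi-separated region); objective values and predictions remain
  close, and nothing downstream consumes deep-path coefficients directly.
* The max-SMD rule's noise floor (above) makes its single-replicate
  selections erratic in very high-dimensional null-heavy designs.
* The NCE screen inherits the generator model's blind spots: confounding
  missed by the CV-tuned LASSO cannot be detected (measured-confounding
  screen only).
* Confidence intervals are HC3-normal; no bootstrap interval is wired
  into the replication loop by default.
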