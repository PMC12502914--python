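# Methods

## Model and estimation procedure

For each of q related problems k the package fits a generalised linear model

    h(E[y_i | x_i]) = beta_0k + sum_j beta_jk x_ij,

with identity link and squared-error loss (Gaussian family) or logit link and
binomial deviance (binomial family).  The problems share the same p features
and either the same samples (multi-task learning: one feature matrix, q
targets) or disjoint samples (transfer learning: one dataset per problem).
Estimation is in two stages.

**Stage 1 (no information sharing).**  Each problem is fitted separately by a
lasso-like elastic net: the mean deviance is penalised by
`lambda1 * (alpha * ||beta||_1 + (1-alpha)/2 * ||beta||^2)` with alpha = 0.95,
which keeps the L1 sparsity behaviour while allowing more than n selected
features and groups of correlated features.  `lambda1` is tuned per problem
by K-fold cross-validation over a 100-value geometric path from the smallest
all-zero penalty downward, using the pooled out-of-fold deviance and the
minimum-CV rule.

**Sign-specific weights.**  A positive stage-1 coefficient is evidence for a
positive final effect and against a negative one, so each feature receives
two weight slots (positive direction j, negative direction p+j).  Internal
weights take the positive/negative part of the problem's own stage-1
coefficient; external weights sum the positive parts and the negative parts
of the other problems' coefficients.  At most one internal slot per feature
is nonzero; both external slots can be.

**Stage 2 (information sharing).**  Each slope is decomposed into
nonnegative parts, `beta_j = gamma_j - gamma_{p+j}`, and the deviance is
penalised by `lambda2 * sum_j z_j * gamma_j` where the penalty factor is the
reciprocal prior weight

    z_j = 1 / ( w_int_j^delta_int + w_ext_j^delta_ext ),     0^0 := 1.

A zero exponent switches that information source off (every term contributes
1); a zero prior weight gives z_j = +inf and the coordinate is excluded
outright.  The problem is solved as a non-negative weighted lasso on the
column-augmented design [X | -X].  Because the paired columns are perfectly
collinear, at most one of gamma_j, gamma_{p+j} is nonzero in any solution —
an invariant the test suite asserts at 1e-8.

**Hyperparameter search.**  Per problem, `(lambda2, delta_int, delta_ext)`
are tuned jointly by K-fold cross-validation over the grid
{0, 0.2, 0.4, 0.6, 0.8, 1.0}^2 for the exponents and a 100-value path for
`lambda2`.  In multi-task mode a fold is excluded jointly for all problems
and the stage-1 coefficients are refitted (at the fixed `lambda1`) on the
remaining rows; in transfer mode only the problem under tuning is refitted
without its fold while the other problems keep their full-data stage-1
coefficients.  `lambda1` itself is tuned once on the full data and held
fixed inside this loop; the mild information leakage is a deliberate design
economy.  With `delta_int = delta_ext = 0` the procedure is exactly the
standard CV lasso, and with `delta_ext = 0` it is an internal-only adaptive
lasso whose output depends on the problem's own data alone — both
reductions are verified to numerical identity in the acceptance tests.

## Numerical choices

- The inner penalised weighted least-squares solves go through scikit-learn's
  coordinate-descent core, which minimises `1/(2n) RSS + lambda * penalty` in
  exactly the parametrisation above.  Penalty factors are absorbed by column
  scaling (valid for a pure L1 penalty), and +inf factors drop the column
  before fitting rather than using a large finite number.
- Features are standardised to unit variance internally (means absorbed into
  the unpenalised intercept); coefficients are reported on the original
  scale.  The sign-split design is standardised before augmentation so
  paired columns share a scale.  Zero-variance columns are left in place and
  receive zero coefficients.
- Binomial fits use iteratively reweighted least squares around the same
  core, with working weights floored at 1e-10 and probabilities clamped to
  [1e-10, 1 - 1e-10]; convergence is declared when the largest coefficient
  change falls below the solver tolerance (default 1e-7, at most 200 IRLS
  passes).
- Regularisation paths are geometric with `lambda_min/lambda_max = 0.01`
  when p > n and `1e-4` otherwise, at most 100 values.  The sign-split path
  uses the feature count p (not the 2p augmented columns) in this rule so
  that its path coincides with the plain lasso path it reduces to.
- Path fits are warm-started in chunks of 10 lambdas and stop early once the
  training deviance ratio exceeds 0.999 or gains less than 1e-5 per chunk
  (the remaining positions repeat the last coefficients).  This mirrors the
  early-exit convention of coordinate-descent path solvers and avoids the
  near-interpolation regime at the smallest lambdas, which is never selected
  by cross-validation.  Path fits use a working tolerance of 1e-4 (scaled by
  the squared target norm inside the core) and a per-chunk sweep budget of
  2000, which bounds the work spent in that tail the same way glmnet's
  path-wide iteration cap does; single final fits use 1e-7 with a 1e5
  budget.  Equivalence tests tighten all of these.
- CV curves are indexed by path position; each fold builds its path from its
  own training rows, out-of-fold predictions are pooled (not averaged per
  fold), and the reported `lambda2` is the full-data path value at the
  selected position, where the final coefficients are re-solved.
- Exact metric ties are broken toward `delta_ext = 0`, then
  `delta_int = 0`, then the larger `lambda2` — prefer less transfer, then
  less adaptation, then stronger shrinkage.  A degenerate null-gradient path
  (e.g. a constant target) collapses to a single tiny lambda with a warning.
- Fold assignment is balanced to within one sample.  For binomial targets
  folds are stratified by default; a shared multi-task partition can only be
  stratified against one target and uses the first problem's.  All
  randomness flows from one user seed through per-problem spawned
  generators, so a problem's folds do not depend on how many other problems
  accompany it.
- An optional `ridge_refit` switch replaces a problem's stage-1 fit with a
  CV-tuned ridge fit when the lasso-like stage 1 is entirely zero (off by
  default).

## Synthetic data

The generator defines the benchmark study conditions: AR(1)-correlated
Gaussian features (`corr(x_j, x_l) = rho^|j-l|`, rho = 0.5) via the exact
O(np) recursion `x_j = rho x_{j-1} + sqrt(1-rho^2) e_j`; spike-and-slab
effects `B[:,k] = theta + delta_k` with `theta_j ~ Bern(pi_theta) N(0,1)`
shared across problems and `delta_jk ~ Bern(pi_delta) N(0,1)` specific;
targets `y = X B[:,k] + e`, `e ~ N(0,1)`.  Defaults: q = 3, p = 200,
n = 100 training samples (multi-task) or (50, 100, 200) (transfer).  The
hold-out size defaults to a desk-scale 2000, which leaves Monte-Carlo error
on a hold-out MSE near 1 at about +/-3%; a 10000-sample hold-out is one
config field away.  A binomial
extension draws targets Bernoulli(logistic(XB)); it is provided for
completeness and is not part of the benchmark conditions.

What this emulates — and what it does not: features are exactly Gaussian
and stationary, effects are independent across features, and noise is
homoscedastic.  Real omics data have heavy tails, blockwise and long-range
correlation, and technical covariates; passing the simulation harness shows
the estimator recovers the intended behaviour under the stated model, not
that it is robust to those violations.

## Study harness

`run_study` fits, per replicate, the full-grid model and its
`delta = {0} x {0}` reduction on identical data with identical folds, and
reports hold-out MSE, the MSE ratio method/reduction, sparsity (exact
nonzero count), and sign precision (fraction of nonzero estimates with the
true sign; undefined for empty models and excluded from means rather than
substituted, since either 0 or 1 would bias them).  Using the method's own
reduction as the lasso baseline guarantees identical folds and paths, so
the ratio isolates the effect of adaptive, sign-specific, transfer-aware
penalisation.  Problems are averaged first, then replicates.  The bundled
study sizes (p = 100, n = 100, m = 2000, 10 replicates) are chosen so the
full study runs comfortably on a laptop; they scale the benchmark design
down rather than altering its structure.

## Known limitations

- Only Gaussian and binomial families; no Cox, Poisson or multinomial.
- External problems are weighted equally; no per-source weighting.
- Grid search only (no random or Bayesian search), minimum-CV rule only.
- Dense matrices throughout; no sparse-input support.
- The binomial IRLS wrapper is quasi-Newton only; extremely separable data
  rely on the probability clamp for stability.
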