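# Methods

## The model

`emels` fits mixed-effect location-scale models to intensive longitudinal
data (daily diaries, EMA): for person *i* with T_i equally spaced
occasions,

    y_i = X_i beta + Z_i b_i + eps_i,

where the residual process is stationary lag-1 autoregressive with a
*person-specific* variance and autocorrelation:

    Sigma_i[j, k] = sigma2_i / (1 - rho_i^2) * rho_i^|j-k|,
    sigma2_i = exp(s0 + omega_i),     rho_i = tanh(r0 + iota_i).

The joint random effect v_i = (b_i, omega_i, iota_i) is normal with mean
zero and covariance Phi.  The exp and tanh links keep the variance
positive and the autocorrelation inside (-1, 1) on an unconstrained
scale.  The package implements the random-intercept mean structure
(Z_i = 1, so v_i is three-dimensional); richer Z are stored by the data
containers but not fitted.  The linear mixed model with AR(1) errors
(`MixedAR1`) is the special case with the omega/iota variances fixed at
zero; its marginal likelihood is normal with V_i = phi_tau^2 11' +
Sigma and is evaluated in closed form via the Woodbury identity, using
the same exp/tanh parametrization.

Two extensions target prediction with many or nonlinearly acting
predictors:

* **Lasso** (`LassoEMELS`): the marginal log-likelihood minus
  `lambda * sum_j |beta_j|` over the slopes; the intercept, s0, r0 and
  Phi are never penalized.
* **Tree** (`EMELSTree`): the RE-EM alternation — grow a CART tree on
  the random-effect-freed residuals `y - Z b_hat`, refit the mixed model
  on the leaf-membership dummies, repeat until the marginal
  log-likelihood stabilizes.

## Estimation

The marginal likelihood integrates the conditional normal density over
v_i.  The integral is approximated by **adaptive Gauss–Hermite
quadrature** (AGH): a tensor-product rule with Q nodes per dimension,
recentered at each person's posterior mode and rescaled by the Cholesky
factor of the inverse curvature there, with log-sum-exp stabilization.
Implementation choices that matter:

* The mode search runs in *whitened* coordinates u (v = L u, L the
  Cholesky factor of Phi), where the prior is standard normal.  This
  keeps the damped-Newton iteration and its finite-difference curvature
  well conditioned for any Phi, including the nearly singular
  covariances that arise when a variance component is estimated at (or
  pinned to) zero.
* The final curvature uses a larger finite-difference step (3e-3) than
  the mode search (1e-4): the second difference of a ~1e1-magnitude
  log-density loses about seven digits to cancellation at the smaller
  step, and that noise would otherwise leak into the quadrature scale
  and make the objective microscopically rough.
* The conditional density is evaluated from six per-person sufficient
  statistics of the residual vector, exploiting the tridiagonal AR(1)
  inverse — one likelihood evaluation is O(n_total) plus O(I Q^3) node
  arithmetic, with no T x T matrix ever formed.

The outer optimization alternates (a) refreshing the adaptation at the
current parameters and (b) an L-BFGS cycle on the fixed-adaptation
objective with a central-finite-difference gradient.  This is a
fixed-point map in theta; it converges linearly near the optimum.
Convergence is declared on parameter movement (`theta_tol`, default
3e-7) rather than on the log-likelihood change alone, because the
log-likelihood flattens out well before the parameters stop moving and
a loglik-only criterion leaves a residual limit cycle of order 1e-4 in
the estimates.  Adaptation refreshes can wiggle the recorded
log-likelihood trace by O(1e-3) at small Q; accepted inner steps are
monotone.

Standard errors come from the inverse observed information
(finite-difference Hessian of the AGH log-likelihood at the optimum,
fixed adaptation), delta-method-transformed to the reporting scale
(exp for the residual-variance intercept, tanh for the autocorrelation
intercept, products of Cholesky entries for Phi).  `n_params` counts
(p+1) fixed effects + 2 (s0, r0) + (k+2)(k+3)/2 free Phi entries; AIC
and BIC use it with n = total observation count.  Likelihood-ratio
tests use the plain chi-square reference even on the variance boundary
(no mixture correction) — df = 5 for location-scale vs. linear AR(1)
with a random intercept.

Starting values: pooled OLS for beta; s0 = log pooled residual
variance; r0 = atanh of the pooled lag-1 residual autocorrelation
(clipped to |rho| <= 0.95); Phi = 0.1 I.  The exponent s0 + omega is
clipped to [-30, 30] before exp, and tanh output to 1 - 1e-12 in
magnitude, so that extreme 3-D quadrature tail nodes cannot overflow.

### Quadrature size

Q = 10 per dimension is the reference setting; Q = 4–5 changes the
benchmark estimates below by less than 0.01 and is roughly 8–60x
faster, so the test-suite and the reproduction script use Q = 4–5 and
the library default stays 10.  With long series, or a large
autocorrelation-heterogeneity variance, the integrand acquires heavy
tails in iota (the 1/(1 - rho^2) factor) and the marginal needs more
nodes: on a T = 3 toy with phi_iota^2 = 0.1 the Q = 10 and Q = 20
values agree to 4e-5, while with phi_iota^2 = 0.5 and T = 6 they can
differ by ~1e-3.

## Penalized estimation

At fixed lambda, block coordinate ascent: proximal-gradient steps with
backtracking and soft-thresholding for beta (exact zeros), L-BFGS for
(s0, r0, Phi) at fixed beta, with the adaptation refreshed each cycle.
The lambda path (default 50 equally spaced values on [0, 500]) is
fitted in increasing order with warm starts.  Information criteria use
the penalized log-likelihood and df = #nonzero beta + 2 + #free Phi
parameters; the "+2" for (s0, r0) keeps the df consistent with the
unpenalized counting rule.  After selection (BIC by default; AIC also
computed) the selected support is refitted unpenalized, and that refit
is the model used for forecasting.  Predictors should be standardized
(`preprocess_predictors(..., standardize=True)`); the constructor warns
otherwise, since the L1 penalty is scale-dependent.

## Trees

`fit_cart` is a from-scratch CART: greedy binary splitting minimizing
within-node SSE; candidate split points are midpoints between
consecutive distinct sorted values; ties break toward the lowest
variable index, then the lowest split value (this makes the exhaustive
search oracle in the tests exact).  A split must improve the SSE by at
least `cp * SSE(root)` (rpart convention, default cp = 0.001) and is
attempted only in nodes with at least `minsplit` rows (default 20),
with at least `minbucket = floor(minsplit/3)` rows per child.  The
grown tree is pruned by weakest-link cost-complexity with the
complexity value chosen by 10-fold cross-validation over rows (seeded
fold assignment, minimizing CV error; no 1-SE rule).

In the alternation, the tree is regrown and repruned every iteration;
leaves enter the mixed model as one dummy regressor each (no separate
intercept), so the fitted leaf effects play the role of leaf means.
The alternation log-likelihood trace is non-decreasing once the tree
structure stabilizes, but it can legitimately *drop* early on: the
first tree is grown on residuals still contaminated by the random
effects, tends to overfit that noise, and the refreshed tree prunes
those spurious splits — a smaller design with a lower likelihood and a
better model.  Convergence is therefore assessed on structure
stabilization plus log-likelihood change, and trees report no
forecast-error variance (no established construction exists for
hierarchical data).

## Forecasting

Task 1 (training person, future occasion): `y_hat = x'beta + z'b_i +
rho_i^H eps_hat_{i,T}` with b_i the empirical-Bayes (posterior-mean)
effect, eps_hat the last Level-1 residual, and rho_i person-specific
under the location-scale model.  Task 2 (new person, no history):
fixed effects only.  Task 3 (new person with history): EB effects from
the history at the training estimates, then the Task-1 formula.
Future design rows are assumed known; no predictor forecasting.

Forecast-error variances follow the BLUP prediction-variance
decomposition (fixed-effect estimation error with cov(beta) from the
observed information, random-effect shrinkage, residual innovation at
its stationary variance).  Under the location-scale model the EB
plug-ins (sigma2_i, rho_i) are treated as known; their estimation
uncertainty is not propagated, which understates the variance slightly
for persons with short histories.  The residual term is the
unconditional stationary variance (not reduced by conditioning on the
observed residuals).

## Synthetic data

`simulate_emels` draws from the model itself: v_i ~ N(0, Phi),
predictors i.i.d. uniform on [0, 10] (or standard normal), residuals
by the exact stationary AR(1) recursion.  `simulate_tree_scenario`
generates the benchmark: nine observation-level Uniform(0, 10)
predictors redrawn at every occasion, a four-leaf outcome rule (split
at 5 on x1, then x2 or x3; leaf constants 10/11/12/13), and
location-scale noise with s0 = -0.67, r0 = 0.26, Phi = diag(1.0, 0.5,
0.5), defaults I = 200, T = 51.  Only the random intercept enters the
mean; omega and iota act through the residual process.  An interaction
builder adds x1*x2-type columns so a linear working model can
approximate the tree's nested splits.

What the generators do *not* emulate: missing or unequally spaced
occasions, non-Gaussian random effects, measurement floors/ceilings of
Likert outcomes, and predictors correlated with each other or over
time.  Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions and the benchmark design,
not robustness to those real-data features.

## The benchmark and problem sizes

The reproduction script (`scripts/acceptance.py`) and the acceptance
tests train on the first 100 persons x 50 occasions of the tree
scenario and forecast occasion 51, exactly the benchmark split.  Two
useful population facts about this design: the best linear
approximation (with the two interactions) to the tree mean has slope
0.30 on x1 and a misfit variance of 0.336, which acts as white noise
and attenuates the estimated residual autocorrelation of the linear
working models toward ~0.16; and the mean stationary residual variance
E[sigma2_i / (1 - rho_i^2)] ~ 1.35, which together with the intercept
variance 1.0 and the misfit puts the fixed-effects-only (Task 2)
forecast MSE near 2.6.  The one-step MSEs are averages over 100
forecasts and are noticeably seed-dependent (the lognormal variance
heterogeneity is heavy-tailed), so the script averages five replicate
simulations per reported tree number (ten for the cheap linear-model
target) and the tests average three seeds; single-replicate values
scatter with an SD of roughly 0.1 around the tree-task averages and
roughly 0.5 around the Task-2 average.

## Known limitations

* Mean-structure random effects beyond the random intercept (k > 1)
  are not fitted.
* Gradients and Hessians are high-accuracy central finite differences,
  not analytic expressions; the gradient contract is agreement with
  independently stepped central differences.
* The LR test on variance boundaries uses the plain chi-square
  reference, which is conservative.
* Lasso lambda selection is information-criterion based;
  cross-validated selection is out of scope.
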