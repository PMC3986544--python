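# Methods

## The model

`mtmmirt` estimates a confirmatory factor model for binary indicators
collected under a multitrait–multimethod (MTMM) design: `T` trait
constructs each measured by the same `M` methods, so the latent trait
and method factors are *crossed*.  For person `p` and item `i`,

    g(pi_pi) = aT_i * thetaT_{p,t(i)} + aM_i * thetaM_{p,m(i)} + beta_i,

with `g` the logit (default) or probit link, `t(i)` / `m(i)` the trait
and method factor item `i` belongs to, and `beta_i` the item intercept
(easiness).  Trait scores are jointly normal with correlation matrix
`Sigma_T`; method scores are independent standard normal and
independent of the traits (the CT-UM structure: correlated traits,
uncorrelated methods).  All latent variances are fixed at 1 for factor
standardization, so loadings carry the full scale of each factor's
influence and are kept nonnegative for sign identification (an
absolute-value reparameterization inside the optimizers, a half-normal
prior and positivity constraint inside the sampler).

Conditional on the latent scores, responses are independent
(local independence), so the observed-data likelihood integrates the
product of Bernoulli terms over all `T + M` latent dimensions — the
integral that makes direct ML estimation of crossed designs hard: a
tensor Gauss–Hermite rule needs `k^(T+M)` nodes per likelihood
evaluation (`8^6 = 262,144` already for `T = M = 3` at 8 points).

Per-item **consistency** (`gammaT`) and **method-specificity**
(`gammaM`) coefficients summarize how much of an item's non-error
variance its trait versus its method factor carries.  Two conventions
are implemented and must be chosen explicitly:

* `squared` (default): `gammaT_i = aT_i^2 / (aT_i^2 + aM_i^2)` — the
  variance-decomposition reading, consistent with calling the
  coefficients variance proportions when all latent variances are 1;
* `literal`: `gammaT_i = aT_i / (aT_i + aM_i)` — the loadings entered
  linearly, as the defining formulas are sometimes printed.

Both satisfy `gammaT + gammaM = 1` per item.  For the verbal
aggression illustration (below), the parameter estimates and the
validity coefficients published in the literature are mutually
inconsistent under *either* convention, which is why the package
refuses to pick one silently.

## Estimators

### Tensor / adaptive Gauss–Hermite quadrature ML (`fit_quadrature`)

The oracle for small latent spaces.  Probabilists' Gauss–Hermite rules
(unit-normal weight) are tensorized over all dimensions; correlated
traits are handled by pre-multiplying the trait block of the nodes by
the Cholesky factor of `Sigma_T`, so the grid always lives in a
standard-normal space.  Optionally the grid is adapted per person:
recentered at the posterior mode of the latent vector (damped Newton
with analytic gradients and Hessians, 100-step cap, prior fallback on
failure) and rescaled by the Cholesky factor of the inverse curvature.

Maximization is quasi-Newton (L-BFGS-B) on an unconstrained
parameterization: `|u|` for loadings, tanh-transformed canonical
partial correlations for the Cholesky factor of `Sigma_T`.  Gradients
for loadings and intercepts are analytic through the posterior-weight
identity `d loglik_p / d psi = E_post[d log p(y_p|z) / d psi]`
(evaluated on the grid); the few correlation parameters are central
differences.  Tolerances: gradient infinity-norm `1e-5`; wide box
bounds (`|u| <= 8` on loadings, `12` on intercepts) act purely as a
guard against likelihood ridges in under-identified configurations —
2PL-type discriminations can genuinely diverge on unlucky samples, and
the marginal likelihood of near-degenerate items is flat enough for an
unbounded quasi-Newton run to walk off.  A `CapacityError` refuses
grids above a configurable node budget (default `1e7`).
Starting values: intercepts from marginal item means through the link,
loadings 0.5, correlations 0.  `estimate_loadings` accepts
`True`/`False`/`"trait"`/`"method"` so sub-models (plain 2PL, fixed
loadings for the variational comparison) are fit without ad-hoc code.

### Alternating imputation posterior (`run_aip`)

The random part is split into a **trait wing** (`aT_i thetaT`) and a
**method wing** (`aM_i thetaM`).  Each outer iteration runs, per wing,
a P-step — an adaptive-quadrature ML fit of the wing's low-dimensional
2PL-type model with the frozen wing's contribution entered as a known
per-person-item offset — and an I-step — a multivariate-normal draw of
the wing's item parameters around the fit (covariance = inverse
numerical Hessian, eigenvalue-floored to PSD) followed by draws of each
person's wing latent variables from the normal approximation to their
conditional posterior (mode, inverse curvature).  The point estimate is
the mean of the post-burn-in parameter draws; chain standard deviations
are reported as diagnostics together with a first-half/second-half
stationarity check.

Design choices worth flagging:

* **Intercept ownership.**  Refitting the full `(a, beta)` 2PL in both
  wings would update the intercepts twice per iteration and lets the
  wings tug them back and forth; intercepts are owned by the method
  wing only (by the trait wing when the method wing is clamped off).
* **Adaptation to a fixed point.**  The adapted grid is frozen during
  each wing optimization (modes recomputed mid-line-search would make
  the objective inconsistent), but a grid frozen at a poor start can
  place its own spurious optimum; each P-step therefore re-adapts at
  the previous optimum and refits until the estimates stop moving
  (at most 6 passes; warm starts make 1–2 passes typical).
* **Covariance refresh.**  The full numerical Hessian is recomputed
  every `cov_refresh = 25` iterations and reused in between — the wing
  estimates move little between alternations once burned in.
* Wing dimension is capped (default 4): the trait wing fits a
  `T`-dimensional correlated model, which is exactly the configuration
  the algorithm stops being cheap for.
* Defaults `iterations = 200`, `burn_in = 100`.

### Monte Carlo local likelihood (`fit_mcll`)

MCLL reconstructs the likelihood (up to the posterior's unknown
normalizing constant, which cancels in maximization) as
`log L(y|theta) = log p(theta|y) - log p(theta) + const`, with the log
posterior density estimated from MCMC parameter draws by local
likelihood density estimation: around a fitting point, the log-density
is modeled as a degree-2 polynomial whose coefficients maximize the
kernel-localized likelihood.

* **Sampler.**  Built-in adaptive random-walk Metropolis-within-Gibbs:
  componentwise updates of every person-by-dimension latent score
  (Gibbs augmentation), componentwise updates of each item's
  `(aT, aM, beta)`, and a joint random-walk on the correlation
  off-diagonals (proposals outside the elliptope rejected).  Proposal
  scales adapt toward ~0.3–0.4 acceptance during burn-in only.  Draws
  from any external sampler can be supplied as CSV instead.
* **Priors** (slightly informative, overridable): half-normal(scale 2)
  on loadings, normal(0, 2^2) on intercepts, and an LKJ-type
  `det(R)^(eta-1)` correlation prior with `eta` chosen so each
  correlation is marginally uniform when attainable (`eta = (4-T)/2`,
  falling back to the jointly uniform `eta = 1`).
* **Local fit.**  Gaussian product kernel with the per-dimension rule
  of thumb `h_j = sd_j * m^(-1/(d+4))`.  For this kernel/polynomial
  pair the localized score equations solve in closed form: the
  kernel-weighted mass, mean and covariance of the draws around the
  fitting point determine the Gaussian `kernel x exp(polynomial)`
  exactly, and dividing the kernel back out yields the coefficients.
  Infinite bandwidth therefore recovers the global Gaussian ML fit to
  the draws, and the fitted value is translation-equivariant by
  construction.  Ill-conditioned weighted moments (or an effective
  kernel sample size below `d + 2`) trigger bandwidth inflation by 1.5,
  at most three times, then a hard error with diagnostics.
* **Maximization.**  Damped Newton from the posterior mean: the local
  quadratic's linear/quadratic coefficients are the fitted gradient and
  Hessian of the log posterior; analytic prior derivatives are
  subtracted (the small correlation block numerically); Levenberg-style
  damping guards the noisy flat directions whose fitted curvature can
  come out with the wrong sign; every step is checked against the true
  (refitted) objective.  The search is confined to the box holding 99%
  of the draws per dimension — the density estimate means nothing
  outside the sample cloud — and boundary-clamped estimates are
  flagged.
* **Known bias floor.**  In high-dimensional parameter spaces the
  product kernel cannot be made much narrower than the posterior spread
  without collapsing the effective sample size, so the fit oversmooths
  skewed marginals; on small-sample 2PL loadings this leaves an
  argmax deviation from the exact MLE on the order of 0.1 that longer
  chains do not remove.  This is a property of kernel-local density
  estimation, priced into the tests and visible in the diagnostics.

### Mean-field variational MM (`fit_vmm`)

For the fixed-loadings case only (the method's stated applicability):
the latent posterior is approximated by a fully factorized density
with Gaussian marginals per person and latent dimension, and a lower
bound on the log-likelihood (expected complete-data log-likelihood
plus entropy) is alternately maximized over the marginals (first
M-step) and the intercepts (second M-step).  Because each item's
predictor involves exactly two latent coordinates, every expectation
reduces to a 1-D Gaussian integral over the predictor, evaluated with
a 21-point Gauss–Hermite rule.  Coordinate updates are damped Newton
steps (analytic in the mean, numeric in log-variance) with a
per-person objective check that reverts non-improving moves, so the
bound is monotone by construction; the alternation stops when the
bound changes by less than `1e-6` (cap 500 iterations).  `Sigma_T` is
a fixed input: a fully factorized family cannot represent a
correlated prior it would itself estimate.

Note on tightness: in one active latent dimension mean-field removes
the factorization error but the *Gaussian-marginal* restriction
remains, leaving a small KL gap (~1e-3 per person on test problems)
between the converged bound and the quadrature log-likelihood.  A
free-form marginal would close it; the Gaussian family is kept for its
closed-form entropy and moments.

## Synthetic data and the verbal aggression preset

`simulate_responses` draws latent scores exactly under the CT-UM
assumptions and responses as Bernoulli at the model-implied
probabilities, with optional missingness completely at random
(matching the ignorable treatment in all likelihoods — missing cells
simply drop out of the product).

The preset `verbal_aggression_wanting_*` reproduces the structure of
the verbal aggression inventory (De Boeck & Wilson's dataset): the 12
"wanting"-mode items crossing 3 behavior-type traits (Curse, Scold,
Shout) with 4 situation-type methods (Bus, Train, Store, Operator),
one item per cell, N = 316 respondents, responses dichotomized by
collapsing *Perhaps* with *Yes*.  MCLL estimates published for these
items serve as the default generating values, making the preset a
realistic recovery benchmark whether or not those published values are
the exact MLE of the real data (see limitations).

What the generator does **not** emulate: polytomous responses,
informative missingness, person drift, local dependence beyond the
crossed factors, or sampling designs other than a simple random
sample.  Passing recovery tests therefore demonstrate correctness of
the estimators *under the model*, not robustness to its violations.

## Identifiability and test design

Three structural facts shaped the test suite and are worth knowing as
a user:

* **Items per cell.**  With one or two indicators per trait-method
  cell the item-level split of variance between the trait and the
  method factor is barely identified (observed SEs above 3 at
  N = 1000 with two items per cell).  Cross-estimator comparisons use
  three items per cell, where the largest SE drops to ~0.3.  On the
  one-item-per-cell verbal-aggression design at N = 316 the problem is
  stark: recovery experiments show posterior loading biases around
  0.8–1.0 that longer chains do not reduce — the posterior mass
  migrates along a soft ridge toward larger trait loadings, exactly as
  the fit of the real data does.  Item-level loading splits from such
  designs at such sample sizes should not be over-interpreted;
  trait correlations, by contrast, recover well (RMSE ~0.1).
  Even at three items per cell a particular sample can land near such
  a ridge without the local Hessian revealing it; one of the shipped
  verification datasets does, and the affected comparisons document it.
* **Loadings at zero.**  A loading enters the likelihood quadratically
  at 0, so its Fisher information vanishes there and the MLE
  fluctuates at the `N^(-1/4)` rate (~0.4 at N = 500).  Tests of
  zero-loading configurations assert that rate, not root-N noise.
* **Rotation in 1 x 1 designs.**  With a single trait and a single
  method factor over the same items, only the per-item loading norm
  `sqrt(aT^2 + aM^2)` is identified; "plain 2PL" references always
  freeze the unused block at zero.

## Problem sizes

The shipped tests and the acceptance script run, as the package's
standard verification suite: a 2-trait x 2-method, 12-item,
N = 1000 dataset shared by all estimator-agreement checks (AIP at
150 alternations, MCLL at 3 chains x 1000 kept draws after 1500
burn-in); a 20-replication MCLL recovery study on the verbal
aggression design at N = 316 (2 chains x 1000 kept after 600
burn-in); and an MCLL fit of the real wanting-mode items at 3 chains
x 4000 kept after 3000 burn-in.

## Known limitations

* **AIP and free discriminations.**  The wing alternation treats
  posterior *draws* of the frozen wing's latent variables as known
  offsets.  The draw noise behaves like measurement error in the
  linear predictor, and each wing's marginal fit absorbs the resulting
  overdispersion into its own loadings; for weakly identified items
  this rectifies into a slow positive feedback — the item's loadings
  random-walk upward while its intercept compensates.  Box bounds on
  the wing fits and a cap on the I-step draw dispersion keep the
  alternation bounded, and a drifting item is visible as an inflated
  chain SD and a large `half_mean_max_shift` diagnostic, but the
  feedback itself is intrinsic to the scheme: on crossed designs with
  free loadings in both wings, expect agreement with exact ML at the
  0.15–0.5 level on the weakest loadings rather than Monte Carlo
  accuracy.  (This is consistent with the method's track record, which
  is on Rasch-type random-item models, and with it not being the
  estimator of choice for correlated-trait crossed models.)
* Standard errors are reported only for the quadrature estimator
  (inverse numerical Hessian); AIP and MCLL return point estimates
  with chain-dispersion diagnostics.
* Polytomous links, bifactor extensions, correlated trait-method
  structures and limited-information (weighted least squares)
  estimation are out of scope.
* The MCLL local fit inherits the kernel bias floor described above;
  for a handful of parameters it is the least accurate of the three ML
  approximations, while being the only one whose cost scales with the
  number of *parameters* rather than latent dimensions.
* On the real verbal aggression wanting-mode items, the package's
  estimators (and its exact quadrature likelihood) locate a
  substantially higher-likelihood solution than the estimates
  published for this dataset, with larger trait loadings and a
  different trait-correlation pattern; chains initialized at the
  published values migrate away from them.  The published solution
  appears not to be a stable optimum of this model on these data, so
  agreement with it is not a correctness criterion for the estimators
  — the synthetic recovery studies are.
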