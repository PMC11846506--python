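# Methods

## Model

`gamvar` fits Poisson state-space models to a species × month matrix of
capture counts on a regular grid with masked (skipped) sessions.  The
latent log-mean for species *i* at month *t* is

    X[i,t] = mu[i,t] + z[i,t]

with a GAM predictor `mu` and a VAR(1) deviation process `z`.

**GAM predictor.**  `mu[i,t] = a_i + b_i * v_t + f_g(t) + f_i(t)` where
`v_t` is the z-scored 12-month trailing moving average of NDVI and
`f_g`, `f_i` are distributed-lag smooths of minimum temperature.  The
moving average encodes the assumption that resource-driven abundance
responds to accumulated greenness over about a year rather than to the
current month.  The distributed-lag smooth sums a bivariate tensor-product
surface `s(lag, temp)` over lags 0..6 months, letting the temperature
response change shape smoothly with delay; six months covers breeding and
behavioural responses to seasonal temperature change.  Lag 0 is included:
the upper bound is on the oldest lag, and the current month carries the
strongest signal.

**Bases and penalties.**  The lag margin uses a cardinal cubic regression
spline with k = 4 knots at the quantiles of the observed lags and the
integrated-squared-second-derivative penalty (`S = D' B^{-1} D` in the
natural-spline construction); the temperature margin uses a rank-3
eigen-truncated thin-plate spline (radial basis `|r|^3/12`, order-2
penalty), with penalized columns rescaled so their penalty is the
identity.  The tensor product has 12 coefficients and one
Kronecker-expanded penalty per margin.  The community-level smooth is
centered (sum-to-zero over observed months) for identifiability against
the intercepts; knots sit at training-window quantiles.  Species-deviation
smooths share the basis but carry an extra projector penalty on the joint
penalty null space with its own smoothing parameter, so a deviation is
nonzero only where the data support it.  Exact basis values are a
convention; equivalence with other implementations holds at the level of
the spanned function space and penalty null spaces, not individual basis
functions.

**Dynamics.**  `z[.,t] = A z[.,t-1] + eps_t`, `eps_t ~ N(0, Sigma)`,
`Sigma = diag(sigma) C diag(sigma)`.  The VAR acts on deviations from the
GAM predictor rather than on `X` itself; this keeps the GAM the stationary
mean of the process and makes the smooths directly interpretable.
Stationarity is enforced by construction through the order-1
partial-autocorrelation map

    P  = (I + B B')^{-1/2} B
    L0 = chol(Sigma) chol(I - P P')^{-1}
    A  = L0 P L0^{-1}

for unconstrained real `B`.  `A` is similar to `P`, whose singular values
are strictly below one, so the spectral radius of `A` is below one for
every real input; `Gamma = L0 L0'` is simultaneously the exact stationary
covariance (it solves `Gamma = A Gamma A' + Sigma`), which is used for the
initial state.  Benchmarks with independent dynamics (GAM-AR, AR)
constrain `B` to be diagonal and fix `C = I`, which removes the
covariances and cross-dependencies while leaving everything else
unchanged.

**Priors** (all configurable through `ModelSpec.priors`): intercepts
N(0, 2²); hierarchical slope mean N(0, 1); slope sd Exponential(2) with a
non-centered slope parameterization; smooth coefficients get the
penalty-matrix normal prior with smoothing parameters
λ ~ Gamma(0.05, 0.005); the unpenalized null-space directions of the
global smooth get a fixed N(0, 2²) prior; process sds Exponential(1);
C ~ LKJ(2), implemented through canonical partial correlations (the C-vine
Beta representation, which is exactly equivalent and gives independent
unconstrained coordinates); unconstrained dynamics entries N(0, 0.5²).
These are weakly informative defaults for unit-scaled covariates and
log-scale counts.

## Estimation

The joint posterior — latent states included, nothing marginalized — is
sampled with the package's own No-U-Turn sampler: multinomial trajectory
sampling, generalized U-turn checks on sub-trees, dual-averaging step-size
adaptation (target acceptance 0.8 by default) and diagonal mass-matrix
estimation in doubling warmup windows.  The gradient of the joint log
density is derived analytically and accumulated in reverse mode through
the entire construction, including Cholesky factors, the symmetric matrix
inverse square root (eigendecomposition with divided differences) and the
stationarity map; the tests validate every variant's gradient against
central finite differences.  Latent states use a non-centered innovation
parameterization (`z` is reconstructed from iid normal innovations through
the state recursion), which removes the worst posterior curvature.
Divergent transitions (energy error > 1000) are counted and reported.

Convergence is assessed with rank-normalized split-R̂ and bulk/tail
effective sample sizes, computed in-package and cross-checked against
`arviz` in the test suite.  Randomized quantile (Dunn–Smyth) residuals
provide absolute goodness-of-fit checks: under a correctly specified model
they are standard normal and serially independent.

## Model comparison and forecast verification

PSIS-LOO follows the standard recipe: per-observation importance ratios,
the `min(0.2 S, 3 sqrt(S))` largest replaced by expected order statistics
of a generalized Pareto distribution fitted with the Zhang–Stephens
posterior-mean estimator, truncation at the raw maximum,
self-normalization, and the tail-shape diagnostic k̂ (warning above 0.7).
ELPD differences between models use pointwise differences with
`SE = sqrt(n var(diff))`, the best model anchored at 0.0/0.0.  Because
latent states are sampled jointly, individual k̂ values can exceed 0.7 on
flexible variants; comparisons remain informative but per-point estimates
should be read with the diagnostic in hand.

Forecast evaluation is exact leave-future-out cross-validation on an
expanding window: refit on each training prefix, draw posterior-predictive
count ensembles for the next 12 months (propagating each draw's dynamics
and adding Poisson noise; covariates for the test window are taken as
observed), and score each fully observed test month with the energy score
and the variogram score of order p = 0.5 with unit pair weights, combined
with equal weight.  Months containing a skipped session are flagged and
not scored.  Scores are computed on the count scale from full
posterior-predictive draws, since forecasts are verified against observed
captures.  The variogram order and weights are configurable; p = 0.5 and
unit weights are the score originators' defaults.

## Scenario tools

*Forecasts* propagate each draw's last latent deviation with that draw's
`A` and `Sigma`, add `mu` from future covariates, and emit Poisson counts.
*Impulse responses* map a pulse of extra captures onto the latent scale at
each draw's baseline (`delta_i = log(lambda_i + extra) - log(lambda_i)`,
baseline = posterior-median `mu` over training), spread it
contemporaneously with the generalized (covariance-conditioned) convention
`delta = Sigma[:,i] delta_i / Sigma[i,i]` — chosen over Cholesky
orthogonalization to avoid imposing a species ordering — and propagate
with `A^h`.  *Covariate contrasts* report `exp(mu(high)) - exp(mu(low))`
for the NDVI moving average moving from −0.50 to +0.50 z-units, all other
terms at training references and the dynamic deviation at zero, plus sign
probabilities.  *Conditional lag functions* evaluate the summed
distributed-lag effect month-by-month for a supplied year of temperatures
(wrapping at the year boundary), global + deviation where a deviation
exists, each curve scaled to unit variance for comparison.

## Synthetic data

The generator emulates a long-running monthly trapping study: ~9 species,
~319 months, low zero-heavy counts, ~5% of whole sessions missing (a
skipped session hides every species at once), seasonal minimum temperature
(sinusoid, period 12, amplitude 8 °C around 5 °C, noise sd 1.5 °C) and
NDVI with seasonality plus a slow random-walk trend, clipped positive,
with a full year of covariate lead-in before the count window.  True
parameters are drawn to satisfy every invariant by construction (the raw
dynamics matrix is pushed through the stationarity map; correlations come
from the C-vine construction).  Counts are simulated unbounded Poisson —
the model places no trap-imposed ceiling — and a 24-month burn-in is
discarded so the recorded window starts at stationarity.  What the
generator does **not** emulate: detection error beyond process noise,
plot-level structure, irregular lunar-month spacing, covariate
measurement error, and real covariate marginal distributions.  Passing
tests therefore demonstrate internal correctness and recoverability under
the model's own assumptions, not performance on field data.

## Problem sizes used in tests and the acceptance script

Fits at the full study scale (9 species × 319 months, 4 chains × (500 +
1,600) iterations) are long-running batch jobs; the test suite and
acceptance script exercise the same code paths at reduced scale:

* parameter recovery: 4 species × 96 months, GAM-VAR, 2 chains ×
  (400 warmup + 800 sampling), 3 seeded replicates in the test suite (1 in
  the acceptance script); coverage of 90% intervals for NDVI slopes and
  diagonal dynamics entries is pooled over replicates, and convergence is
  checked on those same reported parameters.
* model ranking: 4 species × 72 months with strong cross-dependence and
  no missing sessions; GAM-VAR vs AR fit on the first 60 months with
  2 chains × (200 + 200); PSIS-LOO on the training window and a 12-month
  leave-future-out fold per replicate; 5 replicates in the test suite,
  2 in the acceptance script.
* residual calibration: 3 species × 72 months, diagonal-dynamics truth,
  GAM-AR fits with 2 chains × (150 + 150), with a Kolmogorov–Smirnov
  normality check per replicate; 3 replicates in the test suite, 2 in the
  acceptance script.

Monte-Carlo property checks (stationarity of the map, Lyapunov residuals,
score properness, PSIS vs exact leave-one-out) run at the sizes stated in
the tests, typically 100–10,000 random systems or replicates.

## Numerical choices and limitations

* Degenerate corners of the unconstrained space (vanishing smoothing
  parameters making the prior precision numerically singular) evaluate to
  zero posterior density and are rejected by the sampler.
* The observation term returns −inf when any latent log-mean exceeds 40,
  bounding `exp` overflow during early warmup.
* z-scoring uses the sample (n−1) standard deviation; reference moments
  always come from the training window, so expanding-window refits never
  leak future covariate information.
* Sessions are assumed to sit on a regular calendar-month grid with gaps
  masked, one session per month.
* Smoothing-parameter posteriors are explored on the log scale with the
  coefficients centered; very short chains can show R̂ above 1.01 for the
  slowest smoothing parameters even when the substantive parameters have
  mixed well.
* VAR order is fixed at 1 and `A` is time-invariant; no negative-binomial
  observation family; no covariate-forecast propagation (hindcasts use
  observed covariates).
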