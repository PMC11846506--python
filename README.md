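# gamvar

Dynamic GAM–VAR state-space models for multispecies count time series.

## The problem

Ecological monitoring programs produce monthly capture counts for whole
communities — many interacting species, low zero-heavy counts, skipped
sampling sessions — together with environmental covariates such as minimum
temperature and satellite greenness (NDVI).  Forecasting any one species in
isolation discards two strong sources of signal: species respond to shared
environmental drivers (often nonlinearly and with multi-month delays), and
their dynamics are coupled through lagged dependence and correlated process
noise.  `gamvar` is for quantitative ecologists who want to fit, compare
and interrogate multivariate models that use both.

## The model

Counts are Poisson observations of a latent log-mean that splits into a
hierarchical GAM predictor and a stationary VAR(1) deviation:

```
Y[i,t] ~ Poisson(exp(X[i,t]))
X[.,t] = mu[.,t] + z[.,t]
mu[i,t] = a_i + b_i * NDVI_MA12(t) + f_global(mintemp, lag)(t) + f_i(mintemp, lag)(t)
z[.,t] = A z[.,t-1] + eps_t,   eps_t ~ N(0, Sigma),  Sigma = diag(s) C diag(s)
```

* `b_i` are hierarchical NDVI slopes, `b_i ~ N(mu_NDVI, sigma_NDVI^2)`,
  partially pooled toward a community mean.
* `f_global` and the species deviations `f_i` are penalized distributed-lag
  tensor smooths (4 cubic basis functions over lag 0–6 months × 3 thin-plate
  basis functions over temperature); deviation smooths are fully penalized so
  they shrink to zero without evidence.
* `A` is the full lagged-dependence matrix (diagonal: density dependence;
  off-diagonal: cross-species dependence).  Stationarity is enforced by
  sampling an unconstrained matrix and mapping it through a
  partial-autocorrelation construction, so the spectral radius of `A` is
  below one for every draw and forecast variance cannot diverge.
* `C` is the correlation matrix of contemporaneous process errors
  (LKJ prior via canonical partial correlations).

Three nested benchmarks — `GAM-AR` (diagonal dynamics), `GAM-AR-no-pooling`
(independent species smooths and slopes), `AR` (intercepts + AR(1) only) —
are simplifications used for model comparison.  Fitting is by the package's
own No-U-Turn sampler over a hand-differentiated joint log density.
Comparison machinery: PSIS-LOO ELPD with difference SEs, and exact
leave-future-out cross-validation scored with an even combination of the
energy score and the variogram score (order 0.5).  Scenario tools compute
posterior-predictive forecasts, generalized impulse responses, NDVI
contrasts and conditional distributed-lag curves.

## Worked example

```python
import numpy as np
from gamvar import synthetic_data as syn, evaluation as ev
from gamvar.model import ModelSpec, build_model, build_model_data
from gamvar.inference import fit
from gamvar.scenario import impulse_response

cfg = syn.SimulationConfig(n_species=4, n_months=96, seed=11)
params, covariates, counts = syn.simulate_dataset(cfg)

data = build_model_data(counts, covariates)
spec = ModelSpec(variant="GAM-VAR", chains=2, warmup=300, sampling=250,
                 seed=3, max_treedepth=9, target_accept=0.85)
draws, diag = fit(build_model(spec, data), spec)

print("true NDVI slopes:", np.round(params.ndvi_slopes, 2))
print("post NDVI slopes:", np.round(draws.stacked("b").mean(0), 2))
print("max rank-normalized split-Rhat:", round(diag.max_rhat(), 3))

irf = impulse_response(draws, "sp01", extra_captures=3, horizon=6)
print("own-species impulse decay:", np.round(irf.median()[:, 0], 3))
```

Output from this exact script (seeds fixed):

```
true NDVI slopes: [0.21 0.19 0.32 0.24]
post NDVI slopes: [0.24 0.23 0.36 0.22]
max rank-normalized split-Rhat: 1.061
own-species impulse decay: [0.677 0.217 0.135 0.051 0.029 0.006 0.006]
```

The posterior slope means track the generating values within posterior
uncertainty (the R̂ just above 1.05 reflects the deliberately short demo
chains; the slowest parameters are smoothing penalties, not the slopes).
The impulse response shows the log-mean effect of three extra captures of
`sp01` on itself — an immediate jump of 0.68 decaying toward zero within
about six months, the signature of stationary density dependence.

A CLI mirrors the library (`gamvar simulate | preprocess | fit | compare |
crossvalidate | forecast | irf | contrast`), driven by one YAML config.

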