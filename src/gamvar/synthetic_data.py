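"""Generative model for synthetic community count data.

Emulates the structure of a long-running monthly trapping study: around
nine interacting species observed over hundreds of monthly sessions, with
low, zero-heavy counts, roughly five percent of sessions skipped, a
seasonal minimum-temperature covariate, and a slowly varying greenness
(NDVI) covariate.  Counts are drawn from the full model — Poisson
observations of latent log-means that combine per-species intercepts,
hierarchical NDVI slopes, a shared distributed-lag temperature smooth, and
stationary VAR(1) deviations with correlated process errors — so every
downstream stage (preprocessing, fitting, scoring, scenarios) can be tested
without any external download.

The covariates' marginal forms (sinusoid plus noise for temperature,
sinusoid plus slow random walk for NDVI) are this package's own emulation
choice; real series share the seasonality and persistence but not the exact
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics
from .preprocess import (
    CommunityTimeSeries,
    build_lag_design,
    moving_average,
    zscore,
)
from .smooths import build_distributed_lag_smooth

__all__ = [
    "SimulationConfig",
    "TrueParameterSet",
    "simulate_covariates",
    "default_true_params",
    "simulate_community",
    "simulate_dataset",
]

LEAD_IN = 12  # months of covariate lead-in before the count window


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic community."""

    n_species: int = 9
    n_months: int = 319
    missing_rate: float = 0.05
    seed: int = 0
    burn_in: int = 24
    # covariate generator settings
    temp_mean: float = 5.0
    temp_amplitude: float = 8.0
    temp_noise: float = 1.5
    ndvi_mean: float = 0.30
    ndvi_amplitude: float = 0.08
    ndvi_walk_sd: float = 0.012
    ndvi_noise: float = 0.02
    start_date: str = "1996-12-01"

    def __post_init__(self) -> None:
        if self.n_months < 24:
            raise ValueError(
                "n_months must be >= 24 so the 12-month moving average and "
                "6-month lags are computable"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class TrueParameterSet:
    """Ground-truth parameters of the generative model."""

    species_intercepts: np.ndarray
    ndvi_slopes: np.ndarray
    lag_surface_coefs: np.ndarray
    A: np.ndarray
    sigma: np.ndarray
    C: np.ndarray
    deviation_coefs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species_intercepts = np.atleast_1d(
            np.asarray(self.species_intercepts, dtype=float)
        )
        self.ndvi_slopes = np.atleast_1d(np.asarray(self.ndvi_slopes, dtype=float))
        self.lag_surface_coefs = np.asarray(self.lag_surface_coefs, dtype=float)
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))

    @property
    def n_species(self) -> int:
        return self.species_intercepts.size

    def validate(self) -> None:
        n = self.n_species
        if self.ndvi_slopes.size != n or self.sigma.size != n:
            raise ValueError("parameter sizes disagree")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if dynamics.spectral_radius(self.A) >= 1.0:
            raise ValueError("A must have spectral radius < 1")
        # raises if C is not a valid correlation matrix
        dynamics.make_covariance(self.sigma, self.C)

    def dynamics_params(self) -> dynamics.DynamicsParams:
        return dynamics.DynamicsParams(A=self.A, sigma=self.sigma, C=self.C)


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Monthly covariate table with a 12-month lead-in before the counts.

    Minimum temperature is an annual sinusoid (period 12) plus Gaussian
    noise; NDVI adds a slow random-walk trend to its sinusoid and is
    clipped to a plausible positive range.  ``time_index`` runs from
    ``-12`` (lead-in) through ``n_months - 1``.
    """
    rng = np.random.default_rng(config.seed)
    total = config.n_months + LEAD_IN
    t = np.arange(-LEAD_IN, config.n_months)
    phase = 2.0 * np.pi * t / 12.0
    mintemp = (
        config.temp_mean
        + config.temp_amplitude * np.sin(phase)
        + config.temp_noise * rng.standard_normal(total)
    )
    walk = np.cumsum(config.ndvi_walk_sd * rng.standard_normal(total))
    ndvi = (
        config.ndvi_mean
        + config.ndvi_amplitude * np.sin(phase + np.pi / 3.0)
        + walk
        + config.ndvi_noise * rng.standard_normal(total)
    )
    ndvi = np.clip(ndvi, 0.02, 0.95)
    dates = pd.date_range(
        pd.Timestamp(config.start_date) - pd.DateOffset(months=LEAD_IN),
        periods=total,
        freq="MS",
    )
    return pd.DataFrame(
        {
            "time_index": t,
            "date": dates.strftime("%Y-%m-%d"),
            "mintemp": mintemp,
            "ndvi": ndvi,
        }
    )


def _random_correlation(n: int, rng: np.random.Generator, eta: float = 4.0) -> np.ndarray:
    """Random correlation matrix via the C-vine / partial-correlation method."""
    if n == 1:
        return np.ones((1, 1))
    z = np.zeros((n, n))
    for j in range(n - 1):
        alpha = eta + (n - 1 - (j + 1)) / 2.0
        beta_draws = rng.beta(alpha, alpha, size=n - 1 - j)
        z[j + 1 :, j] = 2.0 * beta_draws - 1.0
    L = _cpc_to_cholesky(z)
    C = L @ L.T
    d = np.sqrt(np.diag(C))
    C = C / d[:, None] / d[None, :]
    np.fill_diagonal(C, 1.0)
    return C


def _cpc_to_cholesky(z: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of a correlation matrix from canonical partial
    correlations ``z`` (strictly inside (-1, 1), lower triangle used)."""
    n = z.shape[0]
    L = np.zeros((n, n))
    L[0, 0] = 1.0
    for i in range(1, n):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[i, j] * np.sqrt(rem)
            rem *= 1.0 - z[i, j] ** 2
        L[i, i] = np.sqrt(rem)
    return L


def default_true_params(
    n_species: int, seed: int = 0, n_lag_coefs: int = 11
) -> TrueParameterSet:
    """Draw a ground-truth parameter set satisfying every invariant.

    Off-diagonal lagged-dependence entries are drawn small (|.| <= 0.3)
    and the whole raw matrix is projected through the stationarity map, so
    the returned ``A`` always has spectral radius < 1; at least one
    off-diagonal entry is nonzero whenever ``n_species > 1``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(np.log(3.0), 0.35, size=n_species)
    slopes = rng.normal(0.25, 0.12, size=n_species)
    coefs = rng.normal(0.0, 0.25, size=n_lag_coefs)
    sigma = rng.uniform(0.22, 0.38, size=n_species)
    C = _random_correlation(n_species, rng)
    raw = np.clip(rng.normal(0.0, 0.18, size=(n_species, n_species)), -0.3, 0.3)
    np.fill_diagonal(raw, rng.normal(0.9, 0.2, size=n_species))
    if n_species > 1 and np.all(np.abs(raw - np.diag(np.diag(raw))) < 1e-12):
        raw[0, 1] = 0.2
    Sigma = dynamics.make_covariance(sigma, C)
    A = dynamics.map_to_stationary(raw, Sigma)
    params = TrueParameterSet(
        species_intercepts=intercepts,
        ndvi_slopes=slopes,
        lag_surface_coefs=coefs,
        A=A,
        sigma=sigma,
        C=C,
    )
    params.validate()
    return params


def build_true_mu(
    params: TrueParameterSet, covars: pd.DataFrame, config: SimulationConfig
):
    """Assemble the GAM predictor ``mu`` (n x T) from the true parameters.

    Returns ``(mu, v, dl_design)`` where ``v`` is the z-scored NDVI moving
    average over the count window and ``dl_design`` the constrained
    distributed-lag smooth built from the simulated temperatures.
    """
    t_idx = covars["time_index"].to_numpy()
    count_start = int(np.searchsorted(t_idx, 0))
    if count_start < LEAD_IN:
        raise ValueError(
            f"covariate window too short: need {LEAD_IN} months of lead-in"
        )
    ndvi = covars["ndvi"].to_numpy()
    ma = moving_average(ndvi, window=12)
    window = np.zeros(ma.size, dtype=bool)
    window[count_start:] = True
    v = zscore(ma, reference=window & np.isfinite(ma))[count_start:]
    temp_z = zscore(covars["mintemp"].to_numpy(), reference=window)
    lag_design = build_lag_design(temp_z, max_lag=6, start=count_start)
    dl = build_distributed_lag_smooth(lag_design)
    coefs = params.lag_surface_coefs
    if coefs.size != dl.n_coef:
        raise ValueError(
            f"lag_surface_coefs has length {coefs.size}, design expects {dl.n_coef}"
        )
    f_global = dl.X @ coefs
    mu = (
        params.species_intercepts[:, None]
        + params.ndvi_slopes[:, None] * v[None, :]
        + f_global[None, :]
    )
    for i, dev in params.deviation_coefs.items():
        mu[i] += dl.X @ np.asarray(dev, dtype=float)
    return mu, v, dl


def simulate_community(
    params: TrueParameterSet,
    covars: pd.DataFrame,
    config: SimulationConfig,
) -> CommunityTimeSeries:
    """Simulate counts from the full generative model.

    Latent deviations follow the stationary VAR(1); the initial state is
    drawn from the stationary distribution and a burn-in period is
    simulated and discarded so the recorded window starts at stationarity.
    Counts are Poisson with log-mean ``mu + z``; whole timepoints are then
    masked as missing at ``missing_rate`` (a skipped trapping session hides
    every species at once).
    """
    params.validate()
    rng = np.random.default_rng(config.seed + 1)
    mu, _, _ = build_true_mu(params, covars, config)
    n, T = mu.shape
    dyn = params.dynamics_params()
    mu_ext = np.concatenate([np.tile(mu[:, :1], (1, config.burn_in)), mu], axis=1)
    X = dynamics.simulate_states(dyn, mu_ext, seed=rng)[:, config.burn_in :]
    counts = rng.poisson(np.exp(X))
    mask = np.ones((n, T), dtype=bool)
    missing = rng.random(T) < config.missing_rate
    mask[:, missing] = False
    t_idx = covars["time_index"].to_numpy()
    count_start = int(np.searchsorted(t_idx, 0))
    dates = pd.DatetimeIndex(pd.to_datetime(covars["date"]))[count_start:]
    species = [f"sp{i + 1:02d}" for i in range(n)]
    return CommunityTimeSeries(
        counts=counts,
        mask=mask,
        species_ids=species,
        time_index=np.arange(T),
        dates=dates,
    )


def simulate_dataset(config: SimulationConfig, params: TrueParameterSet | None = None):
    """Convenience wrapper: covariates + true parameters + counts."""
    covars = simulate_covariates(config)
    if params is None:
        params = default_true_params(config.n_species, seed=config.seed)
    counts = simulate_community(params, covars, config)
    return params, covars, counts
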