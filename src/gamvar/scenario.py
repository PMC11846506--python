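"""Post-fit simulation tools: forecasts, impulse responses, covariate
contrasts and conditional distributed-lag functions.

All tools operate on :class:`~gamvar.inference.PosteriorDraws` so every
scenario quantity carries full posterior uncertainty.  Forecasts propagate
each draw's latent deviation forward with that draw's VAR coefficients and
process covariance, add the GAM predictor evaluated at (observed) future
covariates, and emit Poisson counts — the hindcast convention in which
environmental measurements for the evaluation period are taken as known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import PosteriorDraws
from .model import ModelData

__all__ = [
    "ForecastEnsemble",
    "ImpulseResponse",
    "forecast",
    "impulse_response",
    "covariate_contrast",
    "conditional_lag_function",
]


@dataclass
class ForecastEnsemble:
    """Posterior-predictive count draws over a forecast horizon."""

    counts: np.ndarray   # (draws, horizon, species)
    latent: np.ndarray   # (draws, horizon, species) latent states X
    mu: np.ndarray       # (draws, horizon, species) GAM predictor
    species_ids: list
    start: int           # first forecast time index

    @property
    def horizon(self) -> int:
        return self.counts.shape[1]

    def quantiles(self, probs=(0.05, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.95)):
        return np.quantile(self.counts, probs, axis=0)


@dataclass
class ImpulseResponse:
    """Per-draw change in log-mean captures after a one-time impulse."""

    responses: np.ndarray  # (draws, horizon + 1, species), horizon 0 = impact
    impulse_species: str
    extra_captures: float
    species_ids: list

    def median(self) -> np.ndarray:
        return np.median(self.responses, axis=0)


def _draw_indices(n_total: int, max_draws: int | None) -> np.ndarray:
    if max_draws is None or max_draws >= n_total:
        return np.arange(n_total)
    return np.linspace(0, n_total - 1, max_draws).astype(int)


def _sigma_chol(sigma: np.ndarray, C: np.ndarray) -> np.ndarray:
    Sig = sigma[:, None] * C * sigma[None, :]
    return np.linalg.cholesky(Sig)


def _mu_future(draws: PosteriorDraws, data: ModelData, d: int, rows: slice):
    """GAM predictor for one stacked draw over future design rows."""
    a = draws.stacked("a")[d]
    n = a.size
    h = rows.stop - rows.start
    mu = np.tile(a[:, None], (1, h))
    if "b" in draws.params:
        b = draws.stacked("b")[d]
        mu += b[:, None] * data.v_full[rows][None, :]
    if "beta_g" in draws.params:
        mu += (data.Xg_full[rows] @ draws.stacked("beta_g")[d])[None, :]
    for s in draws.dev_species:
        i = draws.species_ids.index(s)
        mu[i] += data.Xg_full[rows] @ draws.stacked(f"beta_dev:{s}")[d]
    return mu


def forecast(
    draws: PosteriorDraws,
    data: ModelData,
    horizon: int,
    seed: int = 0,
    max_draws: int | None = 500,
) -> ForecastEnsemble:
    """Posterior-predictive forecast for ``horizon`` steps past training.

    Requires observed covariates covering the horizon (``data`` carries the
    full covariate span even when the model was trained on a prefix).
    """
    T = draws.params["z"].shape[-1]
    if T + horizon > data.T_full:
        raise ValueError(
            f"future covariates cover only {data.T_full - T} steps, "
            f"horizon {horizon} requested"
        )
    rng = np.random.default_rng(seed)
    z_draws = draws.stacked("z")
    A_draws = draws.stacked("A")
    sig_draws = draws.stacked("sigma")
    C_draws = draws.stacked("C")
    idx = _draw_indices(z_draws.shape[0], max_draws)
    n = z_draws.shape[1]
    rows = slice(T, T + horizon)
    counts = np.empty((idx.size, horizon, n), dtype=int)
    latent = np.empty((idx.size, horizon, n))
    mus = np.empty((idx.size, horizon, n))
    for k, d in enumerate(idx):
        A = A_draws[d]
        Ls = _sigma_chol(sig_draws[d], C_draws[d])
        z = z_draws[d][:, -1]
        mu = _mu_future(draws, data, d, rows)
        for h in range(horizon):
            z = A @ z + Ls @ rng.standard_normal(n)
            x = mu[:, h] + z
            latent[k, h] = x
            mus[k, h] = mu[:, h]
            counts[k, h] = rng.poisson(np.exp(np.clip(x, -30, 30)))
    return ForecastEnsemble(
        counts=counts,
        latent=latent,
        mu=mus,
        species_ids=list(draws.species_ids),
        start=T,
    )


def impulse_response(
    draws: PosteriorDraws,
    species: str,
    extra_captures: float = 3.0,
    horizon: int = 6,
    max_draws: int | None = 1000,
) -> ImpulseResponse:
    """Generalized impulse response to extra captures of one species.

    The impulse is mapped to the latent (log) scale at each draw's baseline
    expected captures (posterior median of the GAM predictor over the
    training window): ``delta_i = log(lam_i + extra) - log(lam_i)``.
    Contemporaneous spillover uses the covariance-conditioned convention
    ``delta = Sigma[:, i] * delta_i / Sigma[i, i]`` — no species ordering is
    imposed — and the deviation is then propagated with that draw's ``A``.
    The response is the difference in log-mean captures, so a zero impulse
    gives an identically zero response.
    """
    if species not in draws.species_ids:
        raise ValueError(f"unknown species {species!r}")
    i = draws.species_ids.index(species)
    mu_draws = draws.stacked("mu")
    A_draws = draws.stacked("A")
    sig_draws = draws.stacked("sigma")
    C_draws = draws.stacked("C")
    idx = _draw_indices(mu_draws.shape[0], max_draws)
    n = mu_draws.shape[1]
    out = np.empty((idx.size, horizon + 1, n))
    for k, d in enumerate(idx):
        lam_base = np.exp(np.median(mu_draws[d], axis=1))
        delta_i = np.log(lam_base[i] + extra_captures) - np.log(lam_base[i])
        Sig = sig_draws[d][:, None] * C_draws[d] * sig_draws[d][None, :]
        delta = Sig[:, i] * (delta_i / Sig[i, i])
        resp = delta
        out[k, 0] = resp
        A = A_draws[d]
        for h in range(1, horizon + 1):
            resp = A @ resp
            out[k, h] = resp
    return ImpulseResponse(
        responses=out,
        impulse_species=species,
        extra_captures=float(extra_captures),
        species_ids=list(draws.species_ids),
    )


def covariate_contrast(
    draws: PosteriorDraws,
    data: ModelData,
    low: float = -0.50,
    high: float = 0.50,
):
    """Expected-capture change when the NDVI moving average shifts from a
    low to a high z-score value, all else at training references.

    Returns ``(delta, prop_at_or_below, prop_above)``: per-draw, per-species
    differences ``exp(mu(high)) - exp(mu(low))`` and the posterior
    probability mass at or below zero vs above zero.
    """
    if "b" not in draws.params:
        raise ValueError("model variant has no NDVI term")
    a = draws.stacked("a")
    b = draws.stacked("b")
    T = draws.params["z"].shape[-1]
    smooth_ref = np.zeros((a.shape[0], a.shape[1]))
    if "beta_g" in draws.params:
        fg_mean = data.Xg_full[:T].mean(axis=0)
        smooth_ref += (draws.stacked("beta_g") @ fg_mean)[:, None]
        for s in draws.dev_species:
            i = draws.species_ids.index(s)
            smooth_ref[:, i] += draws.stacked(f"beta_dev:{s}") @ fg_mean
    elif draws.dev_species:
        fg_mean = data.Xg_full[:T].mean(axis=0)
        for s in draws.dev_species:
            i = draws.species_ids.index(s)
            smooth_ref[:, i] += draws.stacked(f"beta_dev:{s}") @ fg_mean
    mu_ref = a + smooth_ref
    delta = np.exp(mu_ref + b * high) - np.exp(mu_ref + b * low)
    prop_le = (delta <= 0).mean(axis=0)
    return delta, prop_le, 1.0 - prop_le


def conditional_lag_function(
    draws: PosteriorDraws,
    data: ModelData,
    temperature_year: np.ndarray,
    n_functions: int = 1000,
    seed: int = 0,
    standardized: bool = False,
):
    """Simulated seasonal distributed-lag effect curves per species.

    For each calendar month the summed lag effect is evaluated using the
    supplied 12 monthly temperatures (wrapping across the year boundary);
    species with a deviation smooth get global + deviation, the rest the
    global function alone.  Curves are scaled to unit variance for
    comparison (skipped with a warning on zero-variance curves).

    Returns a dict species -> array (n_functions, 12).
    """
    if "beta_g" not in draws.params and not draws.dev_species:
        raise ValueError("model variant has no distributed-lag term")
    temps = np.asarray(temperature_year, dtype=float)
    if temps.size != 12:
        raise ValueError("temperature_year must have 12 monthly values")
    if not standardized:
        temps = (temps - data.temp_mean) / data.temp_sd
    L = data.max_lag
    value_rows = np.empty((12, L + 1))
    for m in range(12):
        for l in range(L + 1):
            value_rows[m, l] = temps[(m - l) % 12]
    rows = data.dl_design.evaluate(value_rows)  # (12, p)
    rng = np.random.default_rng(seed)
    n_total = draws.n_chains * draws.n_draws
    pick = rng.integers(0, n_total, size=n_functions)
    bg = draws.stacked("beta_g") if "beta_g" in draws.params else None
    out = {}
    for s in draws.species_ids:
        coefs = np.zeros((n_functions, rows.shape[1]))
        if bg is not None:
            coefs += bg[pick]
        if s in draws.dev_species:
            coefs += draws.stacked(f"beta_dev:{s}")[pick]
        curves = coefs @ rows.T  # (n_functions, 12)
        sd = curves.std(axis=1, keepdims=True)
        flat = sd[:, 0] <= 1e-12
        if np.any(flat):
            warnings.warn(
                "zero-variance lag-effect curves left unscaled", RuntimeWarning
            )
        sd[sd <= 1e-12] = 1.0
        out[s] = curves / sd
    return out
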