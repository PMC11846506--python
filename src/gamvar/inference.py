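"""Model fitting and MCMC diagnostics.

``fit`` runs the package's No-U-Turn sampler over the joint density of a
:class:`~gamvar.model.JointModel`, one chain per seed spawned from the
model-spec seed, and returns posterior draws of all constrained parameters
(including latent states) together with convergence diagnostics:
rank-normalized split-:math:`\\widehat{R}`, bulk and tail effective sample
sizes, and the divergence count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import ndtri

from .model import JointModel, ModelSpec
from .nuts import nuts_sample

__all__ = [
    "PosteriorDraws",
    "FitDiagnostics",
    "fit",
    "rank_normalized_rhat",
    "ess_bulk",
    "ess_tail",
    "randomized_quantile_residuals",
]


@dataclass
class PosteriorDraws:
    """Per-chain posterior draws with chain/draw structure preserved.

    ``params`` maps parameter names to arrays with leading dimensions
    (chains, draws); latent states ``X``, ``z`` and the GAM predictor
    ``mu`` have trailing (species, time) dimensions.
    """

    params: dict
    species_ids: list
    variant: str
    dev_species: list = field(default_factory=list)
    logp: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of ``name`` with chains flattened into one leading axis."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])


@dataclass
class FitDiagnostics:
    rhat: dict
    ess_bulk: dict
    ess_tail: dict
    n_divergent: int

    def max_rhat(self) -> float:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return float(np.max(vals)) if vals else np.nan


_TRACKED = ("a", "b", "mu_ndvi", "sigma_ndvi", "sigma", "A")


def fit(model: JointModel, spec: ModelSpec | None = None):
    """Sample the joint posterior; returns ``(PosteriorDraws, FitDiagnostics)``."""
    spec = spec or model.spec
    n, T = model.data.n_species, model.data.T
    ss = np.random.SeedSequence(spec.seed)
    chain_seeds = ss.spawn(spec.chains)
    all_draws, all_logps, n_div = [], [], 0
    for c in range(spec.chains):
        rng = np.random.default_rng(chain_seeds[c])
        last_err = None
        for attempt in range(3):
            theta0 = model.initial_theta(rng, jitter=0.05 * (attempt + 1))
            try:
                draws, logps, st = nuts_sample(
                    model.logp_and_grad,
                    theta0,
                    n_warmup=spec.warmup,
                    n_draws=spec.sampling,
                    seed=rng,
                    max_treedepth=spec.max_treedepth,
                    target_accept=spec.target_accept,
                )
                break
            except RuntimeError as err:
                last_err = err
        else:
            raise RuntimeError(
                f"initialization failed for chain {c} (seed {spec.seed}): {last_err}"
            )
        n_div += st.divergences
        all_draws.append(draws)
        all_logps.append(logps)

    # unpack every draw into constrained parameters
    nc, nd = spec.chains, spec.sampling
    first = model.unpack(all_draws[0][0])
    store = {}

    def alloc(name, shape):
        store[name] = np.empty((nc, nd) + shape)

    alloc("a", (n,))
    alloc("sigma", (n,))
    alloc("A", (n, n))
    alloc("C", (n, n))
    alloc("z", (n, T))
    alloc("mu", (n, T))
    alloc("X", (n, T))
    if "b" in first:
        alloc("b", (n,))
    if "mu_ndvi" in first:
        alloc("mu_ndvi", ())
        alloc("sigma_ndvi", ())
    if "beta_g" in first:
        alloc("beta_g", first["beta_g"].shape)
        alloc("lambda_g", first["lambda_g"].shape)
    for s in model.dev_species:
        alloc(f"beta_dev:{s}", first["beta_dev"][s].shape)
    for c in range(nc):
        for d in range(nd):
            p = model.unpack(all_draws[c][d])
            for key in ("a", "sigma", "A", "C", "z", "mu", "X"):
                store[key][c, d] = p[key]
            if "b" in store:
                store["b"][c, d] = p["b"]
            if "mu_ndvi" in store:
                store["mu_ndvi"][c, d] = p["mu_ndvi"]
                store["sigma_ndvi"][c, d] = p["sigma_ndvi"]
            if "beta_g" in store:
                store["beta_g"][c, d] = p["beta_g"]
                store["lambda_g"][c, d] = p["lambda_g"]
            for s in model.dev_species:
                store[f"beta_dev:{s}"][c, d] = p["beta_dev"][s]

    draws_out = PosteriorDraws(
        params=store,
        species_ids=list(model.data.species_ids),
        variant=spec.variant,
        dev_species=list(model.dev_species),
        logp=np.stack(all_logps),
    )

    rhat, essb, esst = {}, {}, {}
    for name in _TRACKED:
        if name not in store:
            continue
        arr = store[name]
        flat = arr.reshape(nc, nd, -1)
        for j in range(flat.shape[2]):
            key = name if flat.shape[2] == 1 else f"{name}[{j}]"
            x = flat[:, :, j]
            rhat[key] = rank_normalized_rhat(x)
            essb[key] = ess_bulk(x)
            esst[key] = ess_tail(x)
    diag = FitDiagnostics(rhat=rhat, ess_bulk=essb, ess_tail=esst, n_divergent=n_div)
    return draws_out, diag


# ---------------------------------------------------------------------------
# convergence statistics


def _split_chains(x: np.ndarray) -> np.ndarray:
    m, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, n - half :]], axis=0)


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    shape = x.shape
    r = sps.rankdata(x.ravel(), method="average").reshape(shape)
    S = x.size
    return ndtri((r - 3.0 / 8.0) / (S - 2.0 * 3.0 / 8.0 + 1.0))


def _basic_rhat(z: np.ndarray) -> float:
    m, n = z.shape
    chain_means = z.mean(axis=1)
    chain_vars = z.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    var_plus = (n - 1.0) / n * W + B / n
    if W <= 0:
        return np.nan
    return float(np.sqrt(var_plus / W))


def rank_normalized_rhat(x: np.ndarray) -> float:
    """Rank-normalized split-:math:`\\widehat{R}` for (chains, draws) input.

    Chains are split in half, pooled draws are mapped through inverse-normal
    fractional ranks, and the classic between/within variance ratio is
    computed on the transformed draws.  Degenerate (constant) draws return
    NaN with a warning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need >= 2 chains and >= 4 draws per chain")
    if np.allclose(x, x.flat[0]):
        warnings.warn("constant draws: rhat undefined", RuntimeWarning)
        return np.nan
    z = _rank_normalize(_split_chains(x))
    return _basic_rhat(z)


def _tau(z: np.ndarray) -> float:
    """Integrated autocorrelation time via Geyer's initial monotone sequence."""
    m, n = z.shape
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    zc = z - z.mean(axis=1, keepdims=True)
    f = np.fft.rfft(zc, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    chain_var = acov[:, 0] * n / (n - 1.0)
    mean_acov = acov.mean(axis=0)
    W = chain_var.mean()
    var_plus = W * (n - 1.0) / n + z.mean(axis=1).var(ddof=1)
    if var_plus <= 0:
        return np.nan
    rho = 1.0 - (W - mean_acov) / var_plus
    rho[0] = 1.0
    # Geyer pairs
    tau = 0.0
    t = 1
    pair_prev = np.inf
    tau = rho[0]
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, pair_prev)
        pair_prev = pair
        tau += 2.0 * pair
        t += 2
    return max(tau, 1.0 / np.log10(n + 10))


def _ess_from(z: np.ndarray) -> float:
    m, n = z.shape
    tau = _tau(z)
    if not np.isfinite(tau) or tau <= 0:
        return np.nan
    return float(m * n / tau)


def ess_bulk(x: np.ndarray) -> float:
    """Bulk effective sample size on rank-normalized split chains."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if np.allclose(x, x.flat[0]):
        return np.nan
    return _ess_from(_rank_normalize(_split_chains(x)))


def ess_tail(x: np.ndarray) -> float:
    """Tail ESS: minimum over the 5% and 95% quantile indicators."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if np.allclose(x, x.flat[0]):
        return np.nan
    out = []
    for q in (0.05, 0.95):
        ind = (x <= np.quantile(x, q)).astype(float)
        if np.allclose(ind, ind.flat[0]):
            out.append(np.nan)
        else:
            out.append(_ess_from(_rank_normalize(_split_chains(ind))))
    return float(np.nanmin(out))


# ---------------------------------------------------------------------------
# residuals


def randomized_quantile_residuals(
    draws: PosteriorDraws,
    counts: np.ndarray,
    mask: np.ndarray,
    max_draws: int = 200,
    seed: int = 0,
):
    """Dunn–Smyth residuals of observed counts under each posterior draw.

    For count ``y`` and that draw's Poisson rate ``lambda``, the residual is
    ``ndtri(u)`` with ``u ~ Uniform(F(y-1; lambda), F(y; lambda))`` (the
    lower limit is 0 when ``y = 0``).  Under a correctly specified model the
    residuals are standard normal and serially independent.  Returns an
    array (draws_used, species, time) with NaN at masked points.
    """
    rng = np.random.default_rng(seed)
    X = draws.stacked("X")
    nd = X.shape[0]
    use = np.linspace(0, nd - 1, min(max_draws, nd)).astype(int)
    counts = np.asarray(counts)
    mask = np.asarray(mask, dtype=bool)
    out = np.full((use.size, *counts.shape), np.nan)
    y = counts[mask]
    for k, d in enumerate(use):
        lam = np.exp(X[d][mask])
        lo = np.where(y > 0, sps.poisson.cdf(y - 1, lam), 0.0)
        hi = sps.poisson.cdf(y, lam)
        u = lo + (hi - lo) * rng.random(y.size)
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        res = np.full(counts.shape, np.nan)
        res[mask] = ndtri(u)
        out[k] = res
    return out
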