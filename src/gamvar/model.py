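"""Joint posterior densities for the GAM-VAR model family.

Four nested variants are supported, each a Poisson state-space model for
species-by-time counts:

``GAM-VAR``
    hierarchical NDVI slopes + shared and species-level distributed-lag
    temperature smooths + stationary VAR(1) latent dynamics with correlated
    process errors;
``GAM-AR``
    same GAM predictor, but independent AR(1) dynamics (diagonal ``A``,
    ``C = I``), removing covariances and temporal cross-dependence;
``GAM-AR-no-pooling``
    independent AR(1) dynamics and no community-level pooling: each species
    has its own NDVI slope and its own full-rank distributed-lag smooth;
``AR``
    per-species intercepts and independent AR(1) dynamics only.

The joint log-density is

.. math::
   \\sum_{(i,t)\\,\\mathrm{obs}} \\log\\mathrm{Pois}(Y_{it} \\mid e^{X_{it}})
   + \\log p(z \\mid A, \\Sigma) + \\log p(\\beta \\mid \\lambda)
   + \\log p(\\text{remaining parameters}),

with ``X = mu + z``.  Masked observations contribute nothing to the
observation term but their latent states remain defined.  All constrained
parameters are sampled on unconstrained scales (log scales for positive
parameters, tanh partial correlations for ``C``, the stationarity map for
``A``, non-centered innovations for ``z`` and non-centered hierarchical
slopes), and the gradient of the log-density is computed analytically by
reverse-mode accumulation through the whole construction — including the
matrix square root, Cholesky factors and the stationarity map — so the
model can be fit with gradient-based MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import gammaln

from ._kernels import forward_states, state_adjoints
from .preprocess import CommunityTimeSeries, LagDesign, build_lag_design, moving_average, zscore
from .smooths import build_distributed_lag_smooth, null_penalty

__all__ = ["ModelSpec", "ModelData", "JointModel", "build_model", "build_model_data"]

VARIANTS = ("GAM-VAR", "GAM-AR", "GAM-AR-no-pooling", "AR")

DEFAULT_PRIORS = {
    "intercept_sd": 2.0,
    "slope_sd": 1.0,          # independent slopes (no-pooling)
    "mu_ndvi_sd": 1.0,        # hierarchical slope mean
    "sigma_ndvi_rate": 2.0,   # Exponential rate on the slope sd
    "lambda_shape": 0.05,     # Gamma prior on smoothing parameters
    "lambda_rate": 0.005,
    "sigma_rate": 1.0,        # Exponential rate on process sds
    "lkj_eta": 2.0,
    "raw_A_sd": 0.5,
    "null_prec": 0.25,        # fixed precision on global-smooth null space
}


@dataclass
class ModelSpec:
    """Which variant to fit and how to run the sampler."""

    variant: str = "GAM-VAR"
    species_subset_for_deviations: list = field(default_factory=list)
    chains: int = 4
    warmup: int = 500
    sampling: int = 1600
    seed: int = 0
    max_treedepth: int = 10
    target_accept: float = 0.8
    priors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")

    def prior(self, key: str) -> float:
        return float(self.priors.get(key, DEFAULT_PRIORS[key]))


@dataclass
class ModelData:
    """Aligned model inputs: counts, mask, covariate designs, evaluators.

    ``T`` is the training length (columns of ``counts``); design rows run
    to ``T_full`` so posterior draws can be pushed through future
    timepoints with observed covariates (hindcast-style forecasting).
    """

    counts: np.ndarray
    mask: np.ndarray
    species_ids: list
    v_full: np.ndarray
    Xg_full: np.ndarray
    penalties_global: list
    penalties_dev: list
    dl_design: object  # PenalizedDesign with .evaluate
    lag_full: LagDesign
    max_lag: int
    temp_mean: float = 0.0
    temp_sd: float = 1.0

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def T(self) -> int:
        return self.counts.shape[1]

    @property
    def T_full(self) -> int:
        return self.v_full.size


def build_model_data(
    cts: CommunityTimeSeries,
    covariates: pd.DataFrame,
    max_lag: int = 6,
    k_lag: int = 4,
    k_temp: int = 3,
) -> ModelData:
    """Assemble designs from aligned count and covariate tables.

    The covariate table must include at least 12 months of lead-in before
    the first count timepoint.  Basis knots and z-scoring moments come from
    the training window (the count columns) only.
    """
    t_idx = covariates["time_index"].to_numpy()
    first = int(cts.time_index[0])
    count_start = int(np.searchsorted(t_idx, first))
    if t_idx[count_start] != first:
        raise ValueError("covariate table does not cover the count window")
    T = cts.n_times
    ndvi = covariates["ndvi"].to_numpy()
    temp = covariates["mintemp"].to_numpy()
    if count_start + T > t_idx.size:
        raise ValueError("covariate table shorter than the count window")
    ma = moving_average(ndvi, window=12)
    train = np.zeros(t_idx.size, dtype=bool)
    train[count_start : count_start + T] = True
    v_full = zscore(ma, reference=train & np.isfinite(ma))[count_start:]
    temp_mean = float(temp[train].mean())
    temp_sd = float(temp[train].std(ddof=1))
    temp_z = zscore(temp, reference=train)
    lag_full = build_lag_design(temp_z, max_lag=max_lag, start=count_start)
    lag_train = LagDesign(
        value_matrix=lag_full.value_matrix[:T], lag_matrix=lag_full.lag_matrix[:T]
    )
    dl = build_distributed_lag_smooth(lag_train, k_lag=k_lag, k_temp=k_temp)
    Xg_full = dl.evaluate(lag_full.value_matrix, lag_full.lag_matrix)
    pen_g = list(dl.penalties)
    Pn = null_penalty(pen_g)
    pen_d = pen_g + ([Pn] if Pn.any() else [])
    return ModelData(
        counts=np.asarray(cts.counts, dtype=float),
        mask=np.asarray(cts.mask, dtype=bool),
        species_ids=list(cts.species_ids),
        v_full=v_full,
        Xg_full=Xg_full,
        penalties_global=pen_g,
        penalties_dev=pen_d,
        dl_design=dl,
        lag_full=lag_full,
        max_lag=max_lag,
        temp_mean=temp_mean,
        temp_sd=temp_sd,
    )


# ---------------------------------------------------------------------------
# matrix adjoint helpers (verified against finite differences in the tests)


def _chol_adjoint(L: np.ndarray, Lbar: np.ndarray) -> np.ndarray:
    """Adjoint of ``L = chol(G)``: map ``dlogp/dL`` to symmetric ``dlogp/dG``."""
    M = L.T @ Lbar
    Phi = np.tril(M)
    Phi[np.diag_indices_from(Phi)] *= 0.5
    Z1 = solve_triangular(L, Phi, lower=True, trans="T", check_finite=False)
    Gbar = solve_triangular(L, Z1.T, lower=True, trans="T", check_finite=False).T
    return 0.5 * (Gbar + Gbar.T)


def _invsqrt_with_adjoint(M: np.ndarray):
    """Return ``R = M^{-1/2}`` and a closure mapping ``Rbar -> Mbar``."""
    w, V = np.linalg.eigh(M)
    f = 1.0 / np.sqrt(w)
    R = (V * f) @ V.T

    denom = w[:, None] - w[None, :]
    F = np.where(
        np.abs(denom) > 1e-12,
        (f[:, None] - f[None, :]) / np.where(np.abs(denom) > 1e-12, denom, 1.0),
        -0.5 * w[:, None] ** -1.5,
    )

    def adjoint(Rbar: np.ndarray) -> np.ndarray:
        Rs = 0.5 * (Rbar + Rbar.T)
        Mbar = V @ (F * (V.T @ Rs @ V)) @ V.T
        return 0.5 * (Mbar + Mbar.T)

    return R, adjoint


class JointModel:
    """A model variant bound to data: log-density, gradient, unpacking."""

    def __init__(self, spec: ModelSpec, data: ModelData):
        self.spec = spec
        self.data = data
        self.variant = spec.variant
        self.is_var = self.variant == "GAM-VAR"
        self.has_gam = self.variant != "AR"
        self.pooled = self.variant in ("GAM-VAR", "GAM-AR")
        self.has_global = self.variant in ("GAM-VAR", "GAM-AR")
        n = data.n_species
        if self.variant == "GAM-AR-no-pooling":
            self.dev_species = list(data.species_ids)
        elif self.has_global:
            self.dev_species = [
                s for s in spec.species_subset_for_deviations if s in data.species_ids
            ]
            missing = set(spec.species_subset_for_deviations) - set(data.species_ids)
            if missing:
                raise ValueError(f"unknown species in deviation subset: {sorted(missing)}")
        else:
            self.dev_species = []
        self.dev_index = [data.species_ids.index(s) for s in self.dev_species]
        self.p_g = data.Xg_full.shape[1]
        self.n_pen_g = len(data.penalties_global)
        self.n_pen_d = len(data.penalties_dev)

        # flat parameter layout
        sl, pos = {}, 0

        def block(name, size):
            nonlocal pos
            sl[name] = slice(pos, pos + size)
            pos += size

        block("a", n)
        if self.has_gam:
            if self.pooled:
                block("u", n)
                block("mu_ndvi", 1)
                block("log_sigma_ndvi", 1)
            else:
                block("b", n)
        if self.has_global:
            block("beta_g", self.p_g)
            block("log_lambda_g", self.n_pen_g)
        for s in self.dev_species:
            block(f"beta_dev:{s}", self.p_g)
            block(f"log_lambda_dev:{s}", self.n_pen_d)
        block("raw_A", n * n if self.is_var else n)
        block("log_sigma", n)
        if self.is_var:
            block("c_raw", n * (n - 1) // 2)
        block("eta", n * data.T)
        self.slices = sl
        self.dim = pos

        T = data.T
        self.Y = data.counts[:, :T]
        self.mask = data.mask[:, :T]
        self.v = data.v_full[:T]
        self.Xg = data.Xg_full[:T]
        self.XgT = self.Xg.T.copy()
        self._loglik_const = -float(
            np.sum(gammaln(self.Y[self.mask] + 1.0))
        )
        Png = null_penalty(data.penalties_global)
        self._fixed_prec_global = (
            self.spec.prior("null_prec") * Png if Png.any() else None
        )
        # LKJ exponents for the canonical partial correlations, by column
        if self.is_var and n > 1:
            eta_lkj = spec.prior("lkj_eta")
            ij = [(i, j) for i in range(1, n) for j in range(i)]
            self._cpc_ij = ij
            self._cpc_alpha = np.array(
                [eta_lkj + (n - 1.0 - (j + 1.0)) / 2.0 for (_, j) in ij]
            )

    # -- parameter handling -------------------------------------------------

    def initial_theta(self, rng: np.random.Generator, jitter: float = 0.05) -> np.ndarray:
        th = np.zeros(self.dim)
        data, sl = self.data, self.slices
        obs_mean = np.array(
            [
                data.counts[i][data.mask[i]].mean() if data.mask[i].any() else 1.0
                for i in range(data.n_species)
            ]
        )
        th[sl["a"]] = np.log(obs_mean + 0.5)
        if self.has_gam and self.pooled:
            th[sl["log_sigma_ndvi"]] = np.log(0.3)
        if self.has_global:
            th[sl["log_lambda_g"]] = np.log(10.0)
        for s in self.dev_species:
            th[sl[f"log_lambda_dev:{s}"]] = np.log(10.0)
        th[sl["log_sigma"]] = np.log(0.3)
        th += jitter * rng.standard_normal(self.dim)
        return th

    def _dynamics_forward(self, th):
        """Build (L_C, L_sig, P, K, L0, A) and caches for the backward pass."""
        n = self.data.n_species
        sl = self.slices
        sigma = np.exp(th[sl["log_sigma"]])
        if self.is_var and n > 1:
            y = th[sl["c_raw"]]
            zc = np.tanh(y)
            L_C = np.zeros((n, n))
            L_C[0, 0] = 1.0
            rem_cache = np.zeros((n, n))
            zmat = np.zeros((n, n))
            for idx, (i, j) in enumerate(self._cpc_ij):
                zmat[i, j] = zc[idx]
            for i in range(1, n):
                rem = 1.0
                for j in range(i):
                    rem_cache[i, j] = rem
                    L_C[i, j] = zmat[i, j] * np.sqrt(rem)
                    rem *= 1.0 - zmat[i, j] ** 2
                rem_cache[i, i] = rem
                L_C[i, i] = np.sqrt(rem)
            cache_c = (y, zc, zmat, rem_cache)
        else:
            L_C = np.eye(n)
            cache_c = None
        L_sig = sigma[:, None] * L_C
        if self.is_var:
            B = th[sl["raw_A"]].reshape(n, n)
        else:
            B = np.diag(th[sl["raw_A"]])
        M = np.eye(n) + B @ B.T
        R, r_adj = _invsqrt_with_adjoint(M)
        P = R @ B
        G = np.eye(n) - P @ P.T
        K = np.linalg.cholesky(G)
        L0 = solve_triangular(K, L_sig.T, lower=True, trans="T", check_finite=False).T
        Kinv = solve_triangular(K, np.eye(n), lower=True, check_finite=False)
        L0inv = np.linalg.inv(L0)
        A = L0 @ P @ L0inv
        return dict(
            sigma=sigma, L_C=L_C, L_sig=L_sig, B=B, M=M, R=R, r_adj=r_adj,
            P=P, G=G, K=K, Kinv=Kinv, L0=L0, L0inv=L0inv, A=A, cache_c=cache_c,
        )

    def unpack(self, th: np.ndarray) -> dict:
        """Named constrained parameters and latent states for one draw."""
        data, sl = self.data, self.slices
        n, T = data.n_species, data.T
        dyn = self._dynamics_forward(th)
        out = {
            "a": th[sl["a"]].copy(),
            "sigma": dyn["sigma"],
            "A": dyn["A"],
            "C": dyn["L_C"] @ dyn["L_C"].T,
            "L_sig": dyn["L_sig"],
            "L0": dyn["L0"],
        }
        if self.has_gam:
            if self.pooled:
                sN = float(np.exp(th[sl["log_sigma_ndvi"]][0]))
                out["mu_ndvi"] = float(th[sl["mu_ndvi"]][0])
                out["sigma_ndvi"] = sN
                out["b"] = out["mu_ndvi"] + sN * th[sl["u"]]
            else:
                out["b"] = th[sl["b"]].copy()
        if self.has_global:
            out["beta_g"] = th[sl["beta_g"]].copy()
            out["lambda_g"] = np.exp(th[sl["log_lambda_g"]])
        out["beta_dev"] = {
            s: th[sl[f"beta_dev:{s}"]].copy() for s in self.dev_species
        }
        out["lambda_dev"] = {
            s: np.exp(th[sl[f"log_lambda_dev:{s}"]]) for s in self.dev_species
        }
        eta = np.ascontiguousarray(th[sl["eta"]].reshape(n, T))
        z = forward_states(dyn["A"], dyn["L0"], dyn["L_sig"], eta)
        out["z"] = z
        out["mu"] = self._mu(out)
        out["X"] = out["mu"] + z
        return out

    def _mu(self, params: dict) -> np.ndarray:
        data = self.data
        n, T = data.n_species, data.T
        mu = np.tile(params["a"][:, None], (1, T))
        if self.has_gam:
            mu += params["b"][:, None] * self.v[None, :]
        if self.has_global:
            mu += (self.Xg @ params["beta_g"])[None, :]
        for s, i in zip(self.dev_species, self.dev_index):
            mu[i] += self.Xg @ params["beta_dev"][s]
        return mu

    # -- the joint density ---------------------------------------------------

    def logp_and_grad(self, th: np.ndarray):
        try:
            return self._logp_and_grad(th)
        except np.linalg.LinAlgError:
            # numerically degenerate corner (e.g. vanishing smoothing
            # parameter): zero posterior density, reject the proposal
            return -np.inf, np.zeros(self.dim)

    def _logp_and_grad(self, th: np.ndarray):
        spec, data, sl = self.spec, self.data, self.slices
        n, T = data.n_species, data.T
        grad = np.zeros(self.dim)
        lp = 0.0

        a = th[sl["a"]]
        if self.has_gam:
            if self.pooled:
                u = th[sl["u"]]
                muN = th[sl["mu_ndvi"]][0]
                lsN = th[sl["log_sigma_ndvi"]][0]
                sN = np.exp(lsN)
                b = muN + sN * u
            else:
                b = th[sl["b"]]
        dyn = self._dynamics_forward(th)
        A, L0, L_sig = dyn["A"], dyn["L0"], dyn["L_sig"]

        eta = np.ascontiguousarray(th[sl["eta"]].reshape(n, T))
        z = forward_states(A, L0, L_sig, eta)

        mu = np.broadcast_to(a[:, None], (n, T)).copy()
        if self.has_gam:
            mu += b[:, None] * self.v[None, :]
        if self.has_global:
            bg = th[sl["beta_g"]]
            fg = self.Xg @ bg
            mu += fg[None, :]
        bdev = {}
        for s, i in zip(self.dev_species, self.dev_index):
            bd = th[sl[f"beta_dev:{s}"]]
            bdev[s] = bd
            mu[i] += self.Xg @ bd
        X = mu + z
        if np.max(X) > 40.0:
            return -np.inf, grad
        lam = np.exp(X)
        lp += float(np.sum(self.mask * (self.Y * X - lam)))
        gX = self.mask * (self.Y - lam)

        # --- priors on simple blocks -------------------------------------
        isd = spec.prior("intercept_sd")
        lp += -0.5 * float(a @ a) / isd**2
        grad[sl["a"]] += gX.sum(axis=1) - a / isd**2

        gb = np.zeros(n)
        if self.has_gam:
            gb = gX @ self.v
            if self.pooled:
                msd = spec.prior("mu_ndvi_sd")
                srate = spec.prior("sigma_ndvi_rate")
                lp += -0.5 * float(u @ u) - 0.5 * muN**2 / msd**2
                lp += -srate * sN + lsN
                grad[sl["u"]] += sN * gb - u
                grad[sl["mu_ndvi"]] += gb.sum() - muN / msd**2
                grad[sl["log_sigma_ndvi"]] += sN * float(u @ gb) - srate * sN + 1.0
            else:
                ssd = spec.prior("slope_sd")
                lp += -0.5 * float(b @ b) / ssd**2
                grad[sl["b"]] += gb - b / ssd**2

        gcol = gX.sum(axis=0)  # shared across species
        if self.has_global:
            gbg = self.XgT @ gcol
            lp_s, g_beta, g_llam = self._smooth_prior(
                bg, th[sl["log_lambda_g"]], data.penalties_global,
                fixed=self._fixed_prec_global,
            )
            lp += lp_s
            grad[sl["beta_g"]] += gbg + g_beta
            grad[sl["log_lambda_g"]] += g_llam
        for s, i in zip(self.dev_species, self.dev_index):
            gbd = self.XgT @ gX[i]
            lp_s, g_beta, g_llam = self._smooth_prior(
                bdev[s], th[sl[f"log_lambda_dev:{s}"]], data.penalties_dev,
            )
            lp += lp_s
            grad[sl[f"beta_dev:{s}"]] += gbd + g_beta
            grad[sl[f"log_lambda_dev:{s}"]] += g_llam

        # --- latent state backward pass ----------------------------------
        Wm = state_adjoints(A, gX)
        Abar = Wm[:, 1:] @ z[:, :-1].T
        Lsig_bar = Wm[:, 1:] @ eta[:, 1:].T
        geta = np.empty((n, T))
        geta[:, 1:] = L_sig.T @ Wm[:, 1:]
        w0 = Wm[:, 0]
        L0bar = np.outer(w0, eta[:, 0])
        geta[:, 0] = L0.T @ w0
        lp += -0.5 * float(np.sum(eta * eta))
        grad[sl["eta"]] += (geta - eta).ravel()

        # --- adjoints through the stationarity construction ----------------
        P, K, Kinv, L0inv = dyn["P"], dyn["K"], dyn["Kinv"], dyn["L0inv"]
        W = L0inv
        # A = L0 P W
        Pbar = L0.T @ Abar @ W.T
        L0bar += Abar @ W.T @ P.T - A.T @ Abar @ W.T
        # L0 = L_sig K^{-1}
        Lsig_bar += L0bar @ Kinv.T
        Kbar = -L0.T @ L0bar @ Kinv.T
        Gbar = _chol_adjoint(K, np.tril(Kbar))
        Pbar += -2.0 * Gbar @ P
        # P = R B
        R, B = dyn["R"], dyn["B"]
        Bbar = R @ Pbar
        Rbar = Pbar @ B.T
        Mbar = dyn["r_adj"](Rbar)
        Bbar += 2.0 * Mbar @ B
        rawA_sd = spec.prior("raw_A_sd")
        if self.is_var:
            Braw = B
            lp += -0.5 * float(np.sum(Braw * Braw)) / rawA_sd**2
            grad[sl["raw_A"]] += (Bbar - Braw / rawA_sd**2).ravel()
        else:
            bdiag = np.diag(B)
            lp += -0.5 * float(bdiag @ bdiag) / rawA_sd**2
            grad[sl["raw_A"]] += np.diag(Bbar) - bdiag / rawA_sd**2

        # L_sig = diag(sigma) L_C
        sigma, L_C = dyn["sigma"], dyn["L_C"]
        Lsig_bar = np.tril(Lsig_bar)
        sig_bar = np.sum(Lsig_bar * L_C, axis=1)
        srate = spec.prior("sigma_rate")
        lsig = th[sl["log_sigma"]]
        lp += float(np.sum(-srate * sigma + lsig))
        grad[sl["log_sigma"]] += sigma * sig_bar - srate * sigma + 1.0

        if self.is_var and n > 1:
            LCbar = sigma[:, None] * Lsig_bar
            y, zc, zmat, rem_cache = dyn["cache_c"]
            zbar_mat = np.zeros((n, n))
            for i in range(1, n):
                # backward through row i: L[i,j] = z_ij sqrt(rem_j),
                # rem_{j+1} = rem_j (1 - z_ij^2), L[i,i] = sqrt(rem_i)
                rbar = np.zeros(n + 1)
                rem_i = rem_cache[i, i]
                rbar[i] = LCbar[i, i] * 0.5 / np.sqrt(rem_i)
                for j in range(i - 1, -1, -1):
                    rem_j = rem_cache[i, j]
                    zij = zmat[i, j]
                    # rem_{j+1} = rem_j (1 - z^2)
                    zbar_mat[i, j] += rbar[j + 1] * rem_j * (-2.0 * zij)
                    rbar[j] += rbar[j + 1] * (1.0 - zij**2)
                    zbar_mat[i, j] += LCbar[i, j] * np.sqrt(rem_j)
                    rbar[j] += LCbar[i, j] * zij * 0.5 / np.sqrt(rem_j)
            zflat_bar = np.array([zbar_mat[i, j] for (i, j) in self._cpc_ij])
            # LKJ prior (canonical partial correlations) + tanh Jacobian
            lp += float(np.sum(self._cpc_alpha * np.log1p(-zc**2)))
            dz = zflat_bar + self._cpc_alpha * (-2.0 * zc) / (1.0 - zc**2)
            grad[sl["c_raw"]] += dz * (1.0 - zc**2)

        if not np.isfinite(lp):
            return -np.inf, np.zeros(self.dim)
        return lp + self._loglik_const, grad

    def _smooth_prior(self, beta, llam, penalties, fixed=None):
        """Penalty-matrix normal prior with Gamma-distributed smoothing
        parameters; returns (logp, dlogp/dbeta, dlogp/dloglambda)."""
        spec = self.spec
        lam = np.exp(llam)
        p = beta.size
        Q = np.zeros((p, p)) if fixed is None else fixed.copy()
        for lj, Sj in zip(lam, penalties):
            Q += lj * Sj
        Lq = np.linalg.cholesky(Q)
        logdet = 2.0 * float(np.sum(np.log(np.diag(Lq))))
        Qb = Q @ beta
        lp = -0.5 * float(beta @ Qb) + 0.5 * logdet
        g_beta = -Qb
        Qinv = np.linalg.inv(Q)
        a_g = spec.prior("lambda_shape")
        r_g = spec.prior("lambda_rate")
        g_llam = np.empty(lam.size)
        for j, (lj, Sj) in enumerate(zip(lam, penalties)):
            g_llam[j] = lj * (
                -0.5 * float(beta @ Sj @ beta) + 0.5 * float(np.sum(Qinv * Sj))
            )
            lp += a_g * llam[j] - r_g * lj
            g_llam[j] += a_g - r_g * lj
        return lp, g_beta, g_llam

    # -- pointwise likelihood (for LOO / residuals) ---------------------------

    def pointwise_loglik(self, X_draws: np.ndarray) -> np.ndarray:
        """Log-pmf at each observed point for each draw.

        ``X_draws`` has shape (draws, n, T); returns (draws, n_obs) in
        mask order (species varying slowest).
        """
        obs = self.mask
        y = self.Y[obs]
        Xo = X_draws[:, obs]
        return y[None, :] * Xo - np.exp(Xo) - gammaln(y + 1.0)[None, :]


def build_model(spec: ModelSpec, data: ModelData) -> JointModel:
    """Bind a model variant to data; raises on unknown variants."""
    return JointModel(spec, data)
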