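"""Model comparison and forecast verification.

In-sample comparison uses Pareto-smoothed importance-sampling leave-one-out
cross-validation (PSIS-LOO): per-observation importance ratios are
stabilized by replacing the largest tail with expected order statistics of
a fitted generalized Pareto distribution, and the resulting expected log
pointwise predictive density (ELPD) is compared across models with
pointwise-difference standard errors.

Out-of-sample comparison uses exact leave-future-out cross-validation on an
expanding window: models are refit on each training prefix and their
posterior-predictive count ensembles for the next ``horizon`` months are
scored with an evenly weighted combination of two proper multivariate
scoring rules — the energy score (calibration of the joint forecast) and
the variogram score (pairwise dependence between species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .inference import fit
from .model import ModelSpec, build_model, build_model_data
from .preprocess import CommunityTimeSeries
from .scenario import forecast

__all__ = [
    "LooResult",
    "ScoreReport",
    "psis_smooth",
    "elpd_loo",
    "elpd_compare",
    "energy_score",
    "variogram_score",
    "combined_score",
    "leave_future_out_cv",
]

DEFAULT_ORIGINS = (75, 115, 154, 194, 233, 273)
MIN_PSIS_DRAWS = 25


@dataclass
class LooResult:
    elpd: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray

    @property
    def n_points(self) -> int:
        return self.pointwise.size


@dataclass
class ScoreReport:
    """Tidy per-fold, per-horizon forecast scores."""

    table: pd.DataFrame  # columns: model, fold, origin, horizon, score_type, value
    skipped: pd.DataFrame  # timepoints without complete observations

    def fold_means(self, score_type: str = "combined") -> pd.DataFrame:
        sub = self.table[self.table["score_type"] == score_type]
        return (
            sub.groupby(["model", "fold"])["value"].mean().unstack("model")
        )

    def model_means(self, score_type: str = "combined") -> pd.Series:
        sub = self.table[self.table["score_type"] == score_type]
        return sub.groupby("model")["value"].mean()


# ---------------------------------------------------------------------------
# PSIS


def _gpd_fit(z: np.ndarray):
    """Generalized Pareto (k, sigma) via the Zhang–Stephens posterior-mean
    estimator on sorted exceedances."""
    n = z.size
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m / (np.arange(1, m + 1) - 0.5))
    b /= prior_bs * z[int(n / 4 + 0.5) - 1]
    b += 1.0 / z[-1]
    k = np.log1p(-b[:, None] * z[None, :]).mean(axis=1)
    log_lik = n * (np.log(-(b / k)) - k - 1.0)
    weights = 1.0 / np.exp(log_lik - log_lik[:, None]).sum(axis=1)
    b_post = float(np.sum(b * weights))
    k_post = float(np.log1p(-b_post * z).mean())
    sigma = -k_post / b_post
    k_post = k_post * n / (n + prior_k) + prior_k * 0.5 / (n + prior_k)
    return k_post, sigma


def _gpd_quantiles(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if np.abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def psis_smooth(log_ratios: np.ndarray):
    """Pareto-smoothed, self-normalized importance weights for one point.

    The ``M = min(0.2 S, 3 sqrt(S))`` largest ratios are replaced by
    expected order statistics of a generalized Pareto fit to their
    exceedances, truncated at the raw maximum, then self-normalized.
    Returns ``(weights, k_hat)``.
    """
    lr = np.asarray(log_ratios, dtype=float).ravel()
    S = lr.size
    if S < MIN_PSIS_DRAWS:
        raise ValueError(f"need at least {MIN_PSIS_DRAWS} draws, got {S}")
    x = lr - lr.max()
    M = int(min(0.2 * S, 3.0 * np.sqrt(S)))
    order = np.argsort(x)
    tail_idx = order[S - M :]
    cutoff = x[order[S - M - 1]]
    exc = np.exp(x[tail_idx]) - np.exp(cutoff)
    exc_sorted = np.sort(exc)
    if exc_sorted[-1] <= 0 or np.allclose(exc_sorted, exc_sorted[0]):
        khat = -np.inf  # degenerate tail: nothing to smooth
        smoothed = x.copy()
    else:
        khat, sigma = _gpd_fit(exc_sorted[exc_sorted > 0]
                               if np.any(exc_sorted <= 0) else exc_sorted)
        p = (np.arange(1, M + 1) - 0.5) / M
        repl = np.log(np.exp(cutoff) + _gpd_quantiles(p, khat, sigma))
        smoothed = x.copy()
        rank = np.argsort(x[tail_idx])
        smoothed[tail_idx[rank]] = repl
        smoothed = np.minimum(smoothed, 0.0)  # truncate at the raw maximum
    w = np.exp(smoothed - smoothed.max())
    return w / w.sum(), float(khat)


def elpd_loo(pointwise_loglik: np.ndarray) -> LooResult:
    """PSIS-LOO expected log pointwise predictive density.

    ``pointwise_loglik`` is draws x points.  Points with tail shape
    ``k_hat > 0.7`` trigger a warning but are kept.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood draws must be finite")
    S, npts = ll.shape
    pointwise = np.empty(npts)
    ks = np.empty(npts)
    for i in range(npts):
        w, k = psis_smooth(-ll[:, i])
        ks[i] = k
        m = ll[:, i].max()
        pointwise[i] = m + np.log(np.sum(w * np.exp(ll[:, i] - m)))
    n_bad = int(np.sum(ks > 0.7))
    if n_bad:
        warnings.warn(
            f"{n_bad} of {npts} points have Pareto k > 0.7; "
            "PSIS-LOO may be unreliable there",
            RuntimeWarning,
        )
    elpd = float(pointwise.sum())
    se = float(np.sqrt(npts * pointwise.var(ddof=1)))
    return LooResult(elpd=elpd, se=se, pointwise=pointwise, pareto_k=ks)


def elpd_compare(results: dict) -> pd.DataFrame:
    """Rank models by ELPD; differences are relative to the best model.

    The best model's row shows difference 0.0 with SE 0.0; other rows show
    the summed pointwise difference and its standard error
    ``sqrt(n * var(pointwise diffs))``.
    """
    names = list(results)
    npts = {results[m].n_points for m in names}
    if len(npts) != 1:
        raise ValueError("models were scored on different observation sets")
    best = max(names, key=lambda m: results[m].elpd)
    rows = []
    for m in sorted(names, key=lambda m: -results[m].elpd):
        if m == best:
            rows.append((m, results[m].elpd, results[m].se, 0.0, 0.0))
        else:
            d = results[m].pointwise - results[best].pointwise
            rows.append(
                (m, results[m].elpd, results[m].se, float(d.sum()),
                 float(np.sqrt(d.size * d.var(ddof=1))))
            )
    return pd.DataFrame(
        rows, columns=["model", "elpd", "se", "elpd_diff", "se_diff"]
    )


# ---------------------------------------------------------------------------
# proper multivariate scores


def energy_score(ensemble: np.ndarray, y: np.ndarray) -> float:
    """Energy score of an ``(M, n)`` ensemble against an ``n``-vector.

    ``ES = (1/M) sum_m ||x_m - y|| - (1/(2 M^2)) sum_{m,m'} ||x_m - x_m'||``
    """
    X = np.atleast_2d(np.asarray(ensemble, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    M = X.shape[0]
    if M < 2:
        raise ValueError("ensemble needs at least 2 members")
    if X.shape[1] != y.size:
        raise ValueError("ensemble and observation dimensions differ")
    t1 = cdist(X, y[None, :]).mean()
    t2 = pdist(X).sum() / M**2  # off-diagonal pairs counted once; x2 / (2M^2)
    return float(t1 - t2)


def variogram_score(
    ensemble: np.ndarray, y: np.ndarray, p: float = 0.5, w: np.ndarray | None = None
) -> float:
    """Variogram score of order ``p`` with optional pair weights.

    ``VS = sum_{i<j} w_ij (|y_i - y_j|^p - (1/M) sum_m |x_mi - x_mj|^p)^2``
    """
    X = np.atleast_2d(np.asarray(ensemble, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    M, n = X.shape
    if n < 2:
        raise ValueError("variogram score needs at least 2 series")
    if M < 2:
        raise ValueError("ensemble needs at least 2 members")
    if y.size != n:
        raise ValueError("ensemble and observation dimensions differ")
    iu = np.triu_indices(n, k=1)
    vy = np.abs(y[:, None] - y[None, :])[iu] ** p
    vx = (np.abs(X[:, :, None] - X[:, None, :]) ** p).mean(axis=0)[iu]
    ww = np.ones(vy.size) if w is None else np.asarray(w, dtype=float)[iu]
    return float(np.sum(ww * (vy - vx) ** 2))


def combined_score(ensemble, y, p: float = 0.5) -> float:
    """Evenly weighted combination of the energy and variogram scores."""
    return 0.5 * (energy_score(ensemble, y) + variogram_score(ensemble, y, p=p))


# ---------------------------------------------------------------------------
# leave-future-out cross-validation


def leave_future_out_cv(
    cts: CommunityTimeSeries,
    covariates: pd.DataFrame,
    specs: dict,
    origins=DEFAULT_ORIGINS,
    horizon: int = 12,
    variogram_p: float = 0.5,
    forecast_draws: int = 400,
    seed: int = 0,
) -> ScoreReport:
    """Exact expanding-window leave-future-out cross-validation.

    For each origin, every model in ``specs`` (name -> :class:`ModelSpec`)
    is refit on the first ``origin`` timepoints and its posterior-predictive
    ensemble for the next ``horizon`` months is scored against the held-out
    observations.  Timepoints without a complete observation vector
    (skipped sessions) are flagged and not scored.
    """
    origins = list(origins)
    T = cts.n_times
    for o in origins:
        if o + horizon > T:
            raise ValueError(
                f"origin {o} + horizon {horizon} exceeds series length {T}"
            )
    rows, skipped = [], []
    for fold, origin in enumerate(origins):
        train = cts.subset_times(origin)
        data = build_model_data(train, covariates)
        for name, spec in specs.items():
            m = build_model(spec, data)
            draws, _ = fit(m, spec)
            ens = forecast(
                draws, data, horizon=horizon, seed=seed + 1000 * fold,
                max_draws=forecast_draws,
            )
            for h in range(horizon):
                t = origin + h
                if not cts.mask[:, t].all():
                    skipped.append((name, fold, origin, h + 1, int(t)))
                    continue
                y = cts.counts[:, t]
                X = ens.counts[:, h, :]
                es = energy_score(X, y)
                vs = variogram_score(X, y, p=variogram_p)
                rows.append((name, fold, origin, h + 1, "energy", es))
                rows.append((name, fold, origin, h + 1, "variogram", vs))
                rows.append((name, fold, origin, h + 1, "combined", 0.5 * (es + vs)))
    table = pd.DataFrame(
        rows, columns=["model", "fold", "origin", "horizon", "score_type", "value"]
    )
    skipped_df = pd.DataFrame(
        skipped, columns=["model", "fold", "origin", "horizon", "time"]
    )
    return ScoreReport(table=table, skipped=skipped_df)


def loglik_matrix(model, draws, max_draws: int | None = None) -> np.ndarray:
    """Pointwise log-likelihood (draws x observed points) for PSIS-LOO."""
    X = draws.stacked("X")
    if max_draws is not None and X.shape[0] > max_draws:
        X = X[np.linspace(0, X.shape[0] - 1, max_draws).astype(int)]
    return model.pointwise_loglik(X)
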