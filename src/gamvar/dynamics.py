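"""Latent VAR(1) machinery with enforced stationarity.

The latent deviations :math:`z_t` of each species' log-mean from its GAM
predictor follow a first-order vector autoregression

.. math:: z_t = A z_{t-1} + \\varepsilon_t, \\qquad
          \\varepsilon_t \\sim \\mathcal{N}(0, \\Sigma),

where the diagonal of ``A`` captures density dependence, the off-diagonals
lagged cross-species dependence, and ``Sigma = diag(sigma) C diag(sigma)``
combines per-species process scales with a correlation matrix of
contemporaneous process errors.

Stationarity (spectral radius of ``A`` strictly below one, so forecast
variance converges rather than growing without bound) is enforced by
parameterizing ``A`` through an unconstrained real matrix: the raw matrix is
squashed to a partial-autocorrelation-like matrix ``P`` with all singular
values below one, and ``A`` is recovered so that the process with innovation
covariance ``Sigma`` is stationary.  The order-1 construction used here is
closed form:

.. math::
   P = (I + BB^\\top)^{-1/2} B, \\quad
   L_0 = \\mathrm{chol}(\\Sigma)\\,\\mathrm{chol}(I - PP^\\top)^{-1}, \\quad
   A = L_0 P L_0^{-1},

which makes ``A`` similar to ``P`` (hence spectral radius < 1 for every real
input) and gives the stationary covariance directly as
``Gamma = L_0 L_0^T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

__all__ = [
    "DynamicsParams",
    "map_to_stationary",
    "stationary_factors",
    "make_covariance",
    "stationary_covariance",
    "simulate_states",
]


def _check_correlation(C: np.ndarray) -> None:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("C must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("C must have unit diagonal")
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as err:
        raise ValueError("C must be positive definite") from err


@dataclass
class DynamicsParams:
    """Stationary VAR(1) parameters for ``n`` interacting series.

    Attributes
    ----------
    A : (n, n) coefficient matrix, spectral radius < 1.
    sigma : (n,) strictly positive process standard deviations.
    C : (n, n) correlation matrix of contemporaneous process errors.
    """

    A: np.ndarray
    sigma: np.ndarray
    C: np.ndarray
    Sigma: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        _check_correlation(self.C)
        rho = spectral_radius(self.A)
        if rho >= 1.0:
            raise ValueError(f"A is not stationary (spectral radius {rho:.4f} >= 1)")
        self.Sigma = make_covariance(self.sigma, self.C)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def stationary_covariance(self) -> np.ndarray:
        return stationary_covariance(self.A, self.Sigma)


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.atleast_2d(A)))))


def make_covariance(sigma: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Assemble ``Sigma = diag(sigma) C diag(sigma)`` (symmetric PD)."""
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    _check_correlation(C)
    return sigma[:, None] * C * sigma[None, :]


def stationary_factors(
    raw_A: np.ndarray, Sigma: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(P, L0, A)`` of the stationarity-enforcing construction.

    ``P`` has all singular values < 1; ``L0`` is the lower-triangular factor
    of the stationary covariance ``Gamma = L0 L0^T``; ``A = L0 P L0^{-1}``.
    """
    B = np.atleast_2d(np.asarray(raw_A, dtype=float))
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    if B.shape != Sigma.shape:
        raise ValueError("raw_A and Sigma must have matching shapes")
    try:
        L_sig = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as err:
        raise ValueError("Sigma must be positive definite") from err
    n = B.shape[0]
    # symmetric inverse square root of I + B B^T via eigendecomposition
    M = np.eye(n) + B @ B.T
    w, V = np.linalg.eigh(M)
    R = (V * (1.0 / np.sqrt(w))) @ V.T
    P = R @ B
    K = np.linalg.cholesky(np.eye(n) - P @ P.T)
    L0 = sla.solve_triangular(K, L_sig.T, lower=True, trans="T").T
    A = L0 @ P @ np.linalg.inv(L0)
    return P, L0, A


def map_to_stationary(raw_A: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Map an unconstrained real matrix to a stationary VAR(1) coefficient
    matrix for innovation covariance ``Sigma``.

    Guaranteed spectral radius < 1 for every real input; smooth and
    injective.  ``raw_A = 0`` maps to ``A = 0``; for ``n = 1`` the map is
    ``a = r / sqrt(1 + r^2)``.
    """
    _, _, A = stationary_factors(raw_A, Sigma)
    return A


def stationary_covariance(A: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Solve the discrete Lyapunov equation ``Gamma = A Gamma A^T + Sigma``."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    rho = spectral_radius(A)
    if rho >= 1.0:
        raise ValueError(f"A is not stationary (spectral radius {rho:.4f} >= 1)")
    Gamma = sla.solve_discrete_lyapunov(A, Sigma)
    return 0.5 * (Gamma + Gamma.T)


def simulate_states(
    params: DynamicsParams,
    mu: np.ndarray,
    init: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate latent states ``X = mu + z`` on top of an ``n x T`` predictor.

    ``z_1`` is drawn from the stationary distribution ``N(0, Gamma)`` unless
    ``init`` supplies a starting deviation; thereafter
    ``z_t = A z_{t-1} + eps_t`` with ``eps_t ~ N(0, Sigma)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    n, T = mu.shape
    if n != params.n:
        raise ValueError("mu row count must equal number of series")
    L_sig = np.linalg.cholesky(params.Sigma)
    z = np.empty((n, T))
    if init is not None:
        z[:, 0] = np.asarray(init, dtype=float)
    else:
        Gamma = params.stationary_covariance()
        z[:, 0] = np.linalg.cholesky(Gamma) @ rng.standard_normal(n)
    eps = L_sig @ rng.standard_normal((n, max(T - 1, 0)))
    for t in range(1, T):
        z[:, t] = params.A @ z[:, t - 1] + eps[:, t - 1]
    return mu + z
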