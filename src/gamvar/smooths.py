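"""Penalized spline bases for hierarchical distributed-lag smooths.

The nonlinear temperature response is a tensor-product smooth of two
marginal bases — a cubic regression spline over lag (default four basis
functions) and a low-rank thin-plate spline over minimum temperature
(default three) — summed over lags 0..L so that each timepoint receives the
accumulated effect of the past half year of temperatures.  A shared
community-level surface is paired with per-species deviation surfaces whose
null spaces are fully penalized, so deviations shrink to zero unless the
data support them.

Each construction returns a :class:`PenalizedDesign` carrying the design
matrix, one symmetric positive semidefinite penalty per smoothing
parameter, the dimension of the unpenalized null space, and an ``evaluate``
callable for fresh covariate values (needed for scenario simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "PenalizedDesign",
    "HierarchicalSmoothSet",
    "cubic_basis",
    "thin_plate_basis",
    "tensor_product",
    "distributed_lag_design",
    "sum_to_zero",
    "make_hierarchical",
]

_PSD_TOL = 1e-8


@dataclass
class PenalizedDesign:
    """Design matrix with its penalty matrices and null-space metadata."""

    X: np.ndarray
    penalties: list
    nullspace_dim: int
    constraint: np.ndarray | None = None  # reparameterization Z, columns = new basis
    evaluate: Callable | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.penalties = [np.asarray(S, dtype=float) for S in self.penalties]
        p = self.X.shape[1]
        for S in self.penalties:
            if S.shape != (p, p):
                raise ValueError("penalty dimension must match design columns")
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValueError("penalties must be symmetric")
            if np.linalg.eigvalsh(S).min() < -_PSD_TOL * max(
                1.0, float(np.abs(S).max())
            ):
                raise ValueError("penalties must be positive semidefinite")

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


@dataclass
class HierarchicalSmoothSet:
    """Shared community-level smooth plus per-species deviation smooths."""

    global_design: PenalizedDesign
    deviations: dict
    species_subset: list


def _quantile_knots(x: np.ndarray, k: int) -> np.ndarray:
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct covariate values")
    knots = np.quantile(np.unique(x), np.linspace(0, 1, k))
    if np.unique(knots).size < k:
        raise ValueError(f"need at least {k} distinct covariate values")
    return knots


def cubic_basis(x, k: int = 4) -> PenalizedDesign:
    """Cardinal cubic regression spline with knots at covariate quantiles.

    Basis function ``j`` is the natural cubic spline interpolating the
    indicator of knot ``j``; the penalty is the integrated squared second
    derivative, whose null space (constant and linear functions) has
    dimension 2.
    """
    x = np.asarray(x, dtype=float).ravel()
    if k < 3:
        raise ValueError("cubic basis needs k >= 3")
    knots = _quantile_knots(x, k)
    h = np.diff(knots)
    # D maps knot values to scaled second differences, B is the natural
    # spline Gram matrix; F = B^{-1} D gives second derivatives at interior
    # knots and S = D' B^{-1} D the curvature penalty.
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    F_int = np.linalg.solve(B, D)
    F = np.vstack([np.zeros(k), F_int, np.zeros(k)])  # natural end conditions
    S = D.T @ F_int
    S = 0.5 * (S + S.T)

    def evaluate(xnew) -> np.ndarray:
        xv = np.asarray(xnew, dtype=float).ravel()
        out = np.zeros((xv.size, k))
        j = np.clip(np.searchsorted(knots, xv, side="right") - 1, 0, k - 2)
        lo, hi = knots[j], knots[j + 1]
        hj = hi - lo
        inside = (xv >= knots[0]) & (xv <= knots[-1])
        am = (hi - xv) / hj
        ap = (xv - lo) / hj
        cm = ((hi - xv) ** 3 / hj - hj * (hi - xv)) / 6.0
        cp = ((xv - lo) ** 3 / hj - hj * (xv - lo)) / 6.0
        for r in np.nonzero(inside)[0]:
            out[r, j[r]] += am[r]
            out[r, j[r] + 1] += ap[r]
            out[r] += cm[r] * F[j[r]] + cp[r] * F[j[r] + 1]
        # linear extrapolation beyond the knot range (natural spline)
        for r in np.nonzero(~inside)[0]:
            if xv[r] < knots[0]:
                hj0 = h[0]
                slope = (_unit(k, 1) - _unit(k, 0)) / hj0 - hj0 * F[1] / 6.0
                out[r] = _unit(k, 0) + (xv[r] - knots[0]) * slope
            else:
                hje = h[-1]
                slope = (_unit(k, k - 1) - _unit(k, k - 2)) / hje + hje * F[k - 2] / 6.0
                out[r] = _unit(k, k - 1) + (xv[r] - knots[-1]) * slope
        return out

    return PenalizedDesign(
        X=evaluate(x), penalties=[S], nullspace_dim=2, evaluate=evaluate
    )


def _unit(k: int, j: int) -> np.ndarray:
    e = np.zeros(k)
    e[j] = 1.0
    return e


def thin_plate_basis(x, k: int = 3, max_knots: int = 50) -> PenalizedDesign:
    """Low-rank thin-plate regression spline (1-D, order-2 penalty).

    Full radial basis ``|x - x_j|^3 / 12`` on the distinct covariate values
    is eigen-truncated, on the orthogonal complement of the polynomial null
    space, to ``k - 2`` penalized directions; the constant and linear
    functions complete the basis, so the unconstrained null space has
    dimension 2.  Penalized columns are scaled so their penalty is the
    identity.
    """
    x = np.asarray(x, dtype=float).ravel()
    if k < 3:
        raise ValueError("thin-plate basis needs k >= 3")
    pts = np.unique(x)
    if pts.size < k:
        raise ValueError(f"need at least {k} distinct covariate values")
    if pts.size > max_knots:
        pts = np.quantile(pts, np.linspace(0, 1, max_knots))
        pts = np.unique(pts)
    q = pts.size
    center, scale = pts.mean(), pts.std()
    E = np.abs(pts[:, None] - pts[None, :]) ** 3 / 12.0
    T = np.column_stack([np.ones(q), (pts - center) / scale])
    Z = null_space(T.T)  # q x (q-2)
    M = Z.T @ E @ Z
    M = 0.5 * (M + M.T)
    w, U = np.linalg.eigh(M)
    order = np.argsort(w)[::-1][: k - 2]
    w_sel = w[order]
    if np.any(w_sel <= 0):
        raise ValueError("thin-plate penalty is not positive on selected modes")
    # radial coefficient directions, scaled so the penalty becomes I
    W = Z @ U[:, order] / np.sqrt(w_sel)[None, :]

    def evaluate(xnew) -> np.ndarray:
        xv = np.asarray(xnew, dtype=float).ravel()
        e = np.abs(xv[:, None] - pts[None, :]) ** 3 / 12.0
        rad = e @ W
        poly = np.column_stack([np.ones(xv.size), (xv - center) / scale])
        return np.column_stack([poly, rad])

    S = np.zeros((k, k))
    S[2:, 2:] = np.eye(k - 2)
    return PenalizedDesign(
        X=evaluate(x), penalties=[S], nullspace_dim=2, evaluate=evaluate
    )


def _total_penalty(d: PenalizedDesign) -> np.ndarray:
    return np.sum(d.penalties, axis=0)


def tensor_product(b_lag: PenalizedDesign, b_temp: PenalizedDesign) -> PenalizedDesign:
    """Tensor-product smooth of two marginal bases.

    Columns are row-wise Kronecker products (``k_lag * k_temp`` of them);
    exactly two penalties result, each marginal roughness penalty expanded
    against the identity of the other margin.
    """
    if b_lag.X.shape[0] != b_temp.X.shape[0]:
        raise ValueError("marginal bases must be built on matched rows")
    kl, kt = b_lag.n_coef, b_temp.n_coef
    X = np.einsum("ij,ik->ijk", b_lag.X, b_temp.X).reshape(-1, kl * kt)
    S1 = np.kron(_total_penalty(b_lag), np.eye(kt))
    S2 = np.kron(np.eye(kl), _total_penalty(b_temp))
    ev_l, ev_t = b_lag.evaluate, b_temp.evaluate

    def evaluate(lag_vals, temp_vals) -> np.ndarray:
        Bl = ev_l(lag_vals)
        Bt = ev_t(temp_vals)
        return np.einsum("ij,ik->ijk", Bl, Bt).reshape(-1, kl * kt)

    return PenalizedDesign(
        X=X,
        penalties=[S1, S2],
        nullspace_dim=b_lag.nullspace_dim * b_temp.nullspace_dim,
        evaluate=evaluate,
    )


def distributed_lag_design(
    tensor: PenalizedDesign, lag_design
) -> PenalizedDesign:
    """Sum the tensor basis over lags 0..L for each timepoint.

    Row ``t`` equals ``sum_l B(lag=l, temp=value_matrix[t, l])``; penalties
    are inherited unchanged because the summation is linear in the
    coefficients.
    """
    V = lag_design.value_matrix
    Lmat = lag_design.lag_matrix
    T, L1 = V.shape
    p = len(tensor.penalties[0])
    X = np.zeros((T, p))
    for l in range(L1):
        X += tensor.evaluate(Lmat[:, l], V[:, l])

    def evaluate(value_row, lag_row=None) -> np.ndarray:
        vr = np.atleast_2d(np.asarray(value_row, dtype=float))
        lr = (
            np.tile(np.arange(vr.shape[1], dtype=float), (vr.shape[0], 1))
            if lag_row is None
            else np.atleast_2d(np.asarray(lag_row, dtype=float))
        )
        out = np.zeros((vr.shape[0], p))
        for l in range(vr.shape[1]):
            out += tensor.evaluate(lr[:, l], vr[:, l])
        return out

    return PenalizedDesign(
        X=X,
        penalties=list(tensor.penalties),
        nullspace_dim=tensor.nullspace_dim,
        evaluate=evaluate,
    )


def sum_to_zero(design: PenalizedDesign) -> PenalizedDesign:
    """Absorb the identifiability constraint ``sum_t f(t) = 0``.

    The coefficient space is reparameterized onto the null space of the
    design's column-sum vector, dropping one column; penalties follow the
    same transform.  Column sums of the constrained design are ~0, keeping
    the smooth orthogonal to the intercept.
    """
    c = design.X.sum(axis=0)[None, :]
    Z = null_space(c)
    Xc = design.X @ Z
    pens = [Z.T @ S @ Z for S in design.penalties]
    pens = [0.5 * (S + S.T) for S in pens]
    ns = _joint_null_dim(pens)
    ev = design.evaluate

    def evaluate(*args, **kwargs) -> np.ndarray:
        return ev(*args, **kwargs) @ Z

    return PenalizedDesign(
        X=Xc, penalties=pens, nullspace_dim=ns, constraint=Z, evaluate=evaluate
    )


def _joint_null_dim(penalties: Sequence[np.ndarray]) -> int:
    St = np.sum(penalties, axis=0)
    w = np.linalg.eigvalsh(St)
    tol = max(1.0, float(w.max())) * 1e-9
    return int(np.sum(w < tol))


def null_penalty(penalties: Sequence[np.ndarray]) -> np.ndarray:
    """Projector onto the joint null space of the given penalties."""
    St = np.sum(penalties, axis=0)
    St = 0.5 * (St + St.T)
    w, V = np.linalg.eigh(St)
    tol = max(1.0, float(w.max())) * 1e-9
    N = V[:, w < tol]
    return N @ N.T


def build_distributed_lag_smooth(
    lag_design, k_lag: int = 4, k_temp: int = 3, constrain: bool = True
) -> PenalizedDesign:
    """Full distributed-lag tensor smooth from a :class:`LagDesign`.

    Marginal bases are built on the pooled (lag, temperature) points of the
    lag design — a cubic regression spline over lag, a low-rank thin-plate
    spline over temperature — then tensored, summed over lags, and (by
    default) centered with the sum-to-zero constraint.
    """
    lags_flat = lag_design.lag_matrix.ravel()
    temps_flat = lag_design.value_matrix.ravel()
    b_lag = cubic_basis(lags_flat, k=k_lag)
    b_temp = thin_plate_basis(temps_flat, k=k_temp)
    tensor = tensor_product(b_lag, b_temp)
    dl = distributed_lag_design(tensor, lag_design)
    return sum_to_zero(dl) if constrain else dl


def make_hierarchical(
    global_design: PenalizedDesign, species_subset, species_ids=None
) -> HierarchicalSmoothSet:
    """Pair the (constrained) global smooth with per-species deviations.

    Each deviation shares the global basis dimensions but carries its own
    penalties and smoothing parameters, including a projector penalty on
    the joint null space so that every nonzero deviation is penalized —
    deviations appear only where the data support them.  Species effects
    are global + deviation.
    """
    species_subset = list(species_subset)
    if not species_subset:
        raise ValueError("species_subset must be nonempty")
    if species_ids is not None:
        unknown = [s for s in species_subset if s not in species_ids]
        if unknown:
            raise ValueError(f"unknown species labels: {unknown}")
    Pn = null_penalty(global_design.penalties)
    deviations = {}
    for sp in species_subset:
        pens = list(global_design.penalties)
        if Pn.any():
            pens = pens + [Pn]
        deviations[sp] = PenalizedDesign(
            X=global_design.X.copy(),
            penalties=pens,
            nullspace_dim=0,
            constraint=global_design.constraint,
            evaluate=global_design.evaluate,
        )
    return HierarchicalSmoothSet(
        global_design=global_design,
        deviations=deviations,
        species_subset=species_subset,
    )
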