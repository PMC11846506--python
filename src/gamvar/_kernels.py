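"""Hot loops of the joint-density evaluation.

The sequential VAR(1) state recursion (forward) and its reverse-mode
adjoint recursion (backward) are the only O(T) loops in a gradient
evaluation; they are JIT-compiled with numba when available and fall back
to vectorized numpy otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _forward_nb(A, L0, Lsig, eta):
    n, T = eta.shape
    z = np.empty((n, T))
    for i in range(n):
        acc = 0.0
        for j in range(n):
            acc += L0[i, j] * eta[j, 0]
        z[i, 0] = acc
    for t in range(1, T):
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += A[i, j] * z[j, t - 1] + Lsig[i, j] * eta[j, t]
            z[i, t] = acc
    return z


@njit(cache=False)
def _adjoint_nb(A, gX):
    """Accumulated state adjoints W with W[:, t] = sum_{s>=t} (A^T)^{s-t} gX[:, s]."""
    n, T = gX.shape
    W = gX.copy()
    for t in range(T - 1, 0, -1):
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += A[j, i] * W[j, t]
            W[i, t - 1] += acc
    return W


def forward_states(A, L0, Lsig, eta):
    if _HAVE_NUMBA:
        return _forward_nb(A, L0, Lsig, eta)
    n, T = eta.shape
    z = np.empty((n, T))
    z[:, 0] = L0 @ eta[:, 0]
    eps = Lsig @ eta[:, 1:]
    for t in range(1, T):
        z[:, t] = A @ z[:, t - 1] + eps[:, t - 1]
    return z


def state_adjoints(A, gX):
    if _HAVE_NUMBA:
        return _adjoint_nb(A, gX)
    n, T = gX.shape
    W = gX.copy()
    AT = A.T
    for t in range(T - 1, 0, -1):
        W[:, t - 1] += AT @ W[:, t]
    return W
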