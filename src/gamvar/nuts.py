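"""No-U-Turn sampler with dual-averaging step size and diagonal mass
adaptation.

A self-contained adaptive Hamiltonian Monte Carlo implementation used by
:mod:`gamvar.inference`: multinomial trajectory sampling, the generalized
no-U-turn termination criterion on sub-trees, Stan-style warmup windows
(initial step-size phase, doubling covariance-estimation windows, final
step-size phase), and divergence detection via the energy error.  Only the
joint log-density and its gradient are required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["nuts_sample", "NutsStats"]

_MAX_ENERGY_ERROR = 1000.0


@dataclass
class NutsStats:
    divergences: int
    step_size: float
    inv_mass: np.ndarray
    mean_accept: float
    n_grad_evals: int
    treedepths: np.ndarray


class _Tree:
    __slots__ = (
        "theta_m", "r_m", "grad_m", "theta_p", "r_p", "grad_p",
        "theta_prop", "grad_prop", "logp_prop", "log_weight", "rho",
        "turning", "diverging",
    )


def _kinetic(r: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(r * inv_mass, r))


def nuts_sample(
    logp_grad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    seed,
    max_treedepth: int = 10,
    target_accept: float = 0.8,
):
    """Run one NUTS chain; returns ``(draws, logps, stats)``.

    ``logp_grad(theta)`` must return the joint log-density and its
    gradient; non-finite values are treated as rejections/divergences.
    """
    rng = np.random.default_rng(seed)
    theta = np.array(theta0, dtype=float)
    dim = theta.size
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise RuntimeError("initialization failure: non-finite log density at start")
    inv_mass = np.ones(dim)
    n_evals = [1]

    def wrapped(th):
        n_evals[0] += 1
        lp, g = logp_grad(th)
        if not np.isfinite(lp) or not np.all(np.isfinite(g)):
            return -np.inf, np.zeros(dim)
        return lp, g

    def leapfrog(th, r, g, eps):
        r1 = r + 0.5 * eps * g
        th1 = th + eps * inv_mass * r1
        lp1, g1 = wrapped(th1)
        r1 = r1 + 0.5 * eps * g1
        return th1, r1, g1, lp1

    # --- initial step size heuristic -------------------------------------
    eps = 0.1 / dim**0.25
    r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(r0, inv_mass)
    _, r1, _, lp1 = leapfrog(theta, r0, grad, eps)
    dh = (lp1 - _kinetic(r1, inv_mass)) - h0
    direction = 1 if dh > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, _, lp1 = leapfrog(theta, r0, grad, eps)
        dh = (lp1 - _kinetic(r1, inv_mass)) - h0
        if not np.isfinite(dh):
            dh = -np.inf
        if (direction == 1 and dh <= np.log(0.5)) or (
            direction == -1 and dh >= np.log(0.5)
        ):
            break

    # --- dual averaging state --------------------------------------------
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # --- warmup window schedule (Stan-like) -------------------------------
    if n_warmup >= 150:
        init_buf, term_buf, base_win = 75, 50, 25
    else:
        init_buf = max(1, int(0.15 * n_warmup))
        term_buf = max(1, int(0.10 * n_warmup))
        base_win = max(1, n_warmup - init_buf - term_buf)
    window_ends = []
    pos, win = init_buf, base_win
    while pos + win < n_warmup - term_buf:
        window_ends.append(pos + win)
        pos += win
        win *= 2
    window_ends.append(n_warmup - term_buf)

    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    treedepths = np.zeros(n_draws, dtype=int)
    divergences = 0
    accepts = []
    adapt_count = 0

    def build_tree(th, r, g, lp, direction, depth, eps, h0):
        tree = _Tree()
        if depth == 0:
            th1, r1, g1, lp1 = leapfrog(th, r, g, direction * eps)
            h1 = lp1 - _kinetic(r1, inv_mass)
            delta = h1 - h0
            tree.diverging = (not np.isfinite(delta)) or (-delta > _MAX_ENERGY_ERROR)
            tree.turning = False
            tree.theta_m = tree.theta_p = tree.theta_prop = th1
            tree.r_m = tree.r_p = r1
            tree.grad_m = tree.grad_p = tree.grad_prop = g1
            tree.logp_prop = lp1
            tree.log_weight = -np.inf if tree.diverging else delta
            tree.rho = r1.copy()
            accepts.append(min(1.0, np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0)
            return tree
        first = build_tree(th, r, g, lp, direction, depth - 1, eps, h0)
        if first.diverging or first.turning:
            return first
        if direction == 1:
            second = build_tree(
                first.theta_p, first.r_p, first.grad_p, 0.0, direction, depth - 1, eps, h0
            )
            first.theta_p, first.r_p, first.grad_p = (
                second.theta_p, second.r_p, second.grad_p,
            )
        else:
            second = build_tree(
                first.theta_m, first.r_m, first.grad_m, 0.0, direction, depth - 1, eps, h0
            )
            first.theta_m, first.r_m, first.grad_m = (
                second.theta_m, second.r_m, second.grad_m,
            )
        first.diverging = second.diverging
        total = np.logaddexp(first.log_weight, second.log_weight)
        if np.isfinite(total) and np.log(rng.random()) < second.log_weight - total:
            first.theta_prop = second.theta_prop
            first.grad_prop = second.grad_prop
            first.logp_prop = second.logp_prop
        first.log_weight = total
        first.rho = first.rho + second.rho
        first.turning = second.turning or _uturn(
            first.rho, first.r_m, first.r_p, inv_mass
        )
        return first

    total_iters = n_warmup + n_draws
    for it in range(total_iters):
        r = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - _kinetic(r, inv_mass)
        theta_prop, grad_prop, logp_prop = theta, grad, logp
        log_weight = 0.0
        rho = r.copy()
        th_m, r_m, g_m = theta, r, grad
        th_p, r_p, g_p = theta, r, grad
        depth = 0
        sum_accept_start = len(accepts)
        diverged = False
        while depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                sub = build_tree(th_p, r_p, g_p, 0.0, 1, depth, eps, h0)
                th_p, r_p, g_p = sub.theta_p, sub.r_p, sub.grad_p
            else:
                sub = build_tree(th_m, r_m, g_m, 0.0, -1, depth, eps, h0)
                th_m, r_m, g_m = sub.theta_m, sub.r_m, sub.grad_m
            if sub.diverging:
                diverged = True
                break
            if sub.turning:
                break
            total = np.logaddexp(log_weight, sub.log_weight)
            if np.log(rng.random()) < sub.log_weight - total:
                theta_prop, grad_prop, logp_prop = (
                    sub.theta_prop, sub.grad_prop, sub.logp_prop,
                )
            log_weight = total
            rho = rho + sub.rho
            if _uturn(rho, r_m, r_p, inv_mass):
                break
            depth += 1
        theta, grad, logp = theta_prop, grad_prop, logp_prop

        new_accepts = accepts[sum_accept_start:]
        accept_stat = float(np.mean(new_accepts)) if new_accepts else 0.0

        if it < n_warmup:
            adapt_count += 1
            h_bar = (1.0 - 1.0 / (adapt_count + t0)) * h_bar + (
                target_accept - accept_stat
            ) / (adapt_count + t0)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            w = adapt_count**-kappa
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it >= init_buf and it < window_ends[-1]:
                welford_n += 1
                d = theta - welford_mean
                welford_mean += d / welford_n
                welford_m2 += d * (theta - welford_mean)
                if it + 1 in window_ends and welford_n > 1:
                    var = welford_m2 / (welford_n - 1)
                    inv_mass = var * (welford_n / (welford_n + 5.0)) + 1e-3 * (
                        5.0 / (welford_n + 5.0)
                    )
                    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)
                    mu = np.log(10.0 * eps)
                    h_bar, adapt_count = 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            if diverged:
                divergences += 1
            j = it - n_warmup
            draws[j] = theta
            logps[j] = logp
            treedepths[j] = depth

    stats = NutsStats(
        divergences=divergences,
        step_size=eps,
        inv_mass=inv_mass,
        mean_accept=float(np.mean(accepts)) if accepts else 0.0,
        n_grad_evals=n_evals[0],
        treedepths=treedepths,
    )
    return draws, logps, stats


def _uturn(rho, r_m, r_p, inv_mass) -> bool:
    v_m = inv_mass * r_m
    v_p = inv_mass * r_p
    return bool(np.dot(rho, v_m) <= 0.0 or np.dot(rho, v_p) <= 0.0)
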