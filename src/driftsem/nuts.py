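"""No-U-Turn sampler with dual-averaging step-size and diagonal mass
adaptation.

A compact, dependency-free implementation of multinomial NUTS (the variant
used by modern probabilistic-programming backends): trajectories double
until the first U-turn, and the next state is drawn from the whole
trajectory with weights proportional to the canonical density.  Warmup
adapts the step size toward a target acceptance statistic and estimates a
diagonal mass matrix from an intermediate warmup window.

The sampler is generic: it only needs a callable returning the log target
density and its gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["nuts_sample", "NUTSStats"]

_MAX_DELTA_H = 1000.0  # divergence threshold


@dataclass
class NUTSStats:
    step_size: float
    inv_mass: np.ndarray
    accept_rate: float
    divergences: int
    treedepths: np.ndarray


class _Tree:
    __slots__ = (
        "x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
        "x_prop", "logw", "sum_p", "n_div", "stop", "sum_accept", "n_accept",
    )


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p, inv_mass * p))


def _leapfrog(x, p, g, eps, logp_grad, inv_mass):
    p = p + 0.5 * eps * g
    x = x + eps * inv_mass * p
    lp, g = logp_grad(x)
    p = p + 0.5 * eps * g
    return x, p, g, lp


def _uturn(x_plus, x_minus, p_plus, p_minus, inv_mass):
    dx = x_plus - x_minus
    return (
        float(np.dot(dx, inv_mass * p_minus)) < 0.0
        or float(np.dot(dx, inv_mass * p_plus)) < 0.0
    )


def _build_tree(x, p, g, direction, depth, eps, h0, logp_grad, inv_mass, rng):
    if depth == 0:
        x1, p1, g1, lp1 = _leapfrog(x, p, g, direction * eps, logp_grad, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass)
        dh = h1 - h0
        t = _Tree()
        t.x_minus = t.x_plus = t.x_prop = x1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = g1
        t.logw = dh if np.isfinite(dh) else -np.inf
        t.sum_p = p1.copy()
        t.n_div = 0 if dh > -_MAX_DELTA_H else 1
        t.stop = bool(t.n_div)
        t.sum_accept = float(min(1.0, np.exp(min(dh, 0.0)))) if np.isfinite(dh) else 0.0
        t.n_accept = 1
        return t

    inner = _build_tree(x, p, g, direction, depth - 1, eps, h0, logp_grad, inv_mass, rng)
    if inner.stop:
        return inner
    if direction == 1:
        outer = _build_tree(
            inner.x_plus, inner.p_plus, inner.g_plus, 1, depth - 1, eps, h0,
            logp_grad, inv_mass, rng,
        )
        inner.x_plus, inner.p_plus, inner.g_plus = outer.x_plus, outer.p_plus, outer.g_plus
    else:
        outer = _build_tree(
            inner.x_minus, inner.p_minus, inner.g_minus, -1, depth - 1, eps, h0,
            logp_grad, inv_mass, rng,
        )
        inner.x_minus, inner.p_minus, inner.g_minus = outer.x_minus, outer.p_minus, outer.g_minus

    total = np.logaddexp(inner.logw, outer.logw)
    if np.isfinite(total) and np.log(rng.random()) < outer.logw - total:
        inner.x_prop = outer.x_prop
    inner.logw = total
    inner.sum_p = inner.sum_p + outer.sum_p
    inner.n_div += outer.n_div
    inner.stop = outer.stop
    inner.sum_accept += outer.sum_accept
    inner.n_accept += outer.n_accept
    if _uturn(inner.x_plus, inner.x_minus, inner.p_plus, inner.p_minus, inv_mass):
        inner.stop = True  # internal u-turn stops the doubling
    return inner


def _nuts_step(x, lp, g, eps, logp_grad, inv_mass, mass, rng, max_treedepth):
    p0 = rng.standard_normal(x.size) * np.sqrt(mass)
    h0 = lp - _kinetic(p0, inv_mass)
    x_minus = x_plus = x
    p_minus = p_plus = p0
    g_minus = g_plus = g
    x_new, lp_new, g_new = x, lp, g
    logw_total = 0.0  # weight of the initial point relative to exp(h0)
    sum_accept, n_accept, n_div = 0.0, 0, 0
    depth = 0
    while depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            t = _build_tree(x_plus, p_plus, g_plus, 1, depth, eps, h0, logp_grad, inv_mass, rng)
            x_plus, p_plus, g_plus = t.x_plus, t.p_plus, t.g_plus
        else:
            t = _build_tree(x_minus, p_minus, g_minus, -1, depth, eps, h0, logp_grad, inv_mass, rng)
            x_minus, p_minus, g_minus = t.x_minus, t.p_minus, t.g_minus
        sum_accept += t.sum_accept
        n_accept += t.n_accept
        if t.n_div:
            n_div += 1
            break
        if t.stop:
            break
        total = np.logaddexp(logw_total, t.logw)
        if np.log(rng.random()) < t.logw - total:
            x_new = t.x_prop
            lp_new, g_new = logp_grad(x_new)
        logw_total = total
        if _uturn(x_plus, x_minus, p_plus, p_minus, inv_mass):
            break
        depth += 1
    accept_stat = sum_accept / max(n_accept, 1)
    return x_new, lp_new, g_new, accept_stat, depth, n_div


def nuts_sample(
    logp_grad,
    x0,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
):
    """Run one NUTS chain; returns (draws, NUTSStats).

    ``logp_grad(x) -> (logp, grad)`` must be finite at ``x0``.
    """
    x = np.asarray(x0, dtype=float).copy()
    lp, g = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")
    dim = x.size
    inv_mass = np.ones(dim)
    mass = np.ones(dim)

    # initial step size: aim for ~50% acceptance of a single leapfrog step
    eps = 0.1
    for _ in range(50):
        p0 = rng.standard_normal(dim)
        _, p1, _, lp1 = _leapfrog(x, p0, g, eps, logp_grad, inv_mass)
        dh = (lp1 - _kinetic(p1, inv_mass)) - (lp - _kinetic(p0, inv_mass))
        if not np.isfinite(dh) or dh < np.log(0.5):
            eps *= 0.5
        elif dh > np.log(0.95):
            eps *= 2.0
        else:
            break

    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # expanding slow windows for diagonal mass estimation (Stan-style):
    # an initial fast interval, doubling covariance windows, a final fast
    # interval for step-size only
    init_fast = min(max(int(0.15 * n_warmup), 10), n_warmup)
    term_fast = min(max(int(0.1 * n_warmup), 10), n_warmup)
    slow_total = max(n_warmup - init_fast - term_fast, 0)
    window_ends = []
    wsize = 25
    pos = init_fast
    while slow_total > 0 and pos + wsize <= init_fast + slow_total:
        # last window absorbs the remainder
        if pos + 3 * wsize > init_fast + slow_total:
            wsize = init_fast + slow_total - pos
        window_ends.append(pos + wsize)
        pos += wsize
        wsize *= 2
    window: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    accepts = []
    depths = np.zeros(n_warmup + n_draws, dtype=int)
    divergences = 0
    da_iter = 0

    for it in range(n_warmup + n_draws):
        x, lp, g, a_stat, depth, n_div = _nuts_step(
            x, lp, g, eps, logp_grad, inv_mass, mass, rng, max_treedepth
        )
        depths[it] = depth
        if it >= n_warmup:  # warmup divergences reflect step-size search
            divergences += n_div
        if it < n_warmup:
            da_iter += 1
            h_bar = (1.0 - 1.0 / (da_iter + t0)) * h_bar + (
                target_accept - a_stat
            ) / (da_iter + t0)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            in_slow = init_fast <= it < n_warmup - term_fast
            if in_slow:
                window.append(x.copy())
            if window_ends and it == window_ends[0] - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0, ddof=1)
                n = len(window)
                var = var * (n / (n + 5.0)) + 1e-3 * (5.0 / (n + 5.0))
                inv_mass = var
                mass = 1.0 / var
                # restart step-size adaptation around the current value
                mu = np.log(10.0 * eps)
                h_bar, log_eps_bar, da_iter = 0.0, 0.0, 0
                window = []
                window_ends.pop(0)
        else:
            if it == n_warmup:
                eps = float(np.exp(log_eps_bar)) if n_warmup > 0 else eps
            draws[it - n_warmup] = x
            accepts.append(a_stat)

    stats = NUTSStats(
        step_size=eps,
        inv_mass=inv_mass,
        accept_rate=float(np.mean(accepts)) if accepts else np.nan,
        divergences=divergences,
        treedepths=depths,
    )
    return draws, stats
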