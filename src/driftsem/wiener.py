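"""Two-boundary Wiener first-passage-time density, choice probabilities and
trial simulation.

This is the measurement model of the package: a drift-diffusion process with
drift ``v``, boundary separation ``a``, non-decision time ``t0`` and relative
start point ``w`` (fixed at 1/2 throughout the package: accuracy coding with
an unbiased start).  The diffusion coefficient is fixed at 1, which sets the
scale of ``v`` and ``a``.

Under accuracy coding the upper boundary collects correct responses and the
lower boundary errors.  The density of an absorption at the *lower* boundary
at decision time ``t - t0`` is evaluated with the classical pair of series
expansions (a small-time and a large-time representation of the same
density); whichever series needs fewer terms at the target precision is
used per evaluation point.  The upper-boundary density follows from the
reflection identity ``f_upper(t; v, w) = f_lower(t; -v, 1-w)``.

All entry points are vectorised over trials and, where noted, return the
analytic gradients with respect to ``(v, a, t0)`` that the hierarchical
sampler requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiffusionParams",
    "wiener_logpdf",
    "wiener_logpdf_grad",
    "wiener_prob_correct",
    "wiener_sample",
]

# target absolute precision of the dimensionless density f(tau, w)
_EPS = 1e-7
_TINY = 1e-300


def _make_grad_kernel():
    """Compile the elementwise log-density + gradient kernel (w = 1/2)."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is normally present
        return None

    eps = _EPS

    @njit(cache=True, fastmath=False)
    def kernel(t, correct, v, a, t0):
        n = t.shape[0]
        lp = np.empty(n)
        gv = np.zeros(n)
        ga = np.zeros(n)
        gt0 = np.zeros(n)
        w = 0.5
        sqrt2pi = np.sqrt(2.0 * np.pi)
        for i in range(n):
            ai = a[i]
            t0i = t0[i]
            if not (np.isfinite(v[i]) and np.isfinite(ai) and np.isfinite(t0i)) \
                    or ai <= 0.0 or t[i] <= t0i or t0i < 0.0:
                lp[i] = -np.inf
                continue
            sign = -1.0 if correct[i] != 0 else 1.0
            veff = sign * v[i]
            td = t[i] - t0i
            tau = td / (ai * ai)
            # choose series by required number of terms
            arg_s = 2.0 * eps * np.sqrt(2.0 * np.pi * tau)
            if arg_s < 1.0:
                ks = 2.0 + np.sqrt(-2.0 * tau * np.log(arg_s))
                if ks < np.sqrt(tau) + 1.0:
                    ks = np.sqrt(tau) + 1.0
            else:
                ks = 2.0
            arg_l = np.pi * tau * eps
            if arg_l < 1.0:
                kl = np.sqrt(-2.0 * np.log(arg_l) / (np.pi * np.pi * tau))
                m = 1.0 / (np.pi * np.sqrt(tau))
                if kl < m:
                    kl = m
            else:
                kl = 1.0 / (np.pi * np.sqrt(tau))
            if ks < kl:
                K = int(np.ceil(ks))
                s0 = 0.0
                s1 = 0.0
                for k in range(-K, K + 1):
                    c = w + 2.0 * k
                    e = np.exp(-c * c / (2.0 * tau))
                    s0 += c * e
                    s1 += c * c * c * e
                pref = 1.0 / (sqrt2pi * tau * np.sqrt(tau))
                f = pref * s0
                dfdtau = pref * (-1.5 / tau * s0 + s1 / (2.0 * tau * tau))
            else:
                K = int(np.ceil(kl))
                s0 = 0.0
                s1 = 0.0
                for k in range(1, K + 1):
                    lam = k * k * np.pi * np.pi / 2.0
                    b = k * np.sin(k * np.pi * w) * np.exp(-lam * tau)
                    s0 += b
                    s1 -= lam * b
                f = np.pi * s0
                dfdtau = np.pi * s1
            if not (f > 0.0):
                lp[i] = -np.inf
                continue
            lp[i] = (
                -2.0 * np.log(ai)
                - veff * ai * w
                - veff * veff * td / 2.0
                + np.log(f)
            )
            r = dfdtau / f
            dveff = -ai * w - veff * td
            dtd = -veff * veff / 2.0 + r / (ai * ai)
            gv[i] = sign * dveff
            ga[i] = -2.0 / ai - veff * w + r * (-2.0 * td / (ai * ai * ai))
            gt0[i] = -dtd
        return lp, gv, ga, gt0

    return kernel


_grad_kernel = _make_grad_kernel()


@dataclass(frozen=True)
class DiffusionParams:
    """Wiener parameters for one subject/condition cell.

    v : drift rate (evidence units per second, unbounded)
    a : boundary separation (> 0)
    t0 : non-decision time in seconds (>= 0)
    w : relative start point, fixed at 0.5 (accuracy coding)
    """

    v: float
    a: float
    t0: float = 0.0
    w: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.v):
            raise ValueError("drift rate v must be finite")
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError("boundary separation a must be positive")
        if not (np.isfinite(self.t0) and self.t0 >= 0):
            raise ValueError("non-decision time t0 must be >= 0")
        if self.w != 0.5:
            raise ValueError("relative start point w is fixed at 0.5")


def _nterms_small(tau: np.ndarray, eps: float) -> np.ndarray:
    """Terms needed by the small-time series (per element)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 2.0 * eps * np.sqrt(2.0 * np.pi * tau)
        ks = 2.0 + np.sqrt(np.maximum(-2.0 * tau * np.log(np.maximum(arg, _TINY)), 0.0))
        ks = np.where(arg < 1.0, np.maximum(ks, np.sqrt(tau) + 1.0), 2.0)
    return ks


def _nterms_large(tau: np.ndarray, eps: float) -> np.ndarray:
    """Terms needed by the large-time series (per element)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = np.pi * tau * eps
        kl = np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg, _TINY)), 0.0) / (np.pi ** 2 * tau))
        kl = np.where(arg < 1.0, np.maximum(kl, 1.0 / (np.pi * np.sqrt(tau))), 1.0 / (np.pi * np.sqrt(tau)))
    return kl


def _f_tau(tau: np.ndarray, w: float, need_grad: bool) -> tuple[np.ndarray, np.ndarray | None]:
    """Dimensionless lower-boundary density f(tau, w) and (optionally) df/dtau.

    ``tau`` is decision time rescaled by a**2; entries must be > 0.
    """
    tau = np.asarray(tau, dtype=float)
    f = np.zeros_like(tau)
    df = np.zeros_like(tau) if need_grad else None

    ks = _nterms_small(tau, _EPS)
    kl = _nterms_large(tau, _EPS)
    small = ks < kl

    if np.any(small):
        ts = tau[small]
        K = int(np.ceil(np.max(ks[small])))
        # series over k = -K..K in terms c_k = w + 2k
        kk = np.arange(-K, K + 1)
        c = w + 2.0 * kk[:, None]  # (terms, n)
        e = np.exp(-c * c / (2.0 * ts[None, :]))
        terms = c * e
        pref = 1.0 / np.sqrt(2.0 * np.pi * ts ** 3)
        s0 = terms.sum(axis=0)
        f[small] = pref * s0
        if need_grad:
            s1 = (terms * (c * c)).sum(axis=0)
            # d/dtau [pref * s0] = pref * (-3/(2 tau) * s0 + s1 / (2 tau^2))
            df[small] = pref * (-1.5 / ts * s0 + s1 / (2.0 * ts ** 2))

    large = ~small
    if np.any(large):
        tl = tau[large]
        K = int(np.ceil(np.max(kl[large])))
        kk = np.arange(1, K + 1)[:, None].astype(float)
        sin = np.sin(kk * np.pi * w)
        lam = kk ** 2 * np.pi ** 2 / 2.0
        terms = kk * sin * np.exp(-lam * tl[None, :])
        f[large] = np.pi * terms.sum(axis=0)
        if need_grad:
            df[large] = np.pi * (-(lam * terms)).sum(axis=0)

    return f, df


def _broadcast(t, correct, v, a, t0):
    t = np.asarray(t, dtype=float)
    correct = np.asarray(correct)
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    shape = np.broadcast_shapes(t.shape, correct.shape, v.shape, a.shape, t0.shape)
    return (np.broadcast_to(x, shape).astype(float, copy=True) for x in (t, correct, v, a, t0))


def wiener_logpdf(t, correct, v, a, t0, w: float = 0.5):
    """Log-density of a response ``(t, correct)`` under the Wiener model.

    Returns ``-inf`` for ``t <= t0`` or nonpositive boundary separation so
    that samplers exploring an unconstrained parameter space can traverse
    invalid regions without raising.  Non-finite *data* are rejected.
    """
    lp, _ = _logpdf_impl(t, correct, v, a, t0, w, need_grad=False)
    return lp


def wiener_logpdf_grad(t, correct, v, a, t0, w: float = 0.5):
    """Log-density and its gradients d/dv, d/da, d/dt0 (elementwise).

    Dispatches to a compiled kernel for array input when numba is
    available; the pure-numpy path is kept as the reference implementation.
    """
    if _grad_kernel is not None and w == 0.5:
        t_a = np.asarray(t, dtype=float)
        if t_a.ndim == 1:
            c_a = np.ascontiguousarray(np.asarray(correct), dtype=np.int64)
            v_a, a_a, t0_a = (
                np.ascontiguousarray(np.broadcast_to(np.asarray(x, float), t_a.shape))
                for x in (v, a, t0)
            )
            if not (np.all(np.isfinite(t_a)) and np.all(t_a > 0)):
                raise ValueError("response times must be finite and positive")
            lp, gv, ga, gt0 = _grad_kernel(
                np.ascontiguousarray(t_a), c_a, v_a, a_a, t0_a
            )
            return lp, np.stack([gv, ga, gt0])
    return _logpdf_impl(t, correct, v, a, t0, w, need_grad=True)


def _logpdf_impl(t, correct, v, a, t0, w, need_grad):
    if w != 0.5:
        raise ValueError("relative start point w is fixed at 0.5")
    t, correct, v, a, t0 = _broadcast(t, correct, v, a, t0)
    scalar = t.ndim == 0
    if scalar:
        t, correct, v, a, t0 = (np.atleast_1d(x) for x in (t, correct, v, a, t0))
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(correct)):
        raise ValueError("response times and accuracies must be finite")
    if np.any(t <= 0):
        raise ValueError("response times must be positive")

    lp = np.full(t.shape, -np.inf)
    grads = np.zeros((3,) + t.shape) if need_grad else None

    finite_par = np.isfinite(v) & np.isfinite(a) & np.isfinite(t0)
    ok = finite_par & (a > 0) & (t > t0) & (t0 >= 0)
    if not np.any(ok):
        if scalar:
            lp = lp[0]
            grads = None if grads is None else grads[:, 0]
        return (lp, grads) if need_grad else (lp, None)

    tt, cc, vv, aa, tz = (x[ok] for x in (t, correct, v, a, t0))
    # reflection: a correct response is a lower-boundary absorption at -v
    sign = np.where(cc.astype(bool), -1.0, 1.0)
    veff = sign * vv
    td = tt - tz
    tau = td / (aa * aa)

    f, dfdtau = _f_tau(tau, w, need_grad)
    pos = f > 0
    logf = np.where(pos, np.log(np.maximum(f, _TINY)), -np.inf)
    lp_ok = -2.0 * np.log(aa) - veff * aa * w - veff ** 2 * td / 2.0 + logf
    out = np.full(tt.shape, -np.inf)
    out[pos] = lp_ok[pos]
    lp[ok] = out

    if need_grad:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(pos, dfdtau / np.maximum(f, _TINY), 0.0)
        dveff = -aa * w - veff * td
        dtd = -(veff ** 2) / 2.0 + r / (aa * aa)
        da = -2.0 / aa - veff * w + r * (-2.0 * td / aa ** 3)
        gv = np.where(pos, sign * dveff, 0.0)
        ga = np.where(pos, da, 0.0)
        gt0 = np.where(pos, -dtd, 0.0)
        grads[0][ok] = gv
        grads[1][ok] = ga
        grads[2][ok] = gt0
    if scalar:
        lp = lp[0]
        grads = None if grads is None else grads[:, 0]
    return lp, grads


def wiener_prob_correct(v, a, w: float = 0.5):
    """Probability of absorption at the correct (upper) boundary.

    Closed form ``(1 - exp(-2 v a w)) / (1 - exp(-2 v a))``; equals ``w`` at
    zero drift and ``1/(1 + exp(-v a))`` for the unbiased start used here.
    """
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise ValueError("boundary separation a must be positive")
    if w != 0.5:
        raise ValueError("relative start point w is fixed at 0.5")
    # numerically stable logistic form for w = 1/2
    out = 1.0 / (1.0 + np.exp(-v * a))
    if out.ndim == 0:
        return float(out)
    return out


def _fpt_grid(v: float, a: float, n: int = 4096) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decision-time grid and both boundary densities, for inverse-CDF sampling."""
    # slowest decay rate of the large-time series sets the upper tail
    lam = v * v / 2.0 + np.pi ** 2 / (2.0 * a * a)
    t_max = max(np.log(1e14) / lam, 0.2 * a * a)
    td = np.geomspace(1e-6 * a * a + 1e-9, t_max, n)
    tau = td / (a * a)
    f_err, _ = _f_tau(tau, 0.5, False)  # lower boundary at drift v
    f_low = (1.0 / a ** 2) * np.exp(-v * a * 0.5 - v ** 2 * td / 2.0) * f_err
    f_cor_tau, _ = _f_tau(tau, 0.5, False)
    f_up = (1.0 / a ** 2) * np.exp(v * a * 0.5 - v ** 2 * td / 2.0) * f_cor_tau
    return td, np.maximum(f_up, 0.0), np.maximum(f_low, 0.0)


def wiener_sample(params: DiffusionParams, n: int, seed=None):
    """Draw ``n`` i.i.d. trials ``(rt, correct)``; reproducible given ``seed``.

    Choices are drawn from the closed-form absorption probability; decision
    times from the numerically inverted conditional first-passage-time CDF on
    a dense log-spaced grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = params if isinstance(params, DiffusionParams) else DiffusionParams(*params)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    td_grid, f_up, f_low = _fpt_grid(p.v, p.a)
    correct = rng.random(n) < wiener_prob_correct(p.v, p.a)
    rt = np.empty(n)
    for flag, dens in ((True, f_up), (False, f_low)):
        m = correct == flag
        k = int(m.sum())
        if k == 0:
            continue
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(td_grid))])
        total = cdf[-1]
        if total <= 0:
            # vanishing mass at this boundary: fall back to the other one
            rt[m] = p.t0 + td_grid[0]
            continue
        u = rng.random(k) * total
        rt[m] = p.t0 + np.interp(u, cdf, td_grid)
    return rt, correct.astype(int)
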