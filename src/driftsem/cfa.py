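"""Maximum-likelihood confirmatory factor analysis on covariance matrices.

The module fits single-factor and bifactor measurement models to a sample
covariance (or correlation) matrix by minimising the normal-theory ML
discrepancy

    F_ML = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - p,

with chi-square = (N - 1) * F_ML.  Factors are orthogonal with unit
variance; loadings, error variances and declared error covariances are free.
Error variances are left unconstrained so that improper ("Heywood")
solutions are detected and surfaced as warnings rather than hidden, and
loadings can optionally be bounded at zero (the positivity constraint used
for bifactor attentional-control models).

Also provided: fit indices (CFI, RMSEA with 90% CI, SRMR), the
Kaiser-Meyer-Olkin factorability index, composite-reliability coefficients
(omega, hierarchical omega) and the good/acceptable/bad fit classification
used to summarise fits across posterior draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SEMModelSpec",
    "CFAModel",
    "CFAResults",
    "fit_ml",
    "fit_indices",
    "kmo",
    "omega_single",
    "omega_hierarchical",
    "classify_fit",
]

_GTOL = 1e-7
_FTOL = 1e-12


@dataclass(frozen=True)
class SEMModelSpec:
    """Structure of a CFA model.

    factors maps each factor name to the indicators it loads on.  All factors
    are mutually orthogonal with variance fixed at 1.  ``correlated_errors``
    lists indicator pairs whose error terms covary (e.g. the congruent and
    incongruent measures of the same task).  ``nonnegative`` constrains all
    loadings to be >= 0 when True, or only the named factors' loadings when a
    set of factor names is given.
    """

    indicators: tuple[str, ...]
    factors: dict[str, tuple[str, ...]]
    correlated_errors: tuple[tuple[str, str], ...] = ()
    nonnegative: bool | frozenset[str] = False

    def __post_init__(self):
        object.__setattr__(self, "indicators", tuple(self.indicators))
        object.__setattr__(
            self, "factors", {k: tuple(v) for k, v in self.factors.items()}
        )
        object.__setattr__(
            self,
            "correlated_errors",
            tuple((a, b) for a, b in self.correlated_errors),
        )
        idx = set(self.indicators)
        for f, inds in self.factors.items():
            missing = set(inds) - idx
            if missing:
                raise ValueError(f"factor {f!r} references unknown indicators {missing}")
        loaded = set().union(*self.factors.values()) if self.factors else set()
        if idx - loaded:
            raise ValueError(f"indicators load on no factor: {idx - loaded}")
        for a, b in self.correlated_errors:
            if a not in idx or b not in idx or a == b:
                raise ValueError(f"bad correlated-error pair ({a}, {b})")

    @classmethod
    def single_factor(cls, indicators, factor: str = "g", nonnegative: bool = False):
        inds = tuple(indicators)
        return cls(inds, {factor: inds}, nonnegative=nonnegative)

    @classmethod
    def bifactor(
        cls,
        indicators,
        specific,
        correlated_errors=(),
        general: str = "g",
        specific_name: str = "s",
        nonnegative=True,
    ):
        """General factor on all indicators plus one orthogonal specific
        factor on the high-control subset; loadings nonnegative by default."""
        inds = tuple(indicators)
        return cls(
            inds,
            {general: inds, specific_name: tuple(specific)},
            correlated_errors=tuple(correlated_errors),
            nonnegative=nonnegative,
        )

    @property
    def n_free(self) -> int:
        return (
            sum(len(v) for v in self.factors.values())
            + len(self.indicators)
            + len(self.correlated_errors)
        )

    def degrees_of_freedom(self) -> int:
        p = len(self.indicators)
        return p * (p + 1) // 2 - self.n_free


def _as_matrix(S, indicators=None):
    if isinstance(S, pd.DataFrame):
        if indicators is not None:
            S = S.loc[list(indicators), list(indicators)]
        names = tuple(S.index)
        return np.asarray(S, dtype=float), names
    S = np.asarray(S, dtype=float)
    names = tuple(indicators) if indicators is not None else tuple(
        f"x{i + 1}" for i in range(S.shape[0])
    )
    return S, names


class CFAModel:
    """Confirmatory factor model for a sample covariance/correlation matrix.

    Parameters
    ----------
    spec : SEMModelSpec
    S : (p, p) array or DataFrame
        Sample covariance or correlation matrix; must be symmetric positive
        definite.  A DataFrame is aligned to ``spec.indicators``.
    n_obs : int
        Sample size N used for the chi-square multiplier (N - 1).
    """

    def __init__(self, spec: SEMModelSpec, S, n_obs: int):
        self.spec = spec
        S, names = _as_matrix(S, spec.indicators)
        p = len(spec.indicators)
        if S.shape != (p, p):
            raise ValueError(f"S has shape {S.shape}, spec declares {p} indicators")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        S = 0.5 * (S + S.T)
        ev = np.linalg.eigvalsh(S)
        if ev[0] <= 0:
            raise ValueError(
                f"S is not positive definite (smallest eigenvalue {ev[0]:.3e})"
            )
        if n_obs < 2:
            raise ValueError("n_obs must be >= 2")
        self.S = S
        self.n_obs = int(n_obs)
        self._logdet_S = float(np.linalg.slogdet(S)[1])
        self._iname = {n: i for i, n in enumerate(spec.indicators)}
        # loading slots: (factor order, indicator order within factor)
        self._slots = [
            (f, self._iname[ind]) for f in spec.factors for ind in spec.factors[f]
        ]
        self._fnames = list(spec.factors)
        self._pairs = [
            (self._iname[a], self._iname[b]) for a, b in spec.correlated_errors
        ]

    # -- parameter vector layout: [loadings..., error variances..., error covs...]
    def _unpack(self, x):
        p = len(self.spec.indicators)
        nl = len(self._slots)
        Lam = np.zeros((p, len(self._fnames)))
        fcol = {f: j for j, f in enumerate(self._fnames)}
        for k, (f, i) in enumerate(self._slots):
            Lam[i, fcol[f]] = x[k]
        Theta = np.diag(x[nl : nl + p].copy())
        for k, (i, j) in enumerate(self._pairs):
            Theta[i, j] = Theta[j, i] = x[nl + p + k]
        return Lam, Theta

    def implied_cov(self, x):
        Lam, Theta = self._unpack(x)
        return Lam @ Lam.T + Theta

    def discrepancy(self, x):
        """F_ML at parameter vector x (large when Sigma is not PD)."""
        f, _ = self._fml_and_grad(x, need_grad=False)
        return f

    def _fml_and_grad(self, x, need_grad=True):
        p = len(self.spec.indicators)
        Sigma = self.implied_cov(x)
        try:
            c = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e10 + float(np.sum(x * x)), (x * 2.0 if need_grad else None)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        Sinv = np.linalg.inv(Sigma)
        f = logdet + float(np.trace(self.S @ Sinv)) - self._logdet_S - p
        if not need_grad:
            return f, None
        G = Sinv @ (Sigma - self.S) @ Sinv  # dF/dSigma (symmetric)
        Lam, _ = self._unpack(x)
        dLam = 2.0 * G @ Lam
        fcol = {fn: j for j, fn in enumerate(self._fnames)}
        g = np.empty_like(x)
        for k, (fn, i) in enumerate(self._slots):
            g[k] = dLam[i, fcol[fn]]
        nl = len(self._slots)
        g[nl : nl + p] = np.diag(G)
        for k, (i, j) in enumerate(self._pairs):
            g[nl + p + k] = 2.0 * G[i, j]
        return f, g

    def start_values(self):
        """Deterministic starting values: first principal component of S
        scaled by 0.7 for each factor (restricted to its indicators), error
        variances at half the observed variances, zero error covariances."""
        S = self.S
        sd = np.sqrt(np.diag(S))
        x0 = np.empty(self.spec.n_free)
        pos = 0
        for fn in self._fnames:
            idx = [self._iname[i] for i in self.spec.factors[fn]]
            sub = S[np.ix_(idx, idx)]
            w, V = np.linalg.eigh(sub)
            pc = V[:, -1] * np.sqrt(max(w[-1], 1e-8))
            if pc.sum() < 0:
                pc = -pc
            scale = 0.7 if fn == self._fnames[0] else 0.35
            x0[pos : pos + len(idx)] = scale * pc
            pos += len(idx)
        p = len(self.spec.indicators)
        x0[pos : pos + p] = 0.5 * np.diag(S)
        x0[pos + p :] = 0.0
        return x0

    def _bounds(self):
        nn = self.spec.nonnegative
        if nn is False or (isinstance(nn, frozenset) and not nn):
            return None
        bounded_factors = (
            set(self._fnames) if nn is True else set(nn)
        )
        lb = np.full(self.spec.n_free, -np.inf)
        ub = np.full(self.spec.n_free, np.inf)
        for k, (fn, _) in enumerate(self._slots):
            if fn in bounded_factors:
                lb[k] = 0.0
        return optimize.Bounds(lb, ub)

    def fit(self, start=None, maxiter: int = 2000) -> "CFAResults":
        x0 = self.start_values() if start is None else np.asarray(start, float)
        res = optimize.minimize(
            self._fml_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=self._bounds(),
            options={"maxiter": maxiter, "ftol": _FTOL, "gtol": _GTOL, "maxls": 60},
        )
        fml = max(float(res.fun), 0.0)
        grad_norm = float(np.max(np.abs(res.jac)))
        # L-BFGS-B reports success on ftol; also accept a tiny projected grad
        converged = bool(res.success or grad_norm < 1e-5) and fml < 1e9
        status = "converged"
        messages: list[str] = []
        if not converged:
            status = "nonconverged"
            messages.append(f"optimizer: {res.message}")
        else:
            Lam, Theta = self._unpack(res.x)
            if np.any(np.diag(Theta) < -1e-8):
                status = "converged_with_warnings"
                messages.append("negative error variance estimate")
            if self.spec.degrees_of_freedom() > 0:
                info = self._information(res.x)
                evals = np.linalg.eigvalsh(0.5 * (info + info.T))
                if evals[0] < 1e-8 * max(evals[-1], 1.0):
                    status = "converged_with_warnings"
                    messages.append("information matrix (near-)singular; standard errors unavailable")
        return CFAResults(self, res.x, fml, status, tuple(messages))

    def _information(self, x, h=1e-5):
        """Numerical Hessian of F_ML (finite differences of the analytic
        gradient); singularity signals an unidentified solution."""
        n = x.size
        H = np.empty((n, n))
        for k in range(n):
            xp = x.copy()
            xp[k] += h
            _, gp = self._fml_and_grad(xp)
            xm = x.copy()
            xm[k] -= h
            _, gm = self._fml_and_grad(xm)
            H[:, k] = (gp - gm) / (2 * h)
        return H


@dataclass
class CFAResults:
    """Fitted CFA: estimates, fit statistics and reliability coefficients."""

    model: CFAModel
    params: np.ndarray
    fml: float
    status: str  # converged | converged_with_warnings | nonconverged
    messages: tuple[str, ...] = ()
    _indices: dict = field(default=None, repr=False)

    # -- estimates ---------------------------------------------------------
    @property
    def loadings(self) -> pd.DataFrame:
        Lam, _ = self.model._unpack(self.params)
        return pd.DataFrame(
            Lam, index=self.model.spec.indicators, columns=self.model._fnames
        )

    @property
    def error_cov(self) -> pd.DataFrame:
        _, Theta = self.model._unpack(self.params)
        names = self.model.spec.indicators
        return pd.DataFrame(Theta, index=names, columns=names)

    @property
    def implied(self) -> np.ndarray:
        return self.model.implied_cov(self.params)

    def standardized(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Loadings and error (co)variances rescaled to unit implied
        variances (the completely standardized solution)."""
        d = 1.0 / np.sqrt(np.diag(self.implied))
        lam = self.loadings * d[:, None]
        theta = self.error_cov * np.outer(d, d)
        return lam, theta

    # -- fit statistics ----------------------------------------------------
    @property
    def df(self) -> int:
        return self.model.spec.degrees_of_freedom()

    @property
    def chi2(self) -> float:
        return (self.model.n_obs - 1) * self.fml

    @property
    def pvalue(self) -> float:
        if self.df <= 0:
            return 1.0
        return float(stats.chi2.sf(self.chi2, self.df))

    def fit_indices(self) -> dict:
        if self._indices is None:
            self._indices = fit_indices(self, self.model.S, self.model.n_obs)
        return self._indices

    def classify(self) -> str:
        return classify_fit(self, self.fit_indices(), self.model.n_obs)

    # -- reliability -------------------------------------------------------
    def omega(self) -> float:
        return omega_single(self)

    def omega_hierarchical(self, factor: str) -> float:
        return omega_hierarchical(self, factor)

    def summary(self) -> str:
        idx = self.fit_indices()
        lam, theta = self.standardized()
        lines = [
            "Confirmatory factor analysis (normal-theory ML)",
            "=" * 48,
            f"indicators: {len(self.model.spec.indicators)}   "
            f"N = {self.model.n_obs}   status: {self.status}",
            f"chi2({self.df}) = {self.chi2:.2f}, p = {self.pvalue:.3f}",
            f"CFI = {idx['cfi']:.3f}   SRMR = {idx['srmr']:.3f}   "
            f"RMSEA = {idx['rmsea']:.3f} "
            f"[{idx['rmsea_ci'][0]:.3f}, {idx['rmsea_ci'][1]:.3f}]",
            "",
            "Standardized loadings:",
            lam.round(3).to_string(),
            "",
            "Standardized error variances:",
            pd.Series(np.diag(theta), index=self.model.spec.indicators)
            .round(3)
            .to_string(),
        ]
        if self.messages:
            lines += ["", "warnings: " + "; ".join(self.messages)]
        return "\n".join(lines)


def fit_ml(spec: SEMModelSpec, S, n_obs: int) -> CFAResults:
    """Fit ``spec`` to the sample matrix ``S`` with sample size ``n_obs``."""
    return CFAModel(spec, S, n_obs).fit()


def _baseline_chi2(S, n_obs):
    """Independence (diagonal) baseline model."""
    p = S.shape[0]
    fb = float(np.sum(np.log(np.diag(S))) - np.linalg.slogdet(S)[1])
    return (n_obs - 1) * fb, p * (p - 1) // 2


def _rmsea_ci(chi2, df, n_obs, level=0.90):
    """90% CI by inverting the noncentral chi-square at the tail
    probabilities; lower bound floored at zero."""
    if df <= 0:
        return (0.0, 0.0)
    lo_p, hi_p = (1 + level) / 2, (1 - level) / 2  # 0.95, 0.05
    nm1 = n_obs - 1

    def bound(prob):
        # find lambda with ncx2.cdf(chi2, df, lambda) == prob
        if stats.ncx2.cdf(chi2, df, 1e-10) < prob:
            return 0.0
        hi = max(chi2, 1.0)
        while stats.ncx2.cdf(chi2, df, hi) > prob:
            hi *= 2
            if hi > 1e8:
                break
        lam = optimize.brentq(
            lambda l: stats.ncx2.cdf(chi2, df, l) - prob, 1e-10, hi, xtol=1e-8
        )
        return np.sqrt(lam / (df * nm1))

    return (float(bound(lo_p)), float(bound(hi_p)))


def fit_indices(fit: CFAResults, S=None, n_obs=None) -> dict:
    """CFI, RMSEA (with 90% CI), SRMR and the chi-square pair."""
    if fit.status == "nonconverged":
        raise ValueError("fit indices undefined for a nonconverged model")
    S = fit.model.S if S is None else np.asarray(S, float)
    n_obs = fit.model.n_obs if n_obs is None else int(n_obs)
    chi2, df = fit.chi2, fit.df
    out = {"chi2": chi2, "df": df, "pvalue": fit.pvalue}
    if df == 0:
        out.update(cfi=1.0, rmsea=0.0, rmsea_ci=(0.0, 0.0), srmr=_srmr(S, fit.implied), saturated=True)
        return out
    chi2_b, df_b = _baseline_chi2(S, n_obs)
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    out["cfi"] = 1.0 if den == 0 else 1.0 - num / den
    out["rmsea"] = float(np.sqrt(num / (df * (n_obs - 1))))
    out["rmsea_ci"] = _rmsea_ci(chi2, df, n_obs)
    out["srmr"] = _srmr(S, fit.implied)
    out["saturated"] = False
    return out


def _srmr(S, Sigma):
    """Root mean square residual of the correlation-metric matrices over all
    unique elements including the diagonal (each matrix standardized by its
    own variances, so diagonal residuals vanish for correlation input)."""
    ds = 1.0 / np.sqrt(np.diag(S))
    dm = 1.0 / np.sqrt(np.diag(Sigma))
    R = S * np.outer(ds, ds)
    Rhat = Sigma * np.outer(dm, dm)
    p = S.shape[0]
    iu = np.triu_indices(p)
    resid = (R - Rhat)[iu]
    return float(np.sqrt(np.mean(resid ** 2)))


def kmo(R) -> float:
    """Kaiser-Meyer-Olkin factorability index of a correlation matrix.

    Uses the anti-image correlations q_ij = -r^ij / sqrt(r^ii r^jj) from the
    inverse of R:  KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j.
    """
    R, _ = _as_matrix(R)
    if not np.allclose(R, R.T, atol=1e-10) or not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must be a symmetric correlation matrix")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise ValueError("R is singular; KMO undefined") from err
    d = 1.0 / np.sqrt(np.diag(Rinv))
    Q = -Rinv * np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = float(np.sum(R[off] ** 2))
    q2 = float(np.sum(Q[off] ** 2))
    if r2 < 1e-10:
        warnings.warn("correlations are essentially zero; KMO is uninformative")
    return r2 / (r2 + q2)


def omega_single(fit: CFAResults) -> float:
    """McDonald's omega of a single-factor model from the standardized
    solution: (sum lambda)^2 / ((sum lambda)^2 + sum theta)."""
    if len(fit.model._fnames) != 1:
        raise ValueError("omega_single requires a single-factor model")
    if fit.status == "nonconverged":
        raise ValueError("omega undefined for a nonconverged model")
    lam, theta = fit.standardized()
    s = float(lam.iloc[:, 0].sum())
    th = float(np.sum(np.diag(theta))) + 2.0 * sum(
        theta.loc[a, b] for a, b in fit.model.spec.correlated_errors
    )
    return s * s / (s * s + th)


def omega_hierarchical(fit: CFAResults, factor: str) -> float:
    """Hierarchical omega of a specific factor in a bifactor model.

    The composite is the sum of the specific factor's own indicators; its
    variance aggregates general loadings, specific loadings, error variances
    and declared error covariances among those indicators (standardized
    solution).
    """
    if factor not in fit.model._fnames:
        raise ValueError(f"unknown factor {factor!r}")
    if fit.status == "nonconverged":
        raise ValueError("omega undefined for a nonconverged model")
    lam, theta = fit.standardized()
    members = list(fit.model.spec.factors[factor])
    spec_sum = float(lam.loc[members, factor].sum())
    total = 0.0
    for fn in fit.model._fnames:
        total += float(lam.loc[members, fn].sum()) ** 2
    total += float(np.sum(np.diag(theta.loc[members, members])))
    for a, b in fit.model.spec.correlated_errors:
        if a in members and b in members:
            total += 2.0 * float(theta.loc[a, b])
    return spec_sum ** 2 / total


def classify_fit(fit: CFAResults, indices: dict | None = None, n_obs: int | None = None) -> str:
    """Label a fit good / acceptable / bad / warnings / nonconverged.

    For N <= 250: good = CFI > .95 & SRMR < .08; acceptable = CFI in
    [.90, .95] & SRMR < .08.  For N > 250 the RMSEA joins the rule: good
    additionally needs RMSEA < .06, acceptable RMSEA in [.06, .08] with
    CFI > .90.
    """
    if fit.status == "nonconverged":
        return "nonconverged"
    if fit.status == "converged_with_warnings":
        return "warnings"
    indices = fit.fit_indices() if indices is None else indices
    n_obs = fit.model.n_obs if n_obs is None else n_obs
    cfi, srmr, rmsea = indices["cfi"], indices["srmr"], indices["rmsea"]
    if n_obs <= 250:
        if cfi > 0.95 and srmr < 0.08:
            return "good"
        if 0.90 <= cfi <= 0.95 and srmr < 0.08:
            return "acceptable"
        return "bad"
    if cfi > 0.95 and srmr < 0.08 and rmsea < 0.06:
        return "good"
    if cfi > 0.90 and srmr < 0.08 and 0.06 <= rmsea <= 0.08:
        return "acceptable"
    return "bad"
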