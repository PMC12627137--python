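"""Hierarchical Bayesian Wiener diffusion model with jointly estimated
random-effect correlations.

Model
-----
Every fixed effect (drift means / congruency differences, boundary
separation, non-decision time; see :mod:`driftsem.design`) carries a
by-subject random effect.  On the unconstrained real line (no link
functions),

    theta_s = beta + u_s,     u_s ~ MVN(0, diag(tau) * Omega * diag(tau)),

with a weakly-informative half-t prior on the random-effect standard
deviations ``tau``, an LKJ prior on the correlation matrix ``Omega``
(optionally block-structured by diffusion parameter), and Cauchy priors on
the fixed effects.  Trials contribute Wiener first-passage-time
log-densities at the subject-level parameters; implied nonpositive boundary
separations or non-decision times exceeding an observed response time send
the log posterior to -inf rather than raising, so the sampler can traverse.

Sampling uses the package's NUTS implementation with a non-centered
parametrization (``u_s = diag(tau) L z_s`` with ``z_s`` standard normal and
``L`` the correlation Cholesky factor).  Convergence is gated on split
R-hat < 1.05 for all fixed effects, random-effect SDs and correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec, build_design
from .nuts import nuts_sample
from .prep import ControlRoleMap, TrialDataset
from .transforms import CorrCholeskyTransform, half_t_logpdf_grad
from .wiener import wiener_logpdf_grad

__all__ = [
    "PriorSpec",
    "HierarchicalDiffusionModel",
    "DiffusionResults",
    "PosteriorDraws",
    "ConvergenceReport",
    "CovarianceDraws",
    "extract_cov_draws",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyper-parameters (all scales > 0).

    Defaults: LKJ concentration 1 (uniform over correlation matrices),
    half-t(3, 10) on random-effect SDs, Cauchy(0, 5) on drift means,
    Cauchy(0, 2.5) on drift differences, and weakly-informative Cauchy
    priors centered at plausible values for boundary separation (1.5) and
    non-decision time (0.3).
    """

    lkj_eta: float = 1.0
    sd_df: float = 3.0
    sd_scale: float = 10.0
    v_mean_scale: float = 5.0
    v_delta_scale: float = 2.5
    a_loc: float = 1.5
    a_scale: float = 2.5
    t0_loc: float = 0.3
    t0_scale: float = 2.5

    def __post_init__(self):
        for name in ("lkj_eta", "sd_df", "sd_scale", "v_mean_scale",
                     "v_delta_scale", "a_scale", "t0_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ConvergenceReport:
    rhat: dict
    threshold: float = 1.05

    @property
    def passed(self) -> bool:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return bool(vals) and max(vals) < self.threshold

    @property
    def worst(self) -> tuple[str, float]:
        name = max(self.rhat, key=lambda k: self.rhat[k])
        return name, self.rhat[name]


@dataclass
class PosteriorDraws:
    """Group-level posterior draws, shaped (chains, draws, ...)."""

    param_names: list[str]
    subjects: list
    beta: np.ndarray       # (C, D, K)
    tau: np.ndarray        # (C, D, K)
    omega: np.ndarray      # (C, D, K, K) correlation matrices
    u: np.ndarray | None   # (C, D, S, K) subject displacements

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape((-1,) + arr.shape[2:])


@dataclass
class CovarianceDraws:
    """Per-draw covariance/correlation matrices of a parameter subset."""

    names: list[str]
    covs: np.ndarray    # (n_draws, k, k)
    corrs: np.ndarray   # (n_draws, k, k)

    @property
    def mean_cov(self) -> np.ndarray:
        return self.covs.mean(axis=0)

    @property
    def mean_corr(self) -> np.ndarray:
        return self.corrs.mean(axis=0)

    def corr_interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        lo = np.quantile(self.corrs, (1 - level) / 2, axis=0)
        hi = np.quantile(self.corrs, (1 + level) / 2, axis=0)
        return lo, hi

    def mean_corr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_corr, index=self.names, columns=self.names)


class HierarchicalDiffusionModel:
    """Hierarchical Wiener diffusion model for a trial-level dataset.

    Parameters
    ----------
    data : TrialDataset or DataFrame with (subject, task, condition, rt, correct)
    coding : 'difference' or 'condition'
    roles : ControlRoleMap, optional (defaults to incongruent = high control)
    priors : PriorSpec, optional
    block_corr : restrict correlations to within-diffusion-parameter blocks
    """

    def __init__(self, data, coding: str = "difference",
                 roles: ControlRoleMap | None = None,
                 priors: PriorSpec | None = None,
                 block_corr: bool = False):
        if not isinstance(data, TrialDataset):
            data = TrialDataset(pd.DataFrame(data))
        self.data = data
        self.priors = priors or PriorSpec()
        self.design: DesignSpec = build_design(data, coding, roles, block_corr)
        d = self.design
        self._transforms = [
            CorrCholeskyTransform(len(b), self.priors.lkj_eta) for b in d.blocks
        ]
        self._m = sum(t.n_free for t in self._transforms)
        K, S = d.n_params, d.n_subjects
        self.n_free = 2 * K + self._m + S * K
        kind = np.asarray(d.param_kind)
        self._prior_loc = np.where(kind == "a", self.priors.a_loc,
                          np.where(kind == "t0", self.priors.t0_loc, 0.0))
        self._prior_scale = np.where(kind == "v_mean", self.priors.v_mean_scale,
                            np.where(kind == "v_delta", self.priors.v_delta_scale,
                            np.where(kind == "a", self.priors.a_scale,
                                     self.priors.t0_scale)))
        self._vd_safe = np.where(d.vd_idx < 0, 0, d.vd_idx)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "HierarchicalDiffusionModel":
        return cls(TrialDataset(df), **kwargs)

    # ---- parameter vector packing -----------------------------------------
    def pack(self, beta, zeta, r, Z) -> np.ndarray:
        return np.concatenate([np.ravel(beta), np.ravel(zeta), np.ravel(r), np.ravel(Z)])

    def unpack(self, x: np.ndarray):
        K, S = self.design.n_params, self.design.n_subjects
        beta = x[:K]
        zeta = x[K:2 * K]
        r = x[2 * K:2 * K + self._m]
        Z = x[2 * K + self._m:].reshape(S, K)
        return beta, zeta, r, Z

    def _chol_blocks(self, r):
        out, pos = [], 0
        for tr in self._transforms:
            L, aux = tr.forward(r[pos:pos + tr.n_free])
            out.append((L, aux))
            pos += tr.n_free
        return out

    def subject_effects(self, x: np.ndarray) -> np.ndarray:
        """Subject displacement matrix U (S, K) implied by a parameter vector."""
        beta, zeta, r, Z = self.unpack(x)
        tau = np.exp(zeta)
        U = np.zeros_like(Z)
        for (L, _), idx in zip(self._chol_blocks(r), self.design.blocks):
            U[:, idx] = (Z[:, idx] @ L.T) * tau[idx]
        return U

    # ---- log posterior -----------------------------------------------------
    def log_posterior(self, x: np.ndarray, prior_only: bool = False) -> float:
        return self.log_posterior_grad(x, prior_only)[0]

    def log_posterior_grad(self, x: np.ndarray, prior_only: bool = False):
        """Joint log density of data and parameters, with analytic gradient.

        With ``prior_only`` the likelihood term is dropped (zero-trial
        case), leaving the prior measure on the unconstrained space.
        """
        d = self.design
        pr = self.priors
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_free,):
            raise ValueError(f"expected parameter vector of length {self.n_free}")
        beta, zeta, r, Z = self.unpack(x)
        tau = np.exp(zeta)
        blocks = self._chol_blocks(r)

        U = np.zeros_like(Z)
        for (L, _), idx in zip(blocks, d.blocks):
            U[:, idx] = (Z[:, idx] @ L.T) * tau[idx]
        Theta = beta[None, :] + U

        lp = 0.0
        gTheta = np.zeros_like(Theta)
        if not prior_only and d.n_trials:
            s = d.subj_idx
            v = Theta[s, d.vb_idx] + d.vd_coef * Theta[s, self._vd_safe]
            a = Theta[s, d.a_idx]
            t0 = Theta[s, d.t0_idx]
            if np.any(a <= 0) or np.any(d.rt <= t0) or np.any(t0 < 0):
                return -np.inf, np.zeros_like(x)
            ll, grads = wiener_logpdf_grad(d.rt, d.correct, v, a, t0)
            if not np.all(np.isfinite(ll)):
                return -np.inf, np.zeros_like(x)
            lp += float(ll.sum())
            gv, ga, gt0 = grads
            np.add.at(gTheta, (s, d.vb_idx), gv)
            np.add.at(gTheta, (s, self._vd_safe), d.vd_coef * gv)
            np.add.at(gTheta, (s, d.a_idx), ga)
            np.add.at(gTheta, (s, d.t0_idx), gt0)

        # priors --------------------------------------------------------
        lp_b = -np.log1p(((beta - self._prior_loc) / self._prior_scale) ** 2)
        g_b = -2.0 * (beta - self._prior_loc) / (
            self._prior_scale ** 2 + (beta - self._prior_loc) ** 2
        )
        lp += float(lp_b.sum())

        lp_t, g_t = half_t_logpdf_grad(tau, pr.sd_df, pr.sd_scale)
        lp += float(lp_t.sum()) + float(zeta.sum())  # + log-Jacobian

        lp += -0.5 * float(np.sum(Z * Z))

        gbeta = gTheta.sum(axis=0) + g_b
        gZ = -Z.copy()
        gtau = np.zeros_like(tau)
        gr = np.empty(self._m)
        pos = 0
        for (L, aux), idx, tr in zip(blocks, d.blocks, self._transforms):
            lp += tr.log_density(aux)
            gU_b = gTheta[:, idx]
            gZ[:, idx] += (gU_b * tau[idx]) @ L
            M = Z[:, idx] @ L.T
            gtau[idx] = np.sum(gU_b * M, axis=0)
            gL = (gU_b * tau[idx]).T @ Z[:, idx]
            gr[pos:pos + tr.n_free] = tr.backward(aux, gL)
            pos += tr.n_free
        gzeta = (gtau + g_t) * tau + 1.0

        grad = self.pack(gbeta, gzeta, gr, gZ)
        return lp, grad

    # ---- initialization ----------------------------------------------------
    def initial_point(self, rng: np.random.Generator | None = None) -> np.ndarray:
        d = self.design
        K, S = d.n_params, d.n_subjects
        beta = np.zeros(K)
        kind = np.asarray(d.param_kind)
        beta[kind == "v_mean"] = 1.5
        beta[kind == "v_delta"] = 0.3
        beta[kind == "a"] = 1.5
        # non-decision init safely below each task's fastest response
        if d.n_trials:
            for task in d.tasks:
                mask = np.asarray([d.param_names[i] == f"t0[{task}]" for i in range(K)])
                min_rt = float(d.rt[d.a_idx == d.param_index(f"a[{task}]")[0]].min())
                beta[mask] = min(0.25, 0.5 * min_rt)
        else:
            beta[kind == "t0"] = 0.25
        zeta = np.full(K, np.log(0.1))
        r = np.zeros(self._m)
        Z = np.zeros((S, K))
        x = self.pack(beta, zeta, r, Z)
        if rng is not None:
            jitter = 0.05 * rng.standard_normal(self.n_free)
            # leave t0 and boundary fixed effects unjittered to stay valid
            protect = np.concatenate([
                (kind == "t0") | (kind == "a"),
                np.zeros(self.n_free - K, dtype=bool),
            ])
            xj = x + np.where(protect, 0.0, jitter)
            if np.isfinite(self.log_posterior(xj)):
                return xj
        return x

    # ---- sampling ----------------------------------------------------------
    def fit(self, chains: int = 4, warmup: int = 500, draws: int = 500,
            seed: int | None = None, target_accept: float = 0.8,
            max_treedepth: int = 10, prior_only: bool = False,
            max_refits: int = 0, store_subject_effects: bool = True,
            rhat_threshold: float = 1.05) -> "DiffusionResults":
        """Run NUTS; refit with more post-warmup draws while the R-hat gate
        fails and refits remain."""
        attempt = 0
        cur_draws = draws
        while True:
            res = self._fit_once(chains, warmup, cur_draws, seed, target_accept,
                                 max_treedepth, prior_only,
                                 store_subject_effects, rhat_threshold,
                                 refit_round=attempt)
            if res.convergence.passed or attempt >= max_refits:
                return res
            attempt += 1
            cur_draws *= 2

    def _fit_once(self, chains, warmup, draws, seed, target_accept,
                  max_treedepth, prior_only, store_u, rhat_threshold,
                  refit_round=0):
        d = self.design
        K, S = d.n_params, d.n_subjects
        seeds = np.random.SeedSequence(
            seed if seed is None else seed + 100003 * refit_round
        ).spawn(chains)

        def logp_grad(x):
            return self.log_posterior_grad(x, prior_only=prior_only)

        beta = np.empty((chains, draws, K))
        tau = np.empty((chains, draws, K))
        omega = np.empty((chains, draws, K, K))
        U = np.empty((chains, draws, S, K)) if store_u else None
        chain_stats = []
        for c in range(chains):
            rng = np.random.default_rng(seeds[c])
            x0 = self.initial_point(rng)
            raw, stats = nuts_sample(
                logp_grad, x0, warmup, draws, rng,
                target_accept=target_accept, max_treedepth=max_treedepth,
            )
            chain_stats.append(stats)
            for k in range(draws):
                b, z, r, Zm = self.unpack(raw[k])
                beta[c, k] = b
                tau[c, k] = np.exp(z)
                Om = np.eye(K)
                for (L, _), idx in zip(self._chol_blocks(r), d.blocks):
                    Om[np.ix_(idx, idx)] = L @ L.T
                omega[c, k] = Om
                if store_u:
                    Uk = np.zeros((S, K))
                    for (L, _), idx in zip(self._chol_blocks(r), d.blocks):
                        Uk[:, idx] = (Zm[:, idx] @ L.T) * tau[c, k][idx]
                    U[c, k] = Uk

        post = PosteriorDraws(list(d.param_names), list(d.subjects),
                              beta, tau, omega, U)
        report = self._convergence(post, rhat_threshold)
        return DiffusionResults(self, post, report, chain_stats,
                                prior_only=prior_only)

    def _convergence(self, post: PosteriorDraws, threshold: float) -> ConvergenceReport:
        from arviz import rhat as az_rhat

        d = self.design
        rh = {}
        for k, name in enumerate(d.param_names):
            rh[f"beta[{name}]"] = float(az_rhat(post.beta[:, :, k]))
            rh[f"tau[{name}]"] = float(az_rhat(post.tau[:, :, k]))
        for idx in d.blocks:
            for ai in range(len(idx)):
                for bi in range(ai):
                    i, j = idx[ai], idx[bi]
                    series = post.omega[:, :, i, j]
                    if np.allclose(series.std(), 0):
                        continue
                    rh[f"omega[{d.param_names[i]},{d.param_names[j]}]"] = float(
                        az_rhat(series)
                    )
        return ConvergenceReport(rh, threshold)


def extract_cov_draws(draws: PosteriorDraws, subset) -> CovarianceDraws:
    """Per-draw covariance/correlation matrices for a named parameter subset.

    ``subset`` is a list of parameter names or a prefix such as
    ``"v_delta"``.  Per draw, covariance = diag(tau) * Omega * diag(tau)
    restricted to the subset; correlations are the corresponding Omega
    block (zero across correlation blocks when the model was fitted with a
    block structure).
    """
    names = draws.param_names
    if isinstance(subset, str):
        idx = [i for i, n in enumerate(names)
               if n == subset or n.startswith(subset + "[")]
        if not idx:
            raise KeyError(f"no parameter matches {subset!r}")
    else:
        idx = []
        for n in subset:
            if n not in names:
                raise KeyError(f"unknown parameter {n!r}")
            idx.append(names.index(n))
    idx = np.asarray(idx)
    tau = draws.flat(draws.tau)[:, idx]
    om = draws.flat(draws.omega)[:, idx[:, None], idx[None, :]]
    covs = tau[:, :, None] * om * tau[:, None, :]
    return CovarianceDraws([names[i] for i in idx], covs, om)


class DiffusionResults:
    """Posterior draws, convergence diagnostics and derived quantities."""

    def __init__(self, model: HierarchicalDiffusionModel, draws: PosteriorDraws,
                 convergence: ConvergenceReport, sampler_stats,
                 prior_only: bool = False):
        self.model = model
        self.draws = draws
        self.convergence = convergence
        self.sampler_stats = sampler_stats
        self.prior_only = prior_only

    @property
    def divergences(self) -> int:
        return int(sum(s.divergences for s in self.sampler_stats))

    def cov_draws(self, subset) -> CovarianceDraws:
        return extract_cov_draws(self.draws, subset)

    def summary(self) -> pd.DataFrame:
        """Posterior means, SDs, central 95% intervals and R-hat for the
        group-level parameters."""
        rows = []
        d = self.model.design
        for k, name in enumerate(d.param_names):
            for label, arr in ((f"beta[{name}]", self.draws.flat(self.draws.beta)[:, k]),
                               (f"tau[{name}]", self.draws.flat(self.draws.tau)[:, k])):
                rows.append({
                    "parameter": label,
                    "mean": arr.mean(),
                    "sd": arr.std(ddof=1),
                    "q2.5": np.quantile(arr, 0.025),
                    "median": np.quantile(arr, 0.5),
                    "q97.5": np.quantile(arr, 0.975),
                    "rhat": self.convergence.rhat.get(label, np.nan),
                })
        for idx in d.blocks:
            for ai in range(len(idx)):
                for bi in range(ai):
                    i, j = idx[ai], idx[bi]
                    arr = self.draws.flat(self.draws.omega)[:, i, j]
                    label = f"omega[{d.param_names[i]},{d.param_names[j]}]"
                    rows.append({
                        "parameter": label,
                        "mean": arr.mean(),
                        "sd": arr.std(ddof=1),
                        "q2.5": np.quantile(arr, 0.025),
                        "median": np.quantile(arr, 0.5),
                        "q97.5": np.quantile(arr, 0.975),
                        "rhat": self.convergence.rhat.get(label, np.nan),
                    })
        return pd.DataFrame(rows).set_index("parameter")

    def subject_params(self, chain: int, draw: int) -> pd.DataFrame:
        """Subject-level parameter matrix beta + u_s for one draw."""
        if self.draws.u is None:
            raise ValueError("subject effects were not stored")
        theta = self.draws.beta[chain, draw][None, :] + self.draws.u[chain, draw]
        return pd.DataFrame(theta, index=self.draws.subjects,
                            columns=self.draws.param_names)

    def ppc(self, n_draws: int = 500, seed: int | None = None, roles=None):
        """Posterior-predictive CCC report (see :func:`driftsem.ppc.ppc_report`)."""
        from .ppc import ppc_report

        return ppc_report(self, n_draws=n_draws, seed=seed, roles=roles)

    def to_inference_data(self):
        """Export draws as an arviz InferenceData (self-describing names)."""
        import arviz as az

        names = self.draws.param_names
        posterior = {
            "beta": self.draws.beta,
            "tau": self.draws.tau,
            "omega": self.draws.omega,
        }
        dims = {"beta": ["param"], "tau": ["param"],
                "omega": ["param", "param2"]}
        coords = {"param": names, "param2": names,
                  "subject": [str(s) for s in self.draws.subjects]}
        if self.draws.u is not None:
            posterior["u"] = self.draws.u
            dims["u"] = ["subject", "param"]
        return az.from_dict(posterior=posterior, coords=coords, dims=dims)

    def save(self, path) -> None:
        self.to_inference_data().to_netcdf(str(path))
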