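"""SEM over the posterior distribution of covariance matrices.

The hierarchical diffusion fit yields a posterior distribution over the
random-effect covariance matrix.  Beyond fitting each CFA once to the
posterior-mean matrix, the same model is fitted to many covariance matrices
sampled from the posterior, producing a distribution of fit statuses
(good / acceptable / bad / warnings / nonconverged) and of reliability
coefficients that propagates the uncertainty of the correlation estimates
into the SEM stage.

Also here: correlation exceedance probabilities - for a set of thresholds,
the posterior probability that the *average* pairwise correlation exceeds
the threshold and that *all* pairwise correlations do (the positive
manifold) - and a Monte-Carlo sampler for the LKJ prior used to calibrate
what an uninformative dataset would imply for those probabilities
(about 0.16 for all-positive among three measures, 0.04 among four).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cfa import CFAModel, CFAResults, SEMModelSpec

__all__ = [
    "run_posterior_sem",
    "PosteriorSEMSummary",
    "correlation_exceedance",
    "lkj_rvs",
    "DEFAULT_AVG_THRESHOLDS",
    "DEFAULT_ALL_THRESHOLDS",
]

DEFAULT_AVG_THRESHOLDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
DEFAULT_ALL_THRESHOLDS = (0.0, 0.1, 0.2, 0.3)

_STATUSES = ("good", "acceptable", "bad", "warnings", "nonconverged")


@dataclass
class PosteriorSEMSummary:
    """Fit-status counts and reliability distribution across draws."""

    status_counts: dict
    reliability: np.ndarray            # over acceptable-or-good fits only
    mean_result: CFAResults | None     # fit to the posterior-mean matrix
    mean_reliability: float | None
    n_analyzed: int
    empty: bool = False
    reliability_label: str = "omega"

    def status_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": [self.status_counts.get(s, 0) for s in _STATUSES]},
            index=list(_STATUSES),
        )

    def plot_reliability(self, ax=None, bins=20):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        if len(self.reliability):
            ax.hist(self.reliability, bins=bins, color="C0", alpha=0.8)
        if self.mean_reliability is not None:
            ax.axvline(self.mean_reliability, color="red", lw=1.5)
        ax.set_xlabel(self.reliability_label)
        ax.set_ylabel("count")
        return ax


def _subsample_indices(n_total: int, n_matrices: int, seed) -> np.ndarray:
    """Evenly spaced draw indices after a seed-based rotation."""
    rng = np.random.default_rng(seed)
    offset = int(rng.integers(n_total))
    base = np.floor(np.arange(n_matrices) * n_total / n_matrices).astype(int)
    return (base + offset) % n_total


def _reliability_of(fit: CFAResults, omega_h_factor: str | None) -> float:
    if omega_h_factor is None:
        return fit.omega()
    return fit.omega_hierarchical(omega_h_factor)


def run_posterior_sem(
    cov_draws,
    spec: SEMModelSpec,
    n_obs: int,
    n_matrices: int = 500,
    seed: int | None = None,
    omega_h_factor: str | None = None,
    mean_matrix=None,
) -> PosteriorSEMSummary:
    """Fit ``spec`` to ``n_matrices`` posterior covariance matrices.

    ``cov_draws`` is a CovarianceDraws or an (n, k, k) array.  Draws are
    subsampled deterministically given ``seed`` (evenly spaced after a
    random rotation).  Each fit starts cold; statuses are classified with
    the CFI/SRMR(/RMSEA) rule and the reliability distribution is collected
    over draws with acceptable-or-good fit only.  ``omega_h_factor`` selects
    hierarchical omega of that specific factor instead of single-factor
    omega.
    """
    covs = cov_draws.covs if hasattr(cov_draws, "covs") else np.asarray(cov_draws, float)
    n_total = covs.shape[0]
    if n_matrices > n_total:
        raise ValueError(f"n_matrices={n_matrices} exceeds available draws ({n_total})")
    label = "omega" if omega_h_factor is None else f"omega_h[{omega_h_factor}]"

    mean_result, mean_rel = None, None
    S_mean = (cov_draws.mean_cov if hasattr(cov_draws, "mean_cov")
              else covs.mean(axis=0)) if mean_matrix is None else np.asarray(mean_matrix)
    try:
        mean_result = CFAModel(spec, S_mean, n_obs).fit()
        if mean_result.status != "nonconverged":
            mean_rel = _reliability_of(mean_result, omega_h_factor)
    except (ValueError, np.linalg.LinAlgError):
        mean_result = None

    if n_matrices == 0:
        return PosteriorSEMSummary({}, np.empty(0), mean_result, mean_rel, 0,
                                   empty=True, reliability_label=label)

    counts = {s: 0 for s in _STATUSES}
    rel = []
    for i in _subsample_indices(n_total, n_matrices, seed):
        try:
            fit = CFAModel(spec, covs[i], n_obs).fit()
            status = fit.classify()
        except (ValueError, np.linalg.LinAlgError):
            status = "nonconverged"
            fit = None
        counts[status] += 1
        if status in ("good", "acceptable"):
            rel.append(_reliability_of(fit, omega_h_factor))
    return PosteriorSEMSummary(counts, np.asarray(rel), mean_result, mean_rel,
                               n_matrices, reliability_label=label)


def correlation_exceedance(
    corr_draws,
    avg_thresholds=DEFAULT_AVG_THRESHOLDS,
    all_thresholds=DEFAULT_ALL_THRESHOLDS,
) -> pd.DataFrame:
    """Exceedance probabilities of pairwise correlations over draws.

    Per draw, the average and the minimum of the off-diagonal
    upper-triangle entries are computed; the returned table gives, per
    threshold, P(average > t) and P(all > t) (strict inequalities).
    """
    corrs = corr_draws.corrs if hasattr(corr_draws, "corrs") else np.asarray(corr_draws, float)
    if corrs.ndim != 3 or corrs.shape[0] == 0:
        raise ValueError("need a nonempty stack of correlation matrices")
    k = corrs.shape[1]
    iu = np.triu_indices(k, 1)
    vals = corrs[:, iu[0], iu[1]]
    avg = vals.mean(axis=1)
    low = vals.min(axis=1)
    rows = []
    for t in avg_thresholds:
        rows.append({"threshold": t, "statistic": "average",
                     "probability": float(np.mean(avg > t))})
    for t in all_thresholds:
        rows.append({"threshold": t, "statistic": "all",
                     "probability": float(np.mean(low > t))})
    return pd.DataFrame(rows)


def lkj_rvs(dim: int, eta: float = 1.0, size: int = 1,
            rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Sample correlation matrices from the LKJ distribution.

    C-vine construction: partial correlations are drawn from scaled Beta
    distributions and composed into full correlations.  With eta = 1 the
    distribution is uniform over valid correlation matrices.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = np.empty((size, dim, dim))
    out[:] = np.eye(dim)
    if dim == 1:
        return out
    # partial correlations p[k, i], 0 <= k < i < dim
    P = np.zeros((size, dim, dim))
    for k in range(dim - 1):
        b = eta + (dim - 1 - (k + 1)) / 2.0
        for i in range(k + 1, dim):
            P[:, k, i] = 2.0 * rng.beta(b, b, size=size) - 1.0
            rho = P[:, k, i].copy()
            for j in range(k - 1, -1, -1):
                rho = rho * np.sqrt(
                    (1.0 - P[:, j, i] ** 2) * (1.0 - P[:, j, k] ** 2)
                ) + P[:, j, i] * P[:, j, k]
            out[:, k, i] = rho
            out[:, i, k] = rho
    return out
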