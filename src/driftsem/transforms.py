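"""Unconstrained parametrizations used by the hierarchical sampler.

The correlation matrix of the subject-level random effects is sampled
through its Cholesky factor, parametrized by canonical partial correlations
(CPCs): an unconstrained vector ``r`` maps through ``y = tanh(r)`` to CPCs
in (-1, 1), and the CPCs build a valid lower-triangular Cholesky factor row
by row.  The log-density combines the LKJ prior on the resulting correlation
matrix with the log-Jacobians of both maps, so that sampling ``r`` with a
flat reference measure targets LKJ(eta) exactly.  The reverse-mode gradient
of the whole construction is implemented by hand (no autodiff backend is
used anywhere in the package).

Also here: half-t and Cauchy prior helpers with gradients, and the
log-scale transform for positive standard deviations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CorrCholeskyTransform", "half_t_logpdf_grad", "cauchy_logpdf_grad"]


class CorrCholeskyTransform:
    """Bijection between R^{K(K-1)/2} and KxK correlation Cholesky factors.

    ``forward`` returns the Cholesky factor plus a cache; ``log_density``
    evaluates the LKJ(eta) prior in the unconstrained space (prior plus
    Jacobian terms); ``backward`` turns a gradient with respect to the
    Cholesky factor into a gradient with respect to the unconstrained
    vector, adding the prior/Jacobian gradient.
    """

    def __init__(self, dim: int, eta: float = 1.0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        if eta <= 0:
            raise ValueError("eta must be > 0")
        self.dim = dim
        self.eta = eta
        self.n_free = dim * (dim - 1) // 2
        # row-major strict lower-triangle order
        self._rows = [(i, j) for i in range(1, dim) for j in range(i)]

    def forward(self, r: np.ndarray):
        K = self.dim
        r = np.asarray(r, dtype=float)
        if r.shape != (self.n_free,):
            raise ValueError(f"expected vector of length {self.n_free}")
        y = np.tanh(r)
        L = np.zeros((K, K))
        L[0, 0] = 1.0
        cs = []  # per row i: array [c_0 .. c_i]
        pos = 0
        for i in range(1, K):
            c = np.empty(i + 1)
            c[0] = 1.0
            for j in range(i):
                yij = y[pos + j]
                L[i, j] = yij * c[j]
                c[j + 1] = c[j] * np.sqrt(max(1.0 - yij * yij, 1e-300))
            L[i, i] = c[i]
            cs.append(c)
            pos += i
        return L, (y, cs)

    def log_density(self, aux) -> float:
        """LKJ(eta) log-density in the unconstrained space (up to const)."""
        y, cs = aux
        K, eta = self.dim, self.eta
        # tanh Jacobian log(1 - y^2) = 2 log sech(r), written overflow-safely
        lp = float(np.sum(np.log1p(-np.clip(y * y, 0.0, 1.0 - 1e-16))))
        pos = 0
        for i in range(1, K):
            c = cs[i - 1]
            if i >= 2:
                lp += float(np.sum(np.log(c[1:i])))  # y -> L Jacobian
            lp += (K - 1 - i + 2.0 * (eta - 1.0)) * np.log(c[i])  # LKJ on L_ii
            pos += i
        return lp

    def backward(self, aux, gL: np.ndarray) -> np.ndarray:
        """Gradient wrt r of [downstream(L) + log_density], given dL."""
        y, cs = aux
        K, eta = self.dim, self.eta
        gr = np.zeros(self.n_free)
        pos = 0
        for i in range(1, K):
            c = cs[i - 1]
            gc = gL[i, i] + (K - 1 - i + 2.0 * (eta - 1.0)) / c[i]
            for j in range(i - 1, -1, -1):
                yij = y[pos + j]
                s = np.sqrt(max(1.0 - yij * yij, 1e-300))
                gs = gc * c[j]
                gcj = gc * s
                gy = gL[i, j] * c[j] + gs * (-yij / s)
                gcj += gL[i, j] * yij
                if 1 <= j <= i - 1:
                    gcj += 1.0 / c[j]  # Jacobian sum log c_j
                gr[pos + j] = gy * (1.0 - yij * yij) - 2.0 * yij  # chain + tanh Jac
                gc = gcj
            pos += i
        return gr


def half_t_logpdf_grad(x: np.ndarray, df: float, scale: float):
    """Half-t log-density (up to const) and d/dx, for x > 0 elementwise."""
    x = np.asarray(x, dtype=float)
    z2 = (x / scale) ** 2
    lp = -0.5 * (df + 1.0) * np.log1p(z2 / df)
    g = -(df + 1.0) * x / (df * scale ** 2 + x ** 2)
    return lp, g


def cauchy_logpdf_grad(x: np.ndarray, loc: float, scale: float):
    """Cauchy log-density (up to const) and d/dx, elementwise."""
    x = np.asarray(x, dtype=float)
    d = x - loc
    lp = -np.log1p((d / scale) ** 2)
    g = -2.0 * d / (scale ** 2 + d ** 2)
    return lp, g
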