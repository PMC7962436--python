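"""Adaptive Gauss-Hermite quadrature for scalar-random-effect models.

Independent validation oracle for the Laplace objective: for models whose
per-cluster random effect is a scalar (the random-intercept model), the
marginal log-likelihood

    log integral N(u; 0, sigma^2) prod_j Pois(y_ij; O_i e^{a_ij'beta + u}) du

is computed by Gauss-Hermite quadrature recentered at the posterior mode and
rescaled by the curvature there, which is essentially exact at 21 nodes.
This module deliberately shares no code path with
:class:`~swdsim.glmm.laplace.LaplaceProblem` beyond elementary numpy.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import gammaln, logsumexp

__all__ = ["aghq_loglik_random_intercept"]


def aghq_loglik_random_intercept(
    y: np.ndarray,
    offsets: np.ndarray,
    A: np.ndarray,
    beta: np.ndarray,
    sigma: float,
    n_nodes: int = 21,
) -> float:
    """Exact-by-quadrature marginal log-likelihood of the random-intercept model.

    Parameters mirror the Laplace problem: ``y`` is ``(N, n)``, ``A`` is the
    ``(N, n, p)`` fixed design, ``sigma`` the random-intercept SD.
    """
    y = np.asarray(y, dtype=float)
    N, n = y.shape
    log_off = np.log(np.asarray(offsets, dtype=float))[:, None]
    fixed = log_off + np.einsum("ijp,p->ij", np.asarray(A, float), beta)
    nodes, weights = hermgauss(n_nodes)
    total = 0.0
    for i in range(N):
        # scalar Newton for the posterior mode
        u = 0.0
        for _ in range(100):
            mu = np.exp(fixed[i] + u)
            g = (y[i] - mu).sum() - u / sigma**2
            h = mu.sum() + 1.0 / sigma**2
            step = g / h
            u += step
            if abs(g) < 1e-12 * (1 + y[i].sum()):
                break
        tau = 1.0 / np.sqrt(mu.sum() + 1.0 / sigma**2)
        uk = u + np.sqrt(2.0) * tau * nodes
        eta = fixed[i][None, :] + uk[:, None]
        loglik_k = (y[i][None, :] * eta - np.exp(eta) - gammaln(y[i] + 1.0)[None, :]).sum(
            axis=1
        )
        logprior_k = -0.5 * np.log(2 * np.pi * sigma**2) - 0.5 * uk**2 / sigma**2
        total += logsumexp(
            np.log(weights) + nodes**2 + loglik_k + logprior_k
        ) + np.log(np.sqrt(2.0) * tau)
    return float(total)
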