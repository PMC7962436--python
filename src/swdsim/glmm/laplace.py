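"""Laplace-approximated marginal likelihood for Poisson mixed models.

For cluster ``i`` with counts ``y_i``, log-offset ``o_i``, fixed design
``A_i``, random loading ``Z_i`` and shared random-effect covariance
``Sigma = L L'``, the marginal likelihood integrates the Poisson likelihood
against the ``N(0, Sigma)`` prior.  Internally the random effects are
whitened (``u = L v``, "spherical" coordinates), so the penalized inner
problem

    max_v  loglik(y_i | eta_i = A_i beta + o_i + Z_i L v) - ||v||^2 / 2

is strictly concave with Hessian ``Htil_i = L' Z_i' W_i Z_i L + I`` that
stays well conditioned even when ``Sigma`` collapses toward singularity
(variance components at the zero boundary).  The Laplace contribution is

    l_i = loglik(y_i | v_i^) - ||v_i^||^2 / 2 - log det(Htil_i) / 2,

because the prior normalization ``-log det(Sigma)/2`` and the curvature
``-log det(Z'WZ + Sigma^-1)/2`` combine exactly into
``-log det(Htil)/2``, and the ``(2 pi)^{q/2}`` factors of the prior and the
Laplace integral cancel; ``sum_i l_i`` plus the ``-log y!`` terms is
directly comparable to exact marginal log-likelihoods such as the
adaptive-quadrature oracle.

The gradient is exact, including the dependence of the mode and of
``log det Htil`` on the parameters (for the Poisson/log link
``dW/deta = W``, so no third-derivative bookkeeping beyond ``W`` itself is
needed).  With ``s_ij = mu_ij (Zt H^-1 Zt')_jj`` (``Zt = Z L``), the
fixed-effect gradient is

    dl/dbeta = A' [ (y - mu) - s/2 + W Zt Htil^-1 Zt' s / 2 ],

and the covariance gradient contracts the factor derivatives ``D_k = dL/dphi_k``
against a single matrix ``S`` assembled from ``v^``, ``Htil^-1`` and
``w = L^-T Htil^-1 L' Z' s`` (all numerically benign quantities); the
formulas are verified against finite differences in the test suite.

All clusters are processed in batched (stacked) linear algebra; clusters
with lower-dimensional control blocks are zero-padded (see
:mod:`swdsim.glmm.covariance`), which leaves the objective exact.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaln

from .covariance import CovarianceStructure

__all__ = ["LaplaceProblem", "InnerError"]


class InnerError(RuntimeError):
    """Inner mode search failed; the outer step should be rejected."""


class LaplaceProblem:
    """Laplace objective/gradient for one dataset and one model structure.

    Parameters
    ----------
    y : (N, n) counts
    offsets : (N,) cluster population sizes
    A : (N, n, p) fixed-effect design
    Z : (N, n, q) random-effect loadings
    structure : covariance parameterization of the shared ``Sigma``

    The whitened posterior modes are warm-started across calls, which keeps
    the inner Newton loop to one or two iterations during outer optimization.
    """

    def __init__(
        self,
        y: np.ndarray,
        offsets: np.ndarray,
        A: np.ndarray,
        Z: np.ndarray,
        structure: CovarianceStructure,
        inner_tol: float = 1e-9,
        inner_maxiter: int = 100,
    ):
        self.y = np.asarray(y, dtype=float)
        self.N, self.n = self.y.shape
        self.A = np.asarray(A, dtype=float)
        self.Z = np.asarray(Z, dtype=float)
        self.q = self.Z.shape[-1]
        self.p = self.A.shape[-1]
        self.log_offsets = np.log(np.asarray(offsets, dtype=float))[:, None]
        self.structure = structure
        if structure.dim != self.q:
            raise ValueError(f"structure dim {structure.dim} != loading dim {self.q}")
        self.inner_tol = inner_tol * (1.0 + self.y.sum(axis=1))  # per cluster
        self.inner_maxiter = inner_maxiter
        self.const = -gammaln(self.y + 1.0).sum()
        self.v = np.zeros((self.N, self.q))  # warm-started whitened modes
        self.n_inner_total = 0

    # ------------------------------------------------------------------
    def split(self, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        psi = np.asarray(psi, dtype=float)
        return psi[: self.p], psi[self.p :]

    def pack(self, beta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return np.concatenate([np.asarray(beta, float), np.asarray(phi, float)])

    # ------------------------------------------------------------------
    # linear predictors are capped so that exploratory outer steps far from
    # the optimum keep the objective, gradient and Hessian finite; the cap
    # is far above any realistic mode (exp(40) expected events)
    ETA_MAX = 40.0

    def _penalized(self, base, Zt, v):
        """Per-cluster penalized log-likelihood in whitened coordinates."""
        eta = np.minimum(base + np.einsum("ijq,iq->ij", Zt, v), self.ETA_MAX)
        mu = np.exp(eta)
        pl = (self.y * eta - mu).sum(axis=1) - 0.5 * (v * v).sum(axis=1)
        return pl, mu

    def _inner(self, base: np.ndarray, Zt: np.ndarray):
        """Damped Newton search for all whitened modes simultaneously."""
        v = self.v.copy()
        pl, mu = self._penalized(base, Zt, v)
        if not np.all(np.isfinite(pl)):  # warm start invalid for these params
            v = np.zeros_like(v)
            pl, mu = self._penalized(base, Zt, v)
        converged = False
        eye = np.eye(self.q)
        for _ in range(self.inner_maxiter):
            self.n_inner_total += 1
            grad = np.einsum("ijq,ij->iq", Zt, self.y - mu) - v
            if np.all(np.abs(grad).max(axis=1) <= self.inner_tol):
                converged = True
                break
            H = np.einsum("ijq,ij,ijr->iqr", Zt, mu, Zt) + eye
            step = np.linalg.solve(H, grad[..., None])[..., 0]
            alpha = np.ones(self.N)
            # rounding slack for the ascent test; capped so that gigantic
            # penalized values far from the optimum cannot mask bad steps
            slack = 1e-10 * (1.0 + np.minimum(np.abs(pl), 1e8))
            for _ in range(40):
                pl_try, mu_try = self._penalized(base, Zt, v + alpha[:, None] * step)
                bad = ~(pl_try >= pl - slack)
                if not np.any(bad):
                    break
                alpha[bad] *= 0.5
            else:
                # no uphill move for some clusters (mode reached to rounding)
                alpha[bad] = 0.0
                pl_try, mu_try = self._penalized(base, Zt, v + alpha[:, None] * step)
            v = v + alpha[:, None] * step
            pl, mu = pl_try, mu_try
        if not converged:
            grad = np.einsum("ijq,ij->iq", Zt, self.y - mu) - v
            if not np.all(np.abs(grad).max(axis=1) <= 1e4 * self.inner_tol):
                raise InnerError("inner Newton did not converge")
        self.v = v
        H = np.einsum("ijq,ij,ijr->iqr", Zt, mu, Zt) + eye
        return v, pl, mu, H

    def _common(self, psi):
        beta, phi = self.split(psi)
        L = self.structure.build_chol(phi)
        Zt = np.einsum("ijq,qr->ijr", self.Z, L)
        base = self.log_offsets + np.einsum("ijp,p->ij", self.A, beta)
        v, pl, mu, H = self._inner(base, Zt)
        chol = np.linalg.cholesky(H)
        logdet_H = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
        value = pl.sum() + self.const - 0.5 * logdet_H.sum()
        return beta, phi, L, Zt, v, mu, H, value

    # ------------------------------------------------------------------
    def value(self, psi: np.ndarray) -> float:
        """Laplace log-marginal-likelihood."""
        return self._common(psi)[-1]

    def value_and_grad(self, psi: np.ndarray) -> tuple[float, np.ndarray]:
        """Laplace log-marginal-likelihood and its exact gradient."""
        beta, phi, L, Zt, v, mu, H, value = self._common(psi)
        Hinv = np.linalg.inv(H)
        Linv = solve_triangular(L, np.eye(self.q), lower=True)

        # s_ij = mu_ij (Zt Hinv Zt')_jj; the log-det's sensitivity to eta
        s = mu * np.einsum("ija,iab,ijb->ij", Zt, Hinv, Zt)
        Zts = np.einsum("ijq,ij->iq", Zt, s)  # Zt' s
        HinvZts = np.einsum("iab,ib->ia", Hinv, Zts)
        wzh = mu * np.einsum("ijq,iq->ij", Zt, HinvZts)
        r = (self.y - mu) - 0.5 * s + 0.5 * wzh
        grad_beta = np.einsum("ijp,ij->p", self.A, r)

        # covariance-parameter gradient: contract dL/dphi_k against S, with
        # vq = Sigma^-1 u^ = L^-T v^ and w = L^-T Hinv L' Z' s, all assembled
        # without ever forming Sigma^-1 (numerically stable near boundaries)
        vq = v @ Linv  # rows: L^-T v_i
        Zs = np.einsum("ijq,ij->iq", self.Z, s)  # Z' s
        w = np.einsum("iab,ib->ia", Hinv, Zs @ L) @ Linv
        vqL = vq @ L
        wL = w @ L
        S = (
            vq.T @ vqL
            - 0.5 * (vq.T @ wL + w.T @ vqL)
            + Linv.T @ Hinv.sum(axis=0)
            - self.N * Linv.T
        )
        D = self.structure.chol_jacobian(phi)
        grad_phi = np.einsum("kab,ab->k", D, S)

        return value, np.concatenate([grad_beta, grad_phi])
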