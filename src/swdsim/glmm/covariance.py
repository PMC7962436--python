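"""Random-effect covariance structures on an unconstrained scale.

Every structure parameterizes a single covariance matrix ``Sigma = L L'``
shared across clusters through the log-Cholesky map: diagonal entries of the
Cholesky factor ``L`` live on the log scale, off-diagonal entries are free.
Positive semidefiniteness is therefore structural, and variance components
can hit the zero boundary only asymptotically (a very negative log-diagonal),
which is reported as a boundary fit rather than an error.

Structures with per-cluster control blocks of differing dimension (the
group-by-time models, where a cluster crossing over at period ``t^I_i`` has
``t^I_i - 1`` control-period effects) are handled upstream by zero-padding
the loading matrices to the maximal block dimension; the padded coordinates
carry prior mass but no likelihood, so they integrate out exactly and the
effective per-cluster covariance is the leading principal submatrix of the
full ``Sigma`` -- which is exactly the intended sub-covariance convention,
because the Cholesky factor of a leading principal submatrix is the leading
submatrix of the Cholesky factor.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Isotropic", "Unstructured", "Composite", "CovarianceStructure"]

# bounds for L-BFGS-B on the unconstrained scale: log-SDs in [-8, 8]
# (SD between ~3e-4 and ~3e3), raw off-diagonal Cholesky entries in [-50, 50]
_LOG_DIAG_BOUNDS = (-8.0, 8.0)
_OFFDIAG_BOUNDS = (-50.0, 50.0)


class CovarianceStructure:
    """Interface: map an unconstrained vector ``phi`` to a Cholesky factor."""

    dim: int
    n_params: int

    def build_chol(self, phi: np.ndarray) -> np.ndarray:
        """Lower-triangular ``L`` with ``Sigma = L L'``."""
        raise NotImplementedError

    def chol_jacobian(self, phi: np.ndarray) -> np.ndarray:
        """``dL/dphi`` as an array of shape ``(n_params, dim, dim)``."""
        raise NotImplementedError

    def initial(self, sd: float = 0.1) -> np.ndarray:
        """Starting values corresponding to ``Sigma = sd^2 I``."""
        raise NotImplementedError

    def bounds(self) -> list[tuple[float, float]]:
        raise NotImplementedError

    def labels(self) -> list[str]:
        raise NotImplementedError

    def sigma(self, phi: np.ndarray) -> np.ndarray:
        L = self.build_chol(phi)
        return L @ L.T

    def at_lower_boundary(self, phi: np.ndarray, tol: float = 1e-6) -> bool:
        """True when any log-SD parameter sits at its lower bound."""
        lo = np.array([b[0] for b in self.bounds()])
        is_diag = np.array([lab.startswith("log_sd") for lab in self.labels()])
        phi = np.asarray(phi, dtype=float)
        return bool(np.any(is_diag & (phi <= lo + tol)))


class Isotropic(CovarianceStructure):
    """``Sigma = sigma^2 I_dim`` with one log-SD parameter (possibly tied
    across many coordinates, as for i.i.d. cluster-period effects)."""

    n_params = 1

    def __init__(self, dim: int, name: str = "sd"):
        self.dim = dim
        self.name = name

    def build_chol(self, phi):
        return np.exp(phi[0]) * np.eye(self.dim)

    def chol_jacobian(self, phi):
        return np.exp(phi[0]) * np.eye(self.dim)[None, :, :]

    def initial(self, sd: float = 0.1):
        return np.array([np.log(sd)])

    def bounds(self):
        return [_LOG_DIAG_BOUNDS]

    def labels(self):
        return [f"log_sd({self.name})"]


class Unstructured(CovarianceStructure):
    """Fully unstructured ``dim x dim`` covariance, ``dim(dim+1)/2`` params.

    Parameter order is row-wise over the lower triangle of ``L``:
    ``(0,0), (1,0), (1,1), (2,0), ...``, diagonals on the log scale.
    """

    def __init__(self, dim: int, name: str = "b"):
        self.dim = dim
        self.name = name
        self.rows, self.cols = np.tril_indices(dim)
        self.n_params = len(self.rows)

    def build_chol(self, phi):
        L = np.zeros((self.dim, self.dim))
        L[self.rows, self.cols] = phi
        idx = np.arange(self.dim)
        L[idx, idx] = np.exp(L[idx, idx])
        return L

    def chol_jacobian(self, phi):
        D = np.zeros((self.n_params, self.dim, self.dim))
        k = np.arange(self.n_params)
        coef = np.where(self.rows == self.cols, np.exp(phi), 1.0)
        D[k, self.rows, self.cols] = coef
        return D

    def initial(self, sd: float = 0.1):
        phi = np.zeros(self.n_params)
        phi[self.rows == self.cols] = np.log(sd)
        return phi

    def bounds(self):
        return [
            _LOG_DIAG_BOUNDS if r == c else _OFFDIAG_BOUNDS
            for r, c in zip(self.rows, self.cols)
        ]

    def labels(self):
        return [
            f"log_sd({self.name}{r + 1})" if r == c else f"chol({self.name}{r + 1},{self.name}{c + 1})"
            for r, c in zip(self.rows, self.cols)
        ]


class Composite(CovarianceStructure):
    """Block-diagonal combination of independent sub-structures."""

    def __init__(self, blocks: list[CovarianceStructure]):
        self.blocks = blocks
        self.dim = sum(b.dim for b in blocks)
        self.n_params = sum(b.n_params for b in blocks)
        self._dim_off = np.cumsum([0] + [b.dim for b in blocks])
        self._par_off = np.cumsum([0] + [b.n_params for b in blocks])

    def build_chol(self, phi):
        L = np.zeros((self.dim, self.dim))
        for b, d0, p0 in zip(self.blocks, self._dim_off, self._par_off):
            L[d0 : d0 + b.dim, d0 : d0 + b.dim] = b.build_chol(
                phi[p0 : p0 + b.n_params]
            )
        return L

    def chol_jacobian(self, phi):
        D = np.zeros((self.n_params, self.dim, self.dim))
        for b, d0, p0 in zip(self.blocks, self._dim_off, self._par_off):
            D[p0 : p0 + b.n_params, d0 : d0 + b.dim, d0 : d0 + b.dim] = (
                b.chol_jacobian(phi[p0 : p0 + b.n_params])
            )
        return D

    def initial(self, sd: float = 0.1):
        return np.concatenate([b.initial(sd) for b in self.blocks])

    def bounds(self):
        return [bb for b in self.blocks for bb in b.bounds()]

    def labels(self):
        return [lab for b in self.blocks for lab in b.labels()]
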