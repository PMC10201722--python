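"""Singular multivariate normal support on the sum-to-zero hyperplane.

The log-contrast model constrains its compositional coefficients to the
affine hyperplane ``{theta : sum_j theta_j = 0}``.  The conjugate prior that
respects this constraint exactly is a degenerate (rank ``k-1``) Gaussian
whose covariance is ``T diag(psi) T`` with ``T = I - J/k`` the centering
projector.  This module provides the centering matrix, pseudo-inverse /
pseudo-determinant linear algebra, and density evaluation plus sampling for
that singular normal.  Densities are taken with respect to the
``(k-1)``-dimensional Hausdorff measure on the hyperplane; every acceptance
ratio in the sampler uses the same dominating measure so the convention
cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "centering_matrix",
    "pseudo_inverse_and_logpdet",
    "SMVNParams",
    "smvn_logpdf",
    "smvn_sample",
    "EigenGaussian",
    "eigen_gaussian",
]

#: relative eigenvalue cutoff below which a mode is treated as null.
#: T's null space is exact in theory; only rounding perturbs it.
DEFAULT_TOL = 1e-10


def centering_matrix(k: int) -> np.ndarray:
    """Return the ``k x k`` centering projector ``T = I - J/k``.

    ``T`` is symmetric, idempotent, of rank ``k - 1``, and annihilates the
    constant vector, so ``T x`` is ``x`` recentred to sum to zero.
    """
    if k < 2:
        raise ValueError(f"centering matrix requires k >= 2, got k={k}")
    return np.eye(k) - np.full((k, k), 1.0 / k)


def pseudo_inverse_and_logpdet(
    M: np.ndarray, tol: float = DEFAULT_TOL
) -> tuple[np.ndarray, float, int]:
    """Moore-Penrose pseudo-inverse, log pseudo-determinant and rank of a PSD matrix.

    The pseudo-determinant is the product of the eigenvalues retained after
    discarding those below ``tol`` times the largest eigenvalue.

    Returns
    -------
    (pinv, log_pdet, rank)
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("M must be symmetric")
    w, U = np.linalg.eigh((M + M.T) / 2.0)
    scale = max(w[-1], 0.0)
    cutoff = tol * scale
    if np.any(w < -max(cutoff, tol)):
        raise ValueError(f"matrix is not positive semi-definite (min eigenvalue {w[0]:.3e})")
    keep = w > cutoff
    rank = int(keep.sum())
    if rank == 0:
        return np.zeros_like(M), 0.0, 0
    Uk = U[:, keep]
    wk = w[keep]
    pinv = (Uk / wk) @ Uk.T
    return pinv, float(np.sum(np.log(wk))), rank


@dataclass
class SMVNParams:
    """Parameters of ``SMVN(T mu, T diag(psi) T)`` on the zero-sum hyperplane."""

    mean: np.ndarray          # pre-projection location mu (length k)
    scales: np.ndarray        # positive per-coordinate scales psi (length k)
    T: np.ndarray = field(init=False)
    cov_pinv: np.ndarray = field(init=False)
    log_pdet: float = field(init=False)
    rank: int = field(init=False)
    _eig_vals: np.ndarray = field(init=False, repr=False)
    _eig_vecs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        k = self.mean.shape[0]
        if self.scales.shape != (k,):
            raise ValueError("mean and scales must have the same length")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be strictly positive")
        self.T = centering_matrix(k)
        cov = self.T @ np.diag(self.scales) @ self.T
        w, U = np.linalg.eigh((cov + cov.T) / 2.0)
        keep = w > DEFAULT_TOL * w[-1]
        self._eig_vals = w[keep]
        self._eig_vecs = U[:, keep]
        self.rank = int(keep.sum())
        self.cov_pinv = (self._eig_vecs / self._eig_vals) @ self._eig_vecs.T
        self.log_pdet = float(np.sum(np.log(self._eig_vals)))

    @property
    def k(self) -> int:
        return self.mean.shape[0]

    @property
    def projected_mean(self) -> np.ndarray:
        return self.T @ self.mean


def smvn_logpdf(theta: np.ndarray, params: SMVNParams, support_tol: float = 1e-8) -> float:
    """Log density of the singular normal at ``theta``.

    Off the hyperplane (``|sum theta_j| > support_tol``) the density is zero
    and ``-inf`` is returned rather than raising, so samplers that evaluate
    candidate states reject instead of crashing.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (params.k,):
        raise ValueError(f"theta must have length {params.k}")
    if abs(theta.sum()) > support_tol:
        return -np.inf
    resid = theta - params.projected_mean
    quad = resid @ params.cov_pinv @ resid
    return float(-0.5 * (params.rank * np.log(2.0 * np.pi) + params.log_pdet) - 0.5 * quad)


def smvn_sample(params: SMVNParams, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Draw from the singular normal by rotating ``k-1`` standard normals.

    Independent standard normals are scaled by the square roots of the
    nonzero eigenvalues of ``T diag(psi) T``, rotated back into the ambient
    space and shifted by ``T mu``; every draw sums to zero exactly up to
    rounding.
    """
    n = 1 if size is None else int(size)
    z = rng.standard_normal((n, params.rank))
    draws = params.projected_mean + (z * np.sqrt(params._eig_vals)) @ params._eig_vecs.T
    return draws[0] if size is None else draws


@dataclass
class EigenGaussian:
    """A (possibly singular) Gaussian held in eigen-factored form.

    Used by the sampler for the exact conditional of theta on the active
    set: ``N(mean, cov)`` with ``cov = U diag(vals)^{-1} U^T`` built from the
    retained eigenpairs of the restricted precision.  ``log_pdet_prec`` is
    the log pseudo-determinant of that precision.
    """

    mean: np.ndarray
    vecs: np.ndarray          # k x r eigenvectors of the precision
    prec_vals: np.ndarray     # r retained precision eigenvalues
    log_pdet_prec: float

    @property
    def rank(self) -> int:
        return self.prec_vals.shape[0]

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.rank)
        return self.mean + self.vecs @ (z / np.sqrt(self.prec_vals))

    @property
    def cov(self) -> np.ndarray:
        return (self.vecs / self.prec_vals) @ self.vecs.T

    @property
    def cov_diag(self) -> np.ndarray:
        return np.einsum("ij,j,ij->i", self.vecs, 1.0 / self.prec_vals, self.vecs)


def eigen_gaussian(precision: np.ndarray, lin: np.ndarray, tol: float = DEFAULT_TOL) -> EigenGaussian:
    """Exact Gaussian with density ``exp(-theta' P theta / 2 + lin' theta)``
    restricted to the row space of the (possibly singular) precision ``P``.

    The mean solves ``P m = proj(lin)`` on the retained eigenspace.
    """
    w, U = np.linalg.eigh((precision + precision.T) / 2.0)
    keep = w > tol * max(w[-1], tol)
    wk, Uk = w[keep], U[:, keep]
    mean = Uk @ ((Uk.T @ lin) / wk)
    return EigenGaussian(mean=mean, vecs=Uk, prec_vals=wk, log_pdet_prec=float(np.sum(np.log(wk))))
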