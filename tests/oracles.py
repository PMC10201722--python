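"""Independent oracles shared by the test suite.

These deliberately avoid the package's own code paths wherever the point is
to cross-check one: the batched collapsed-target evaluator below recomputes
the target from its definition (prior times likelihood, theta integrated on
the hyperplane) with its own linear algebra, and the quadrature masses use
tensor-product Gauss-Legendre rules in log-psi space.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def batched_collapsed_log_target(cfg, psi_batch, ctx):
    """Collapsed log target for a fixed configuration over a batch of psi.

    ``cfg`` is a tuple of active indices; ``psi_batch`` is (N, k).
    Independent re-derivation: prior precision = pinv(T D T), likelihood
    precision = s Z'Z, Gaussian integral on the zero-sum hyperplane.
    """
    k = len(cfg)
    a = np.array(cfg)
    T = np.eye(k) - 1.0 / k
    D = psi_batch[:, :, None] * np.eye(k)
    TDT = T @ D @ T
    w, U = np.linalg.eigh(TDT)
    keep = w > 1e-12 * w[..., -1:]
    wsafe = np.where(keep, w, 1.0)
    logdet_prior = np.where(keep, np.log(wsafe), 0.0).sum(-1)
    P = np.einsum("nij,nj,nkj->nik", U, np.where(keep, 1.0 / wsafe, 0.0), U)
    Gaa = ctx.G[np.ix_(a, a)]
    A = P + ctx.inv_sigma2 * (T @ Gaa @ T)
    wA, UA = np.linalg.eigh(A)
    keepA = wA > 1e-12 * wA[..., -1:]
    wAs = np.where(keepA, wA, 1.0)
    logdetA = np.where(keepA, np.log(wAs), 0.0).sum(-1)
    lin = T @ (ctx.inv_sigma2 * ctx.c[a])
    proj = np.einsum("nij,i->nj", UA, lin)
    quad = 0.5 * np.einsum("nj,nj->n", proj**2, np.where(keepA, 1.0 / wAs, 0.0))
    prior = k * (ctx.log_kappa + ctx.a_psi * ctx.e_log_bpsi - gammaln(ctx.a_psi))
    prior = prior - (ctx.a_psi + 1.0) * np.log(psi_batch).sum(-1)
    prior = prior - ctx.e_bpsi * (1.0 / psi_batch).sum(-1)
    return (quad - 0.5 * logdetA - 0.5 * logdet_prior + prior
            + ctx.log_1mkappa * (ctx.d - k))


def config_log_mass(cfg, ctx, nodes: int = 64, lim: float = 8.0) -> float:
    """log integral of the collapsed target over psi for one configuration,
    by tensor-product Gauss-Legendre quadrature in log-psi space."""
    k = len(cfg)
    if k == 0:
        return float(ctx.log_1mkappa * ctx.d)
    x, wq = np.polynomial.legendre.leggauss(nodes)
    u, wu = lim * x, lim * wq
    grids = np.meshgrid(*([u] * k), indexing="ij")
    U = np.stack([g.ravel() for g in grids], axis=-1)
    logw = np.zeros(U.shape[0])
    for i in range(k):
        logw += np.log(np.meshgrid(*([wu] * k), indexing="ij")[i].ravel())
    lt = batched_collapsed_log_target(cfg, np.exp(U), ctx) + U.sum(-1) + logw
    m = lt.max()
    return float(m + np.log(np.sum(np.exp(lt - m))))


def config_quadrature_expectation(cfg, ctx, func, nodes: int = 64, lim: float = 8.0) -> float:
    """E[func(psi)] under the normalised restriction of the collapsed target
    to one configuration (func maps (N, k) -> (N,))."""
    k = len(cfg)
    x, wq = np.polynomial.legendre.leggauss(nodes)
    u, wu = lim * x, lim * wq
    grids = np.meshgrid(*([u] * k), indexing="ij")
    U = np.stack([g.ravel() for g in grids], axis=-1)
    logw = np.zeros(U.shape[0])
    for i in range(k):
        logw += np.log(np.meshgrid(*([wu] * k), indexing="ij")[i].ravel())
    psi = np.exp(U)
    lt = batched_collapsed_log_target(cfg, psi, ctx) + U.sum(-1) + logw
    m = lt.max()
    wts = np.exp(lt - m)
    return float(np.sum(wts * func(psi)) / np.sum(wts))


def batch_means_se(indicator: np.ndarray, n_batches: int = 100) -> float:
    """Monte Carlo standard error of a chain average via batch means."""
    indicator = np.asarray(indicator, dtype=float)
    L = indicator.size // n_batches
    if L < 1:
        raise ValueError("chain too short for the requested batch count")
    means = indicator[: n_batches * L].reshape(n_batches, L).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def constrained_gls_mode(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Lagrange-multiplier (KKT) solution of min 1/2 x'Ax - b'x  s.t. sum x = 0."""
    k = A.shape[0]
    K = np.block([[A, np.ones((k, 1))], [np.ones((1, k)), np.zeros((1, 1))]])
    sol = np.linalg.solve(K, np.concatenate([b, [0.0]]))
    return sol[:k]
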