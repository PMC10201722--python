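"""Auxiliary unconstrained model supplying data-informed MCMC proposals.

The compositional block (theta, psi, xi) has no conjugate variational
update, so the sampler that handles it needs proposal distributions.  These
are built from a surrogate *unconstrained* model in which each taxon gets an
independent spike-and-slab triple (Omega_j, Delta_j, Upsilon_j): Omega_j is
an unconstrained stand-in for theta_j with slab variance Delta_j and
inclusion indicator Upsilon_j ~ Bern(kappa).  All of its variational updates
are closed-form, and the fitted inverse-gamma pseudo-posterior
q(Delta_j | Upsilon_j = 1) becomes the proposal for psi_j when taxon j is
born in the reversible-jump move.  Conditional (not marginal) expectations
are used throughout so proposal parameters are never shrunk by the
inclusion probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, expit, gammaln

__all__ = [
    "AuxiliaryState",
    "init_auxiliary",
    "update_omega_upsilon",
    "update_delta",
    "aux_sweep",
    "psi_proposal",
    "invgamma_logpdf",
]


@dataclass
class AuxiliaryState:
    """Free parameters of the pseudo variational posteriors, one per taxon."""

    omega_mean: np.ndarray    # mu_Omega_j
    omega_var: np.ndarray     # sigma^2_Omega_j
    upsilon_prob: np.ndarray  # (Upsilon_j)^(1)
    delta_shape: np.ndarray   # a*_Delta_j = 1/2 + a_psi, fixed by conjugacy
    delta_rate: np.ndarray    # b*_Delta_j

    @property
    def d(self) -> int:
        return self.omega_mean.shape[0]

    def e_inv_delta(self, j: int | slice = slice(None)) -> np.ndarray:
        """E_q[Delta_j^{-1} | Upsilon_j = 1]."""
        return self.delta_shape[j] / self.delta_rate[j]

    def e_log_delta(self, j: int | slice = slice(None)) -> np.ndarray:
        """E_q[log Delta_j | Upsilon_j = 1]."""
        return np.log(self.delta_rate[j]) - digamma(self.delta_shape[j])

    def marginal_omega(self) -> np.ndarray:
        """Shrunken marginal mean (Omega_j)^(1) = (Upsilon_j)^(1) mu_Omega_j."""
        return self.upsilon_prob * self.omega_mean


def init_auxiliary(d: int, a_psi: float, e_bpsi: float, kappa_mean: float,
                   z_norm_sq: np.ndarray, inv_sigma2: float) -> AuxiliaryState:
    shape = np.full(d, 0.5 + a_psi)
    rate = np.full(d, float(e_bpsi) * (0.5 + a_psi) / a_psi)  # match prior E[Delta^-1]
    var = 1.0 / (z_norm_sq * inv_sigma2 + shape / rate)
    return AuxiliaryState(
        omega_mean=np.zeros(d),
        omega_var=var,
        upsilon_prob=np.full(d, float(np.clip(kappa_mean, 1e-6, 1 - 1e-6))),
        delta_shape=shape,
        delta_rate=rate,
    )


def update_omega_upsilon(
    aux: AuxiliaryState,
    j: int,
    Z: np.ndarray,
    base_resid: np.ndarray,
    omega_fit: np.ndarray,
    inv_sigma2: float,
    log_kappa: float,
    log_1mkappa: float,
    a_delta: float,
    b_delta: float,
) -> np.ndarray:
    """Coordinate update of (mu_Omega_j, sigma2_Omega_j, (Upsilon_j)^(1)).

    ``base_resid`` is the response with the intercept and unconstrained
    covariate fits removed; ``omega_fit`` is the running fit
    ``Z @ (upsilon * mu_Omega)`` and is updated in place so subsequent
    coordinates see the new value.
    """
    zj = Z[:, j]
    znorm = float(zj @ zj)
    if znorm <= 0:
        raise ValueError(f"zero-norm compositional column {j}")
    old_contrib = aux.upsilon_prob[j] * aux.omega_mean[j]
    resid = base_resid - (omega_fit - old_contrib * zj)

    e_inv = float(aux.e_inv_delta(j))
    e_log = float(aux.e_log_delta(j))
    var = 1.0 / (znorm * inv_sigma2 + e_inv)
    mean = var * inv_sigma2 * float(zj @ resid)

    # printed logistic form of the pseudo inclusion probability
    x = (
        -0.5 * np.log(var)
        + log_1mkappa
        - log_kappa
        + gammaln(a_delta)
        + 0.5 * e_log
        - 0.5 * mean**2 / var
        + (a_delta + 1.0) * e_log
        + b_delta * e_inv
        - a_delta * np.log(b_delta)
    )
    prob = float(expit(-x))

    aux.omega_mean[j] = mean
    aux.omega_var[j] = var
    aux.upsilon_prob[j] = prob
    omega_fit += (prob * mean - old_contrib) * zj
    return omega_fit


def update_delta(aux: AuxiliaryState, j: int, a_psi: float, e_bpsi: float) -> None:
    """Conjugate IG pseudo-posterior for Delta_j given Upsilon_j = 1.

    The shape is 1/2 + a_psi regardless of data; the rate uses the
    *conditional* second moment sigma2_Omega + mu_Omega^2 so the proposal is
    never shrunk by the inclusion probability.
    """
    aux.delta_shape[j] = 0.5 + a_psi
    aux.delta_rate[j] = 0.5 * (aux.omega_var[j] + aux.omega_mean[j] ** 2) + e_bpsi


def aux_sweep(
    aux: AuxiliaryState,
    Z: np.ndarray,
    base_resid: np.ndarray,
    inv_sigma2: float,
    log_kappa: float,
    log_1mkappa: float,
    a_psi: float,
    e_bpsi: float,
) -> None:
    """One full pass: all (Omega_j, Upsilon_j) updates, then all Delta_j updates."""
    omega_fit = Z @ aux.marginal_omega()
    for j in range(aux.d):
        omega_fit = update_omega_upsilon(
            aux, j, Z, base_resid, omega_fit, inv_sigma2,
            log_kappa, log_1mkappa, a_psi, e_bpsi,
        )
    for j in range(aux.d):
        update_delta(aux, j, a_psi, e_bpsi)


def psi_proposal(aux: AuxiliaryState, j: int, rng: np.random.Generator) -> tuple[float, float]:
    """Draw psi_j from IG(a*_Delta_j, b*_Delta_j); return (draw, log proposal density)."""
    a, b = float(aux.delta_shape[j]), float(aux.delta_rate[j])
    draw = 1.0 / rng.gamma(a, 1.0 / b)
    return draw, invgamma_logpdf(draw, a, b)


def invgamma_logpdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -np.inf
    return float(shape * np.log(rate) - gammaln(shape) - (shape + 1.0) * np.log(x) - rate / x)
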