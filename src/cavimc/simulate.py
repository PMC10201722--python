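"""Logistic-normal simulation of compositional regression data.

Latent abundances ``O`` are drawn rowwise from ``N(mu_o, Sigma_o)`` and
pushed through the scaled closure ``q_ij = exp(tau o_ij) / sum_k
exp(tau o_ik)``, giving logistic-normal compositions whose parts differ by
orders of magnitude when some ``mu_o`` components are raised — mimicking
taxon abundance tables.  The response follows the log-contrast model
``y = Z theta + eps`` with ``Z = log Q`` and noise calibrated to a target
signal-to-noise ratio ``SNR = mean(|theta_nonzero|) / sigma``.

Defaults reproduce the benchmark design: ``tau = 2``; ``mu_oj = log(0.5 d)``
for the first five taxa and 0 otherwise; six associated taxa with
coefficients ``(1, -1.5, 0.5, -1, 1.5, -0.5)`` on positions 1-3 and 6-8
(1-based), which collapses to a three-term all-pairs log-ratio model
``y = sum_p theta_p log(q_p / q_{p+5}) + eps`` over the pairs (1,6), (2,7),
(3,8); an AR(1) correlation ``rho^|i-j|`` for the latent field; a held-out
test set of 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._design import DesignBundle

__all__ = ["SimulationSpec", "simulate_dataset", "snr_to_sigma", "default_theta"]

# paired so the model collapses exactly to a three-term all-pairs
# log-ratio form: y = sum_p theta_p log(q_p / q_{p+5}) over p in {1,2,3}
_THETA_VALUES = (1.0, -1.5, 0.5, -1.0, 1.5, -0.5)
_THETA_SUPPORT = (0, 1, 2, 5, 6, 7)  # 0-based: taxa 1-3 and 6-8


def default_theta(d: int) -> np.ndarray:
    """The benchmark coefficient vector: 6 associated taxa, zero-sum by design."""
    if d < 8:
        raise ValueError("default coefficient layout needs d >= 8")
    theta = np.zeros(d)
    theta[list(_THETA_SUPPORT)] = _THETA_VALUES
    return theta


def snr_to_sigma(theta_true: np.ndarray, snr: float) -> float:
    """Noise standard deviation implied by ``SNR = mean(|theta_nonzero|) / sigma``."""
    theta_true = np.asarray(theta_true, dtype=float)
    nz = theta_true[theta_true != 0]
    if nz.size == 0:
        raise ValueError("theta_true has no nonzero coefficients")
    if snr <= 0:
        raise ValueError("snr must be positive")
    return float(np.mean(np.abs(nz)) / snr)


@dataclass
class SimulationSpec:
    """Parameters of one simulated dataset."""

    n: int = 100
    d: int = 45
    tau: float = 2.0
    rho: float = 0.0
    snr: float = 2.5
    n_test: int = 5
    mu_o: np.ndarray | None = None
    theta_true: np.ndarray | None = None
    n_large: int = 5          # taxa with raised latent mean log(0.5 d)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.n_test < 1:
            raise ValueError("n_test must be at least 1")
        if self.mu_o is None:
            mu = np.zeros(self.d)
            mu[: self.n_large] = np.log(self.d * 0.5)
            self.mu_o = mu
        else:
            self.mu_o = np.asarray(self.mu_o, dtype=float)
        if self.theta_true is None:
            self.theta_true = default_theta(self.d)
        else:
            self.theta_true = np.asarray(self.theta_true, dtype=float)
        if abs(self.theta_true.sum()) > 1e-8:
            raise ValueError("theta_true must sum to zero")

    @property
    def sigma(self) -> float:
        return snr_to_sigma(self.theta_true, self.snr)


def _ar1_cov(d: int, rho: float) -> np.ndarray:
    if rho == 0.0:
        return np.eye(d)
    idx = np.arange(d)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _draw_block(spec: SimulationSpec, n: int, rng: np.random.Generator,
                chol: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    O = spec.mu_o + rng.standard_normal((n, spec.d)) @ chol.T
    A = spec.tau * O
    A -= A.max(axis=1, keepdims=True)
    E = np.exp(A)
    Q = E / E.sum(axis=1, keepdims=True)
    Z = np.log(Q)
    y = Z @ spec.theta_true + spec.sigma * rng.standard_normal(n)
    return Q, Z, y


def simulate_dataset(
    spec: SimulationSpec, rng: np.random.Generator | int = 0
) -> tuple[DesignBundle, np.ndarray, dict]:
    """Generate one training bundle plus an identically distributed test split.

    Returns ``(bundle, theta_true, test)`` where ``test`` holds ``Z_test``
    and ``y_test`` (and the noise-free ``mu_test``) for prediction-error
    evaluation.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chol = np.linalg.cholesky(_ar1_cov(spec.d, spec.rho))
    _, Z, y = _draw_block(spec, spec.n, rng, chol)
    _, Z_test, y_test = _draw_block(spec, spec.n_test, rng, chol)
    bundle = DesignBundle(y=y, Z=Z)
    test = {
        "Z": Z_test,
        "y": y_test,
        "mu": Z_test @ spec.theta_true,
    }
    return bundle, spec.theta_true.copy(), test
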