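"""Hyperparameter container for the hierarchical log-contrast model.

Defaults are weakly-informative conjugate choices.  Sparsity of the
compositional block is set through ``d_star``, the prior expected number of
selected taxa, which fixes the beta prior on the inclusion rate kappa as
``a_kappa = 1``, ``b_kappa = (d - d_star) / d``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ModelHyperparams:
    # slab scale psi_j | xi_j=1 ~ IG(a_psi, b_psi), b_psi ~ Gamma(shape, rate)
    a_psi: float = 2.0
    bpsi_shape: float = 0.01
    bpsi_rate: float = 0.01
    # taxon inclusion rate kappa ~ Beta(a_kappa, b_kappa(d))
    d_star: float = 6.0
    a_kappa: float = 1.0
    b_kappa: float | None = None   # derived from d_star unless given
    # unconstrained continuous block: beta | gamma=1 ~ N(0, w), gamma ~ Bern(omega)
    a_omega: float = 1.0
    b_omega: float = 1.0
    a_w: float = 0.01
    w_rate_shape: float = 0.01
    w_rate_rate: float = 0.01
    # grouped categorical block: zeta_g | chi_g=1 ~ N(0, v I), chi_g ~ Bern(varrho)
    a_varrho: float = 1.0
    b_varrho: float = 1.0
    a_v: float = 0.01
    v_rate_shape: float = 0.01
    v_rate_rate: float = 0.01
    # noise variance sigma^2 ~ IG(a_sigma, b_sigma)
    a_sigma: float = 0.01
    b_sigma: float = 0.01
    # sampler move mixture: birth-death vs swap within a between-model move,
    # and between- vs within-model choice
    phi: float = 0.5
    p_between: float = 0.5

    def __post_init__(self) -> None:
        for name in ("a_psi", "bpsi_shape", "bpsi_rate", "a_kappa", "a_omega",
                     "b_omega", "a_w", "w_rate_shape", "w_rate_rate", "a_varrho",
                     "b_varrho", "a_v", "v_rate_shape", "v_rate_rate",
                     "a_sigma", "b_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must be in (0, 1)")
        if not 0.0 < self.p_between < 1.0:
            raise ValueError("p_between must be in (0, 1)")
        if self.d_star < 0:
            raise ValueError("d_star must be nonnegative")

    def kappa_prior(self, d: int) -> tuple[float, float]:
        """(a_kappa, b_kappa) with b_kappa derived from the prior expected
        number of selected taxa when not set explicitly."""
        if self.d_star >= d:
            raise ValueError("d_star must be smaller than the number of taxa")
        b = self.b_kappa if self.b_kappa is not None else (d - self.d_star) / d
        return self.a_kappa, float(b)

    # auxiliary-model IG parameters are tied to the slab prior
    @property
    def a_delta(self) -> float:
        return self.a_psi
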