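import numpy as np
import pytest

from cavimc.sampler import PhaseContext


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_toy_ctx(seed=3, n=12, d=3, theta=(0.5, -0.5, 0.0), sigma=1.0,
                 kappa=0.35, a_psi=2.0, e_bpsi=1.0):
    """Small frozen-analytic-block context for sampler tests."""
    r = np.random.default_rng(seed)
    Z = r.normal(size=(n, d))
    y = Z @ np.asarray(theta, dtype=float) + sigma * r.normal(size=n)
    return PhaseContext(
        Z=Z, G=Z.T @ Z, c=Z.T @ y,
        z_norm_sq=np.einsum("ij,ij->j", Z, Z),
        inv_sigma2=1.0 / sigma**2,
        log_kappa=float(np.log(kappa)), log_1mkappa=float(np.log1p(-kappa)),
        a_psi=a_psi, e_log_bpsi=float(np.log(e_bpsi)), e_bpsi=e_bpsi,
    ), y


@pytest.fixture
def toy_ctx():
    return make_toy_ctx()
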