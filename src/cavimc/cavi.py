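"""Coordinate-ascent variational inference engine.

All unconstrained blocks of the hierarchical log-contrast model have
conjugate variational updates: Gaussian for the intercept, spike-and-slab
Gaussian for the continuous coefficients and for the grouped categorical
coefficient vectors, inverse-gamma for the variances, beta for the
inclusion rates and gamma for the rate hyperparameters.  The compositional
block (theta, psi, xi) is handled by the embedded sampler
(:mod:`cavimc.sampler`); its Monte Carlo expectations enter the analytic
updates and the evidence lower bound as plug-in averages.

The reported ELBO omits the intractable entropy of the sampled block (a
constant while that block's samples are fixed), so it is exact up to an
additive term and is used for differences and convergence monitoring only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, expit, gammaln

from . import sampler as mc
from ._design import DesignBundle
from .auxiliary import AuxiliaryState, aux_sweep, init_auxiliary
from .priors import ModelHyperparams

__all__ = [
    "VariationalState",
    "Schedule",
    "FitResult",
    "init_state",
    "update_beta_gamma",
    "update_zeta_chi",
    "update_remaining_blocks",
    "expected_residual_sq",
    "compute_elbo",
    "fit_cavi_mc",
    "select_variables",
]


@dataclass
class Schedule:
    """Iteration schedule of the outer loop.

    The sampler starts with ``mcmc_init`` iterations per phase and escalates
    to ``mcmc_main`` after ``escalate_after`` variational sweeps, once the
    free parameters have stabilised enough for longer chains to pay off.
    """

    vi_iters: int = 25
    mcmc_init: int = 5000
    mcmc_main: int = 10000
    escalate_after: int = 5
    burn_in_frac: float = 0.2
    aux_sweeps: int = 1
    elbo_rel_tol: float = 1e-3
    elbo_window: int = 3


@dataclass
class VariationalState:
    """Free parameters of every analytic q factor."""

    # intercept (flat prior)
    alpha_mean: float
    alpha_var: float
    # noise variance, q(sigma^2) = IG(sig_shape, sig_rate)
    sig_shape: float
    sig_rate: float
    # continuous covariates
    beta_mean: np.ndarray
    beta_var: np.ndarray
    gamma_prob: np.ndarray
    # categorical groups
    zeta_mean: list
    zeta_cov: list
    chi_prob: np.ndarray
    # beta factors
    omega_ab: tuple
    varrho_ab: tuple
    kappa_ab: tuple
    # variance factors, IG(shape, rate), with gamma rate hyperpriors
    w_ig: tuple
    lw_gamma: tuple
    v_ig: tuple
    lv_gamma: tuple
    # gamma factor for b_psi
    bpsi_gamma: tuple

    # ---- q expectations -------------------------------------------------
    @property
    def inv_sigma2(self) -> float:
        return self.sig_shape / self.sig_rate

    @property
    def e_log_sigma2(self) -> float:
        return float(np.log(self.sig_rate) - digamma(self.sig_shape))

    @property
    def beta_marginal(self) -> np.ndarray:
        return self.gamma_prob * self.beta_mean

    def zeta_marginal(self) -> list:
        return [p * m for p, m in zip(self.chi_prob, self.zeta_mean)]

    @staticmethod
    def _e_log_beta(ab: tuple) -> tuple[float, float]:
        a, b = ab
        tot = digamma(a + b)
        return float(digamma(a) - tot), float(digamma(b) - tot)

    @property
    def e_log_kappa(self) -> tuple[float, float]:
        return self._e_log_beta(self.kappa_ab)

    @property
    def e_bpsi(self) -> float:
        return self.bpsi_gamma[0] / self.bpsi_gamma[1]

    @property
    def e_log_bpsi(self) -> float:
        return float(digamma(self.bpsi_gamma[0]) - np.log(self.bpsi_gamma[1]))

    @staticmethod
    def ig_moments(ig: tuple) -> tuple[float, float]:
        """(E[x^-1], E[log x^-1]) for q(x) = IG(shape, rate)."""
        a, b = ig
        return a / b, float(digamma(a) - np.log(b))


def init_state(
    bundle: DesignBundle, hyper: ModelHyperparams, rng: np.random.Generator
) -> VariationalState:
    """Randomised initial free parameters.

    Random restarts jitter data-scaled starting points: the noise variance
    around a ridge-fit residual variance, unit-scale slab variances and
    b_psi, and inclusion probabilities around their prior means.  (Draws
    straight from the diffuse IG/gamma hyperpriors span tens of orders of
    magnitude and destabilise the first sweep; seeding sigma^2 at the raw
    response variance starves the proposal guidance of signal until the
    compositional block catches up.)
    """
    n, s, G, d = bundle.n, bundle.s, bundle.G, bundle.d
    y = bundle.y
    var_y = max(float(np.var(y)), 1e-12)

    def jitter() -> float:
        return float(np.exp(rng.uniform(-1.0, 1.0)))

    sig0 = var_y
    if d and n >= 8:
        # cross-fit ridge noise estimate: fit on one half of the samples,
        # take the residual variance on the other half (in-sample residuals
        # near-interpolate when d >= n and would start sigma^2 at ~0)
        Zc = bundle.Z - bundle.Z.mean(axis=0)
        yc = y - y.mean()
        a, b = np.arange(0, n, 2), np.arange(1, n, 2)
        est = []
        for tr, te in ((a, b), (b, a)):
            coef = np.linalg.solve(Zc[tr].T @ Zc[tr] + np.eye(d), Zc[tr].T @ yc[tr])
            r = yc[te] - Zc[te] @ coef
            est.append(float(r @ r / te.size))
        sig0 = min(max(float(np.mean(est)), 1e-10), var_y)
    sig0 *= float(np.exp(rng.uniform(-0.5, 0.5)))
    sig_shape = hyper.a_sigma + n / 2.0
    sig_rate = sig_shape * sig0

    a_k, b_k = hyper.kappa_prior(d) if d else (1.0, 1.0)
    kappa0 = float(np.clip((hyper.d_star / d if d else 0.5) * jitter(), 1e-4, 0.5))

    state = VariationalState(
        alpha_mean=float(np.mean(y)) + rng.normal(scale=0.1 * np.sqrt(var_y)),
        alpha_var=sig0 / n,
        sig_shape=sig_shape,
        sig_rate=sig_rate,
        beta_mean=rng.normal(scale=0.1, size=s),
        beta_var=np.full(s, 1.0),
        gamma_prob=rng.uniform(0.2, 0.8, size=s),
        zeta_mean=[rng.normal(scale=0.1, size=m) for m in bundle.group_sizes],
        zeta_cov=[np.eye(m) for m in bundle.group_sizes],
        chi_prob=rng.uniform(0.2, 0.8, size=G),
        omega_ab=(hyper.a_omega, hyper.b_omega),
        varrho_ab=(hyper.a_varrho, hyper.b_varrho),
        kappa_ab=(1.0 + 50.0 * kappa0, 1.0 + 50.0 * (1.0 - kappa0)),
        w_ig=(hyper.a_w + 1.0, (hyper.a_w + 1.0) * jitter()),
        lw_gamma=(hyper.w_rate_shape + hyper.a_w, hyper.w_rate_rate + 1.0),
        v_ig=(hyper.a_v + 1.0, (hyper.a_v + 1.0) * jitter()),
        lv_gamma=(hyper.v_rate_shape + hyper.a_v, hyper.v_rate_rate + 1.0),
        bpsi_gamma=(1.0, 1.0 / jitter()),
    )
    # keep a record of the derived kappa prior for the updates
    state._kappa_prior = (a_k, b_k)
    return state


# ---------------------------------------------------------------------------
# residual bookkeeping

def _fitted_parts(state: VariationalState, bundle: DesignBundle,
                  exps: mc.MCExpectations) -> dict:
    Xb = bundle.X @ state.beta_marginal if bundle.s else np.zeros(bundle.n)
    if bundle.G:
        zeta_full = np.concatenate(state.zeta_marginal())
        Wz = bundle.W @ zeta_full
    else:
        Wz = np.zeros(bundle.n)
    Zt = bundle.Z @ exps.mu_theta_marginal if bundle.d else np.zeros(bundle.n)
    return {"Xb": Xb, "Wz": Wz, "Zt": Zt}


def expected_residual_sq(state: VariationalState, bundle: DesignBundle,
                         exps: mc.MCExpectations) -> float:
    """E_q || y - alpha - X beta - W zeta - Z theta ||^2."""
    parts = _fitted_parts(state, bundle, exps)
    rbar = bundle.y - state.alpha_mean - parts["Xb"] - parts["Wz"] - parts["Zt"]
    val = float(rbar @ rbar) + bundle.n * state.alpha_var
    if bundle.s:
        e_b2 = state.gamma_prob * (state.beta_mean**2 + state.beta_var)
        var_b = e_b2 - state.beta_marginal**2
        col_norms = np.einsum("ij,ij->j", bundle.X, bundle.X)
        val += float(col_norms @ var_b)
    for g, sl in enumerate(bundle.group_slices()):
        Wg = bundle.W[:, sl]
        p, m, C = state.chi_prob[g], state.zeta_mean[g], state.zeta_cov[g]
        e_outer = p * (C + np.outer(m, m))
        cov = e_outer - np.outer(p * m, p * m)
        val += float(np.sum((Wg.T @ Wg) * cov))
    if bundle.d:
        Zt = parts["Zt"]
        val += exps.zt_sq_mean - float(Zt @ Zt)
    return val


# ---------------------------------------------------------------------------
# analytic updates

def update_beta_gamma(state: VariationalState, bundle: DesignBundle,
                      exps: mc.MCExpectations, s: int) -> None:
    """Joint spike-and-slab update of q(beta_s, gamma_s)."""
    Xs = bundle.X[:, s]
    norm = float(Xs @ Xs)
    if norm <= 0:
        raise ValueError(f"zero-norm continuous column {s}")
    parts = _fitted_parts(state, bundle, exps)
    partial = (bundle.y - state.alpha_mean - parts["Wz"] - parts["Zt"]
               - (parts["Xb"] - state.beta_marginal[s] * Xs))
    inv_s2 = state.inv_sigma2
    e_inv_w, e_log_inv_w = state.ig_moments(state.w_ig)
    var = 1.0 / (norm * inv_s2 + e_inv_w)
    mean = inv_s2 * var * float(Xs @ partial)
    lo, l1mo = state._e_log_beta(state.omega_ab)
    x = l1mo - lo - 0.5 * (e_log_inv_w + mean**2 / var + np.log(var))
    state.beta_mean[s] = mean
    state.beta_var[s] = var
    state.gamma_prob[s] = float(expit(-x))


def update_zeta_chi(state: VariationalState, bundle: DesignBundle,
                    exps: mc.MCExpectations, g: int) -> None:
    """Multivariate spike-and-slab update of q(zeta_g, chi_g)."""
    sl = bundle.group_slices()[g]
    Wg = bundle.W[:, sl]
    m_g = Wg.shape[1]
    parts = _fitted_parts(state, bundle, exps)
    own = Wg @ (state.chi_prob[g] * state.zeta_mean[g])
    partial = (bundle.y - state.alpha_mean - parts["Xb"] - parts["Zt"]
               - (parts["Wz"] - own))
    inv_s2 = state.inv_sigma2
    e_inv_v, e_log_inv_v = state.ig_moments(state.v_ig)
    prec = inv_s2 * (Wg.T @ Wg) + e_inv_v * np.eye(m_g)
    cov = np.linalg.inv(prec)
    cov = (cov + cov.T) / 2.0
    mean = inv_s2 * cov @ (Wg.T @ partial)
    lr, l1mr = state._e_log_beta(state.varrho_ab)
    sign, logdet = np.linalg.slogdet(cov)
    x = (l1mr - lr - 0.5 * m_g * e_log_inv_v
         - 0.5 * float(mean @ prec @ mean) - 0.5 * logdet)
    state.zeta_mean[g] = mean
    state.zeta_cov[g] = cov
    state.chi_prob[g] = float(expit(-x))


def _update_alpha(state: VariationalState, bundle: DesignBundle,
                  exps: mc.MCExpectations) -> None:
    parts = _fitted_parts(state, bundle, exps)
    resid = bundle.y - parts["Xb"] - parts["Wz"] - parts["Zt"]
    state.alpha_mean = float(np.mean(resid))
    state.alpha_var = 1.0 / (bundle.n * state.inv_sigma2)


def _update_sigma2(state: VariationalState, bundle: DesignBundle,
                   exps: mc.MCExpectations, hyper: ModelHyperparams) -> None:
    state.sig_shape = hyper.a_sigma + bundle.n / 2.0
    state.sig_rate = hyper.b_sigma + 0.5 * expected_residual_sq(state, bundle, exps)


def _update_hypers(state: VariationalState, bundle: DesignBundle,
                   exps: mc.MCExpectations, hyper: ModelHyperparams) -> None:
    if bundle.s:
        sg = float(np.sum(state.gamma_prob))
        state.omega_ab = (hyper.a_omega + sg, hyper.b_omega + bundle.s - sg)
        e_b2_slab = state.beta_mean**2 + state.beta_var
        e_lw = state.lw_gamma[0] / state.lw_gamma[1]
        state.w_ig = (hyper.a_w + 0.5 * sg,
                      e_lw + 0.5 * float(state.gamma_prob @ e_b2_slab))
        e_inv_w, _ = state.ig_moments(state.w_ig)
        state.lw_gamma = (hyper.w_rate_shape + hyper.a_w,
                          hyper.w_rate_rate + e_inv_w)
    if bundle.G:
        sc = float(np.sum(state.chi_prob))
        state.varrho_ab = (hyper.a_varrho + sc, hyper.b_varrho + bundle.G - sc)
        quad = sum(
            p * (float(np.trace(C)) + float(m @ m))
            for p, m, C in zip(state.chi_prob, state.zeta_mean, state.zeta_cov)
        )
        msum = float(np.dot(state.chi_prob, bundle.group_sizes))
        e_lv = state.lv_gamma[0] / state.lv_gamma[1]
        state.v_ig = (hyper.a_v + 0.5 * msum, e_lv + 0.5 * quad)
        e_inv_v, _ = state.ig_moments(state.v_ig)
        state.lv_gamma = (hyper.v_rate_shape + hyper.a_v,
                          hyper.v_rate_rate + e_inv_v)
    if bundle.d:
        a_k, b_k = state._kappa_prior
        sx = float(np.sum(exps.incl_freq))
        state.kappa_ab = (a_k + sx, b_k + bundle.d - sx)
        state.bpsi_gamma = (
            hyper.bpsi_shape + hyper.a_psi * sx,
            hyper.bpsi_rate + float(np.sum(exps.marg_inv_psi)),
        )


def update_remaining_blocks(state: VariationalState, bundle: DesignBundle,
                            exps: mc.MCExpectations, hyper: ModelHyperparams) -> None:
    """Conjugate updates for the intercept, noise variance and hyperparameters."""
    _update_alpha(state, bundle, exps)
    _update_sigma2(state, bundle, exps, hyper)
    _update_hypers(state, bundle, exps, hyper)


def analytic_sweep(state: VariationalState, bundle: DesignBundle,
                   exps: mc.MCExpectations, hyper: ModelHyperparams) -> None:
    """One full pass in dependency order: alpha, sigma^2, beta/gamma, zeta/chi, hypers."""
    _update_alpha(state, bundle, exps)
    _update_sigma2(state, bundle, exps, hyper)
    for s in range(bundle.s):
        update_beta_gamma(state, bundle, exps, s)
    for g in range(bundle.G):
        update_zeta_chi(state, bundle, exps, g)
    _update_hypers(state, bundle, exps, hyper)


# ---------------------------------------------------------------------------
# evidence lower bound

def _xlogx(p: float) -> float:
    return p * np.log(p) if p > 0 else 0.0


def _beta_term(prior: tuple, q_ab: tuple) -> float:
    """E_q[log p] - E_q[log q] for beta prior/posterior on the same variable."""
    a0, b0 = prior
    a, b = q_ab
    el = float(digamma(a) - digamma(a + b))
    e1l = float(digamma(b) - digamma(a + b))
    lp = (a0 - 1) * el + (b0 - 1) * e1l - betaln(a0, b0)
    lq = (a - 1) * el + (b - 1) * e1l - betaln(a, b)
    return float(lp - lq)


def _gamma_term(prior: tuple, q_ab: tuple) -> float:
    """E_q[log p] - E_q[log q] for gamma (shape, rate) prior/posterior."""
    a0, b0 = prior
    a, b = q_ab
    e = a / b
    elog = digamma(a) - np.log(b)
    lp = a0 * np.log(b0) - gammaln(a0) + (a0 - 1) * elog - b0 * e
    lq = a * np.log(b) - gammaln(a) + (a - 1) * elog - b * e
    return float(lp - lq)


def _ig_term(prior: tuple, q_ab: tuple) -> float:
    """E_q[log p] - E_q[log q] for inverse-gamma (shape, rate) pairs."""
    a0, b0 = prior
    a, b = q_ab
    e_inv = a / b
    e_log = np.log(b) - digamma(a)   # E[log x]
    lp = a0 * np.log(b0) - gammaln(a0) - (a0 + 1) * e_log - b0 * e_inv
    lq = a * np.log(b) - gammaln(a) - (a + 1) * e_log - b * e_inv
    return float(lp - lq)


def compute_elbo(state: VariationalState, exps: mc.MCExpectations,
                 bundle: DesignBundle, hyper: ModelHyperparams) -> float:
    n = bundle.n
    inv_s2 = state.inv_sigma2
    elbo = (-0.5 * n * np.log(2.0 * np.pi) - 0.5 * n * state.e_log_sigma2
            - 0.5 * inv_s2 * expected_residual_sq(state, bundle, exps))
    # intercept: flat prior, Gaussian entropy
    elbo += 0.5 * np.log(2.0 * np.pi * np.e * state.alpha_var)
    # noise variance
    elbo += _ig_term((hyper.a_sigma, hyper.b_sigma), (state.sig_shape, state.sig_rate))

    if bundle.s:
        lo, l1mo = state._e_log_beta(state.omega_ab)
        e_inv_w, e_log_inv_w = state.ig_moments(state.w_ig)
        for s in range(bundle.s):
            p = state.gamma_prob[s]
            m, v = state.beta_mean[s], state.beta_var[s]
            elbo += p * (lo - 0.5 * np.log(2.0 * np.pi) + 0.5 * e_log_inv_w
                         - 0.5 * e_inv_w * (m**2 + v)) + (1 - p) * l1mo
            elbo += -_xlogx(p) - _xlogx(1 - p) + p * 0.5 * np.log(2.0 * np.pi * np.e * v)
        elbo += _beta_term((hyper.a_omega, hyper.b_omega), state.omega_ab)
        e_lw = state.lw_gamma[0] / state.lw_gamma[1]
        e_log_lw = digamma(state.lw_gamma[0]) - np.log(state.lw_gamma[1])
        e_log_w = -state.ig_moments(state.w_ig)[1]
        lp_w = (hyper.a_w * e_log_lw - gammaln(hyper.a_w)
                - (hyper.a_w + 1) * e_log_w - e_lw * e_inv_w)
        a, b = state.w_ig
        lq_w = a * np.log(b) - gammaln(a) - (a + 1) * e_log_w - b * e_inv_w
        elbo += lp_w - lq_w
        elbo += _gamma_term((hyper.w_rate_shape, hyper.w_rate_rate), state.lw_gamma)

    if bundle.G:
        lr, l1mr = state._e_log_beta(state.varrho_ab)
        e_inv_v, e_log_inv_v = state.ig_moments(state.v_ig)
        for g, m_g in enumerate(bundle.group_sizes):
            p = state.chi_prob[g]
            m, C = state.zeta_mean[g], state.zeta_cov[g]
            quad = float(np.trace(C)) + float(m @ m)
            _, logdet = np.linalg.slogdet(C)
            elbo += p * (lr - 0.5 * m_g * np.log(2.0 * np.pi)
                         + 0.5 * m_g * e_log_inv_v - 0.5 * e_inv_v * quad) + (1 - p) * l1mr
            elbo += (-_xlogx(p) - _xlogx(1 - p)
                     + p * 0.5 * (m_g * np.log(2.0 * np.pi * np.e) + logdet))
        elbo += _beta_term((hyper.a_varrho, hyper.b_varrho), state.varrho_ab)
        e_lv = state.lv_gamma[0] / state.lv_gamma[1]
        e_log_lv = digamma(state.lv_gamma[0]) - np.log(state.lv_gamma[1])
        e_log_v = -state.ig_moments(state.v_ig)[1]
        lp_v = (hyper.a_v * e_log_lv - gammaln(hyper.a_v)
                - (hyper.a_v + 1) * e_log_v - e_lv * e_inv_v)
        a, b = state.v_ig
        lq_v = a * np.log(b) - gammaln(a) - (a + 1) * e_log_v - b * e_inv_v
        elbo += lp_v - lq_v
        elbo += _gamma_term((hyper.v_rate_shape, hyper.v_rate_rate), state.lv_gamma)

    if bundle.d:
        lk, l1mk = state._e_log_beta(state.kappa_ab)
        d_bar = float(np.sum(exps.incl_freq))
        elbo += exps.logp_theta_mean
        elbo += (hyper.a_psi * state.e_log_bpsi - gammaln(hyper.a_psi)) * d_bar
        elbo += -(hyper.a_psi + 1.0) * exps.sum_log_psi_mean
        elbo += -state.e_bpsi * exps.sum_inv_psi_mean
        elbo += d_bar * lk + (bundle.d - d_bar) * l1mk
        elbo += _beta_term(state._kappa_prior, state.kappa_ab)
        elbo += _gamma_term((hyper.bpsi_shape, hyper.bpsi_rate), state.bpsi_gamma)
        # entropy of the sampled block omitted (intractable normaliser)
    return float(elbo)


# ---------------------------------------------------------------------------
# results and the outer loop

@dataclass
class FitResult:
    """Posterior summaries of one CAVI-MC run."""

    inclusion_prob: np.ndarray
    theta_mean: np.ndarray
    alpha_mean: float
    sigma2_mean: float
    beta_summary: Optional[pd.DataFrame]
    zeta_summary: Optional[pd.DataFrame]
    elbo_trace: np.ndarray
    converged: bool
    n_iters: int
    run_manifest: dict
    state: VariationalState = field(repr=False, default=None)
    expectations: mc.MCExpectations = field(repr=False, default=None)
    diagnostics: list = field(repr=False, default_factory=list)

    @property
    def final_elbo(self) -> float:
        tail = self.elbo_trace[-min(3, len(self.elbo_trace)):]
        return float(np.mean(tail))


def select_variables(result: FitResult, threshold: float = 0.5) -> np.ndarray:
    """Indicator of taxa whose marginal inclusion probability reaches the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return (result.inclusion_prob >= threshold).astype(int)


def fit_cavi_mc(
    bundle: DesignBundle,
    hyper: ModelHyperparams | None = None,
    schedule: Schedule | None = None,
    seed: int | np.random.Generator = 0,
    keep_trace: bool = False,
) -> FitResult:
    """Run one CAVI-MC chain: auxiliary pseudo-updates, MC phase, analytic sweep.

    Raises ``RuntimeError`` with a diagnostic dump if the ELBO becomes
    non-finite.
    """
    hyper = hyper or ModelHyperparams()
    schedule = schedule or Schedule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    state = init_state(bundle, hyper, rng)
    d = bundle.d
    exps = mc.default_expectations(d, hyper.d_star)
    mc_state = mc.empty_state(d)
    aux = None
    if d:
        z_norm_sq = np.einsum("ij,ij->j", bundle.Z, bundle.Z)
        G = bundle.Z.T @ bundle.Z
        lk, l1mk = state._e_log_beta(state.kappa_ab)
        aux = init_auxiliary(d, hyper.a_psi, state.e_bpsi,
                             np.exp(lk) / (np.exp(lk) + np.exp(l1mk)),
                             z_norm_sq, state.inv_sigma2)

    elbos: list[float] = []
    diags: list = []
    converged = False
    n_done = 0
    for t in range(1, schedule.vi_iters + 1):
        if d:
            parts = _fitted_parts(state, bundle, exps)
            base_resid = bundle.y - state.alpha_mean - parts["Xb"] - parts["Wz"]
            lk, l1mk = state.e_log_kappa
            for _ in range(schedule.aux_sweeps):
                aux_sweep(aux, bundle.Z, base_resid, state.inv_sigma2,
                          lk, l1mk, hyper.a_psi, state.e_bpsi)
            ctx = mc.PhaseContext(
                Z=bundle.Z, G=G, c=bundle.Z.T @ base_resid,
                z_norm_sq=z_norm_sq, inv_sigma2=state.inv_sigma2,
                log_kappa=lk, log_1mkappa=l1mk, a_psi=hyper.a_psi,
                e_log_bpsi=state.e_log_bpsi, e_bpsi=state.e_bpsi,
            )
            probs = mc.xi_inclusion_probs(exps, aux, ctx)
            n_it = schedule.mcmc_init if t <= schedule.escalate_after else schedule.mcmc_main
            exps, diag, mc_state = mc.run_mc_phase(
                mc_state, probs, aux, ctx, n_it, rng,
                phi=hyper.phi, p_between=hyper.p_between,
                burn_in_frac=schedule.burn_in_frac, keep_trace=keep_trace,
            )
            diags.append(diag)

        analytic_sweep(state, bundle, exps, hyper)
        elbo = compute_elbo(state, exps, bundle, hyper)
        if not np.isfinite(elbo):
            raise RuntimeError(
                f"ELBO diverged at iteration {t}: {elbo!r}; "
                f"state={state!r}"
            )
        elbos.append(elbo)
        n_done = t
        w = schedule.elbo_window
        if t > schedule.escalate_after and len(elbos) >= 2 * w:
            cur = float(np.mean(elbos[-w:]))
            prev = float(np.mean(elbos[-2 * w:-w]))
            if abs(cur - prev) < schedule.elbo_rel_tol * max(abs(cur), 1.0):
                converged = True
                break

    theta_mean = exps.mu_theta_marginal.copy()
    beta_summary = None
    if bundle.s:
        beta_summary = pd.DataFrame({
            "mean": state.beta_marginal,
            "conditional_mean": state.beta_mean,
            "inclusion_prob": state.gamma_prob,
        })
    zeta_summary = None
    if bundle.G:
        rows = []
        for g, m in enumerate(bundle.group_sizes):
            for lvl in range(m):
                rows.append({
                    "group": g, "level": lvl,
                    "mean": state.chi_prob[g] * state.zeta_mean[g][lvl],
                    "inclusion_prob": state.chi_prob[g],
                })
        zeta_summary = pd.DataFrame(rows)

    manifest = {
        "n": bundle.n, "d": d, "s": bundle.s, "G": bundle.G,
        "schedule": vars(schedule).copy(),
        "hyper": {k: v for k, v in vars(hyper).items()},
        "n_iters_run": n_done,
    }
    return FitResult(
        inclusion_prob=exps.incl_freq.copy() if d else np.empty(0),
        theta_mean=theta_mean if d else np.empty(0),
        alpha_mean=state.alpha_mean,
        sigma2_mean=state.sig_rate / max(state.sig_shape - 1.0, 1e-12),
        beta_summary=beta_summary,
        zeta_summary=zeta_summary,
        elbo_trace=np.asarray(elbos),
        converged=converged,
        n_iters=n_done,
        run_manifest=manifest,
        state=state,
        expectations=exps,
        diagnostics=diags,
    )
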