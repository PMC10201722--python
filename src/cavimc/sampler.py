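"""Reversible-jump MCMC for the intractable (theta, psi, xi) block.

The variational factor for the compositional block has no closed form: the
truncated Bernoulli prior on the inclusion vector xi (no single-taxon
models) and the per-taxon slab scales psi break conjugacy.  Conditional on
(xi, psi) the coefficients theta are exactly Gaussian on the sum-to-zero
hyperplane, so the sampler works on the collapsed target q(xi, psi | y) —
theta integrated out analytically — and refreshes theta by a Gibbs draw
from its exact conditional each iteration.

Moves:

* between-model (reversible jump): birth/death of one taxon, a joint
  pair-birth/pair-death to enter or leave the empty model (a single birth is
  forbidden by the truncation), or a swap of an active taxon for an inactive
  one.  Taxa are proposed with probabilities from a univariate logistic
  approximation of the collapsed target, refreshed once per outer
  variational iteration; slab scales for born taxa are proposed from the
  auxiliary model's inverse-gamma pseudo-posteriors.
* within-model: Metropolis-Hastings on each active psi_j from the same
  inverse-gamma proposal, xi held fixed.

Expectations accumulated over retained iterations feed the next round of
analytic variational updates; theta moments are Rao-Blackwellised (averages
of exact conditional means and variances rather than raw draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, expit, gammaln

from .auxiliary import AuxiliaryState, invgamma_logpdf, psi_proposal
from .smvn import EigenGaussian, centering_matrix

__all__ = [
    "MCState",
    "MCExpectations",
    "PhaseContext",
    "theta_conditional_params",
    "collapsed_log_target",
    "xi_inclusion_probs",
    "between_model_move",
    "within_model_move",
    "run_mc_phase",
]

_PROB_EPS = 1e-12


@dataclass
class PhaseContext:
    """Quantities frozen for the duration of one MC phase."""

    Z: np.ndarray               # n x d log-composition design
    G: np.ndarray               # Z^T Z, precomputed
    c: np.ndarray               # Z^T r, partial residual projections
    z_norm_sq: np.ndarray       # diag(G)
    inv_sigma2: float           # (sigma^-2)^(1)
    log_kappa: float            # (log kappa)^(1)
    log_1mkappa: float          # (log(1-kappa))^(1)
    a_psi: float
    e_log_bpsi: float           # (log b_psi)^(1)
    e_bpsi: float               # (b_psi)^(1)

    @property
    def d(self) -> int:
        return self.Z.shape[1]


@dataclass
class MCState:
    """Current sampler state: inclusion vector, slab scales and cached conditional."""

    xi: np.ndarray                        # bool, length d, sum != 1
    psi: np.ndarray                       # float, 0 where inactive
    theta: np.ndarray                     # last Gibbs draw, sums to 0
    log_target: float = -np.inf
    cond: EigenGaussian | None = None     # conditional of theta on the active set
    log_pdet_prior: float = 0.0           # log det* of T diag(psi) T on the active set
    prior_pinv: np.ndarray | None = None  # its pseudo-inverse

    @property
    def active(self) -> np.ndarray:
        return np.flatnonzero(self.xi)

    @property
    def d_xi(self) -> int:
        return int(self.xi.sum())


def empty_state(d: int) -> MCState:
    return MCState(xi=np.zeros(d, dtype=bool), psi=np.zeros(d), theta=np.zeros(d))


@dataclass
class MCExpectations:
    """Monte Carlo estimates of the intractable q expectations.

    Conditional averages (suffix ``_nz``) are over iterations with
    ``xi_j = 1`` and are NaN for taxa never included; callers fall back to
    prior-based defaults there.
    """

    incl_freq: np.ndarray          # E[q(xi_j | y)]
    mu_theta_marginal: np.ndarray  # {mu_theta_j}^{1}
    mu_theta_nonzero: np.ndarray   # {mu_theta_j}^{1}_nonzero
    var_theta_bar: np.ndarray      # mean diagonal of the conditional covariance
    log_psi_nonzero: np.ndarray
    inv_psi_nonzero: np.ndarray
    marg_inv_psi: np.ndarray       # mean of xi_j / psi_j over retained iterations
    d_xi_mean: float
    zt_sq_mean: float              # E ||Z theta||^2
    logp_theta_mean: float         # E log p(theta | psi, xi)
    sum_log_psi_mean: float        # E sum_active log psi_j
    sum_inv_psi_mean: float        # E sum_active 1/psi_j
    n_retained: int
    ever_included: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.ever_included is None:
            self.ever_included = self.incl_freq > 0


def default_expectations(d: int, d_star: float) -> MCExpectations:
    """Prior-based placeholder used before the first MC phase."""
    nan = np.full(d, np.nan)
    return MCExpectations(
        incl_freq=np.zeros(d),
        mu_theta_marginal=np.zeros(d),
        mu_theta_nonzero=nan.copy(),
        var_theta_bar=nan.copy(),
        log_psi_nonzero=nan.copy(),
        inv_psi_nonzero=nan.copy(),
        marg_inv_psi=np.zeros(d),
        d_xi_mean=float(max(d_star, 2.0)),
        zt_sq_mean=0.0,
        logp_theta_mean=0.0,
        sum_log_psi_mean=0.0,
        sum_inv_psi_mean=0.0,
        n_retained=0,
        ever_included=np.zeros(d, dtype=bool),
    )


# ---------------------------------------------------------------------------
# exact conditional and collapsed target

def theta_conditional_params(
    active: np.ndarray, psi_active: np.ndarray, ctx: PhaseContext
) -> tuple[EigenGaussian, float, np.ndarray]:
    """Exact conditional of theta on the active set, in eigen-factored form.

    On the hyperplane the conditional density is proportional to
    ``exp(-theta' A theta / 2 + b' theta)`` with
    ``A = (T D(psi) T)^+ + s Z'Z`` restricted to the hyperplane and
    ``b = s Z'r``.  Returns the Gaussian, the log pseudo-determinant of the
    prior covariance ``T D T`` and its pseudo-inverse (both reused by the
    collapsed target).
    """
    k = active.size
    if k < 2:
        raise ValueError("theta conditional requires at least two active taxa")
    T = centering_matrix(k)
    cov_prior = T @ np.diag(psi_active) @ T
    w, U = np.linalg.eigh(cov_prior)
    keep = w > 1e-12 * max(w[-1], 1e-300)
    wk, Uk = w[keep], U[:, keep]
    prior_pinv = (Uk / wk) @ Uk.T
    log_pdet_prior = float(np.sum(np.log(wk)))

    Gaa = ctx.G[np.ix_(active, active)]
    A = prior_pinv + ctx.inv_sigma2 * (T @ Gaa @ T)
    lin = T @ (ctx.inv_sigma2 * ctx.c[active])
    wA, UA = np.linalg.eigh((A + A.T) / 2.0)
    keepA = wA > 1e-12 * max(wA[-1], 1e-300)
    wAk, UAk = wA[keepA], UA[:, keepA]
    mean = UAk @ ((UAk.T @ lin) / wAk)
    # exact in exact arithmetic; re-centering removes the rounding drift of
    # ill-conditioned eigendecompositions off the zero-sum hyperplane
    mean -= mean.mean()
    cond = EigenGaussian(mean=mean, vecs=UAk, prec_vals=wAk,
                         log_pdet_prec=float(np.sum(np.log(wAk))))
    return cond, log_pdet_prior, prior_pinv


def collapsed_log_target(
    xi: np.ndarray, psi: np.ndarray, ctx: PhaseContext
) -> tuple[float, EigenGaussian | None, float, np.ndarray | None]:
    """Log of the collapsed block target q(xi, psi | y), theta integrated out.

    Up to a constant shared by all configurations:
    ``(1/2) b' C b - (1/2) log det* A - (1/2) log det*(T D T)`` plus the
    truncated-Bernoulli and inverse-gamma prior terms; the Gaussian
    ``(2 pi)`` powers from the prior normaliser and the theta integral
    cancel exactly.
    """
    active = np.flatnonzero(xi)
    k = active.size
    if k == 1:
        return -np.inf, None, 0.0, None
    base_inactive = ctx.log_1mkappa * (ctx.d - k)
    if k == 0:
        return base_inactive, None, 0.0, None
    psi_a = psi[active]
    cond, log_pdet_prior, prior_pinv = theta_conditional_params(active, psi_a, ctx)
    lin = cond.vecs @ (cond.prec_vals * (cond.vecs.T @ cond.mean))
    quad = 0.5 * float(cond.mean @ lin)
    prior_bits = k * (
        ctx.log_kappa + ctx.a_psi * ctx.e_log_bpsi - gammaln(ctx.a_psi)
    ) - (ctx.a_psi + 1.0) * float(np.sum(np.log(psi_a))) - ctx.e_bpsi * float(
        np.sum(1.0 / psi_a)
    )
    log_t = quad - 0.5 * cond.log_pdet_prec - 0.5 * log_pdet_prior + prior_bits + base_inactive
    return log_t, cond, log_pdet_prior, prior_pinv


def _refresh_state(state: MCState, ctx: PhaseContext) -> None:
    log_t, cond, lp_prior, p_pinv = collapsed_log_target(state.xi, state.psi, ctx)
    state.log_target = log_t
    state.cond = cond
    state.log_pdet_prior = lp_prior
    state.prior_pinv = p_pinv


# ---------------------------------------------------------------------------
# proposal probabilities (univariate approximation of the collapsed target)

def xi_inclusion_probs(
    exps: MCExpectations,
    aux: AuxiliaryState,
    ctx: PhaseContext,
) -> np.ndarray:
    """Per-taxon proposal probabilities p~(xi_j = 1 | .).

    Transcription of the univariate logistic approximation of the collapsed
    target, with the branch on the expected active-set size {d_xi}: the
    cross-term correction applies when {d_xi} >= 2, a plain sum of squares
    below.  Fallbacks for taxa never yet included: prior inverse-gamma
    moments for the psi expectations, the unconstrained single-taxon
    variance ``1 / (||Z_j||^2 (sigma^-2)^(1))`` for the variance average, and
    the auxiliary model's conditional mean for the theta mean.
    """
    d = ctx.d
    # conditional MC averages built from a handful of visits are noise;
    # treat low-occupancy taxa like never-included ones and lean on the
    # auxiliary model instead
    never = ~exps.ever_included | (exps.incl_freq < 0.05)

    mu_nz = np.where(never, aux.omega_mean, np.nan_to_num(exps.mu_theta_nonzero))
    mu_marg = np.where(never, aux.marginal_omega(),
                       np.nan_to_num(exps.mu_theta_marginal))
    var_bar = np.where(never, 1.0 / (ctx.z_norm_sq * ctx.inv_sigma2),
                       np.nan_to_num(exps.var_theta_bar, nan=1.0))
    var_bar = np.maximum(var_bar, 1e-300)
    prior_log_psi = np.log(ctx.e_bpsi) - digamma(ctx.a_psi)
    prior_inv_psi = ctx.a_psi / ctx.e_bpsi
    log_psi = np.where(never, prior_log_psi, np.nan_to_num(exps.log_psi_nonzero))
    inv_psi = np.where(never, prior_inv_psi, np.nan_to_num(exps.inv_psi_nonzero))

    d_bar = exps.d_xi_mean
    if d_bar >= 2.0:
        total = float(np.sum(mu_marg))
        dot = (1.0 - 1.0 / d_bar) * mu_nz**2 - (2.0 / d_bar) * mu_nz * (total - mu_marg)
    else:
        dot = mu_nz**2

    x = (
        ctx.log_1mkappa
        - dot / (2.0 * var_bar)
        - 0.5 * np.log(var_bar)
        + 0.5 * log_psi
        - ctx.log_kappa
        + gammaln(ctx.a_psi)
        - ctx.a_psi * ctx.e_log_bpsi
        + (ctx.a_psi + 1.0) * log_psi
        + ctx.e_bpsi * inv_psi
    )
    probs = expit(-x)
    return np.clip(probs, _PROB_EPS, 1.0 - _PROB_EPS)


# ---------------------------------------------------------------------------
# moves

def _birth_death_split(k: int, d: int) -> tuple[float, float]:
    """Probability of choosing birth vs death given the current model size."""
    if k == 0:
        return 1.0, 0.0
    if k >= d:
        return 0.0, 1.0
    return 0.5, 0.5


def _pair_log_prob(weights: np.ndarray, i: int, j: int) -> float:
    """Log probability of drawing the unordered pair {i, j} sequentially
    without replacement with selection weights proportional to ``weights``."""
    S = float(weights.sum())
    wi, wj = float(weights[i]), float(weights[j])
    p = wi * wj / S * (1.0 / (S - wi) + 1.0 / (S - wj))
    return float(np.log(p))


def _weighted_choice(rng: np.random.Generator, idx: np.ndarray, w: np.ndarray) -> tuple[int, float]:
    p = w / w.sum()
    pick = rng.choice(idx.size, p=p)
    return int(idx[pick]), float(p[pick])


def between_model_move(
    state: MCState,
    probs: np.ndarray,
    aux: AuxiliaryState,
    ctx: PhaseContext,
    phi: float,
    rng: np.random.Generator,
) -> bool:
    """One reversible-jump move; returns True if accepted.

    With probability ``phi`` a birth-death move, otherwise a swap.  Leaving
    or entering the empty model adds/removes a *pair* of taxa jointly since
    single-taxon models are excluded by the truncated prior; dimension
    matching is through the inverse-gamma psi proposals (Jacobian 1).
    """
    d = ctx.d
    k = state.d_xi
    if rng.random() < phi:
        p_birth, _ = _birth_death_split(k, d)
        do_birth = rng.random() < p_birth
        if k == 0 or (do_birth and k < d):
            if k == 0:
                return _double_birth(state, probs, aux, ctx, rng)
            return _single_birth(state, probs, aux, ctx, rng)
        if k == 2:
            return _double_death(state, probs, aux, ctx, rng)
        return _single_death(state, probs, aux, ctx, rng)
    return _swap_move(state, probs, aux, ctx, rng)


def _accept(state: MCState, ctx: PhaseContext, xi_new: np.ndarray, psi_new: np.ndarray,
            log_hastings: float, rng: np.random.Generator) -> bool:
    log_t, cond, lp_prior, p_pinv = collapsed_log_target(xi_new, psi_new, ctx)
    log_alpha = log_t - state.log_target + log_hastings
    if np.log(rng.random()) < log_alpha:
        state.xi = xi_new
        state.psi = psi_new
        state.log_target = log_t
        state.cond = cond
        state.log_pdet_prior = lp_prior
        state.prior_pinv = p_pinv
        return True
    return False


def _single_birth(state, probs, aux, ctx, rng) -> bool:
    d, k = ctx.d, state.d_xi
    inactive = np.flatnonzero(~state.xi)
    j, sel = _weighted_choice(rng, inactive, probs[inactive])
    psi_j, log_g = psi_proposal(aux, j, rng)
    xi_new = state.xi.copy()
    xi_new[j] = True
    psi_new = state.psi.copy()
    psi_new[j] = psi_j
    # reverse: death of j from the k+1 model
    active_new = np.flatnonzero(xi_new)
    w_death = 1.0 - probs[active_new]
    rev_sel = float(w_death[active_new == j][0] / w_death.sum())
    p_birth, _ = _birth_death_split(k, d)
    _, p_death_rev = _birth_death_split(k + 1, d)
    log_h = (np.log(p_death_rev) + np.log(rev_sel)) - (np.log(p_birth) + np.log(sel) + log_g)
    return _accept(state, ctx, xi_new, psi_new, log_h, rng)


def _single_death(state, probs, aux, ctx, rng) -> bool:
    d, k = ctx.d, state.d_xi  # k >= 3 here
    active = state.active
    w_death = 1.0 - probs[active]
    j, sel = _weighted_choice(rng, active, w_death)
    log_g = invgamma_logpdf(state.psi[j], float(aux.delta_shape[j]), float(aux.delta_rate[j]))
    xi_new = state.xi.copy()
    xi_new[j] = False
    psi_new = state.psi.copy()
    psi_new[j] = 0.0
    inactive_new = np.flatnonzero(~xi_new)
    w_birth = probs[inactive_new]
    rev_sel = float(w_birth[inactive_new == j][0] / w_birth.sum())
    _, p_death = _birth_death_split(k, d)
    p_birth_rev, _ = _birth_death_split(k - 1, d)
    log_h = (np.log(p_birth_rev) + np.log(rev_sel) + log_g) - (np.log(p_death) + np.log(sel))
    return _accept(state, ctx, xi_new, psi_new, log_h, rng)


def _double_birth(state, probs, aux, ctx, rng) -> bool:
    d = ctx.d
    all_idx = np.arange(d)
    i, _ = _weighted_choice(rng, all_idx, probs)
    rest = np.delete(all_idx, i)
    j, _ = _weighted_choice(rng, rest, probs[rest])
    log_pair = _pair_log_prob(probs, i, j)
    psi_i, log_gi = psi_proposal(aux, i, rng)
    psi_j, log_gj = psi_proposal(aux, j, rng)
    xi_new = state.xi.copy()
    xi_new[[i, j]] = True
    psi_new = state.psi.copy()
    psi_new[i], psi_new[j] = psi_i, psi_j
    _, p_death_rev = _birth_death_split(2, d)
    log_h = np.log(p_death_rev) - (log_pair + log_gi + log_gj)
    return _accept(state, ctx, xi_new, psi_new, log_h, rng)


def _double_death(state, probs, aux, ctx, rng) -> bool:
    d = ctx.d
    i, j = state.active
    log_pair = _pair_log_prob(probs, i, j)
    log_gi = invgamma_logpdf(state.psi[i], float(aux.delta_shape[i]), float(aux.delta_rate[i]))
    log_gj = invgamma_logpdf(state.psi[j], float(aux.delta_shape[j]), float(aux.delta_rate[j]))
    xi_new = np.zeros(d, dtype=bool)
    psi_new = np.zeros(d)
    _, p_death = _birth_death_split(2, d)
    log_h = (log_pair + log_gi + log_gj) - np.log(p_death)
    return _accept(state, ctx, xi_new, psi_new, log_h, rng)


def _swap_move(state, probs, aux, ctx, rng) -> bool:
    k = state.d_xi
    if k == 0 or k >= ctx.d:
        return False  # no-op: nothing to swap
    active = state.active
    inactive = np.flatnonzero(~state.xi)
    w_rem = 1.0 - probs[active]
    r, sel_rem = _weighted_choice(rng, active, w_rem)
    a, sel_add = _weighted_choice(rng, inactive, probs[inactive])
    psi_a, log_ga = psi_proposal(aux, a, rng)
    log_gr = invgamma_logpdf(state.psi[r], float(aux.delta_shape[r]), float(aux.delta_rate[r]))
    xi_new = state.xi.copy()
    xi_new[r], xi_new[a] = False, True
    psi_new = state.psi.copy()
    psi_new[r], psi_new[a] = 0.0, psi_a
    active_new = np.flatnonzero(xi_new)
    inactive_new = np.flatnonzero(~xi_new)
    w_rem_new = 1.0 - probs[active_new]
    rev_rem = float(w_rem_new[active_new == a][0] / w_rem_new.sum())
    w_add_new = probs[inactive_new]
    rev_add = float(w_add_new[inactive_new == r][0] / w_add_new.sum())
    log_h = (np.log(rev_rem) + np.log(rev_add) + log_gr) - (
        np.log(sel_rem) + np.log(sel_add) + log_ga
    )
    return _accept(state, ctx, xi_new, psi_new, log_h, rng)


def within_model_move(
    state: MCState,
    aux: AuxiliaryState,
    ctx: PhaseContext,
    rng: np.random.Generator,
) -> int:
    """Componentwise Metropolis-Hastings on the active slab scales; xi fixed.

    Returns the number of accepted components.  A no-op on the empty model.
    """
    accepted = 0
    for j in state.active:
        psi_j, log_g_new = psi_proposal(aux, int(j), rng)
        log_g_old = invgamma_logpdf(
            state.psi[j], float(aux.delta_shape[j]), float(aux.delta_rate[j])
        )
        psi_new = state.psi.copy()
        psi_new[j] = psi_j
        if _accept(state, ctx, state.xi.copy(), psi_new, log_g_old - log_g_new, rng):
            accepted += 1
    return accepted


# ---------------------------------------------------------------------------
# the MC phase

@dataclass
class PhaseDiagnostics:
    n_iters: int = 0
    n_retained: int = 0
    between_attempts: int = 0
    between_accepts: int = 0
    within_attempts: int = 0
    within_accepts: int = 0
    single_taxon_states: int = 0     # retained samples violating the truncation (must stay 0)
    max_abs_theta_sum: float = 0.0
    xi_trace: list | None = None


def run_mc_phase(
    state: MCState,
    probs: np.ndarray,
    aux: AuxiliaryState,
    ctx: PhaseContext,
    n_iters: int,
    rng: np.random.Generator,
    phi: float = 0.5,
    p_between: float = 0.5,
    burn_in_frac: float = 0.2,
    keep_trace: bool = False,
) -> tuple[MCExpectations, PhaseDiagnostics, MCState]:
    """Run one MC phase and accumulate the expectations the CAVI needs.

    The chain warm-starts from ``state``; the first ``burn_in_frac`` of the
    iterations are discarded.  Theta moments are accumulated from the exact
    conditional (mean and covariance diagonal) at each retained iteration; a
    theta draw is still made for the sample path and the zero-sum
    diagnostic.
    """
    d = ctx.d
    _refresh_state(state, ctx)
    n_burn = int(np.floor(burn_in_frac * n_iters))
    diag = PhaseDiagnostics(n_iters=n_iters, xi_trace=[] if keep_trace else None)

    incl = np.zeros(d)
    th_sum = np.zeros(d)
    th_nz_sum = np.zeros(d)
    var_sum = np.zeros(d)
    logpsi_sum = np.zeros(d)
    invpsi_sum = np.zeros(d)
    dxi_sum = 0.0
    ztsq_sum = 0.0
    logp_theta_sum = 0.0
    n_ret = 0

    for it in range(n_iters):
        if rng.random() < p_between:
            diag.between_attempts += 1
            if between_model_move(state, probs, aux, ctx, phi, rng):
                diag.between_accepts += 1
        else:
            k = state.d_xi
            diag.within_attempts += k
            diag.within_accepts += within_model_move(state, aux, ctx, rng)

        # Gibbs refresh of theta from its exact conditional
        active = state.active
        k = active.size
        theta = np.zeros(d)
        if k:
            draw = state.cond.sample(rng)
            theta[active] = draw - draw.mean()   # exact re-projection
        state.theta = theta

        if it < n_burn:
            continue
        n_ret += 1
        if k == 1:
            diag.single_taxon_states += 1
        diag.max_abs_theta_sum = max(diag.max_abs_theta_sum, abs(float(theta.sum())))
        if keep_trace:
            diag.xi_trace.append(tuple(active.tolist()))

        dxi_sum += k
        if k:
            m = state.cond.mean
            cdiag = state.cond.cov_diag
            incl[active] += 1.0
            th_sum[active] += m
            th_nz_sum[active] += m
            var_sum[active] += cdiag
            lp = np.log(state.psi[active])
            ip = 1.0 / state.psi[active]
            logpsi_sum[active] += lp
            invpsi_sum[active] += ip
            Gaa = ctx.G[np.ix_(active, active)]
            cov = state.cond.cov
            ztsq_sum += float(m @ Gaa @ m + np.sum(Gaa * cov))
            quad_prior = float(m @ state.prior_pinv @ m + np.sum(state.prior_pinv * cov))
            logp_theta_sum += (
                -0.5 * (k - 1) * np.log(2.0 * np.pi)
                - 0.5 * state.log_pdet_prior
                - 0.5 * quad_prior
            )

    n_ret = max(n_ret, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        incl_freq = incl / n_ret
        mu_marg = th_sum / n_ret
        mu_nz = np.where(incl > 0, th_nz_sum / np.maximum(incl, 1.0), np.nan)
        var_bar = np.where(incl > 0, var_sum / np.maximum(incl, 1.0), np.nan)
        logpsi_nz = np.where(incl > 0, logpsi_sum / np.maximum(incl, 1.0), np.nan)
        invpsi_nz = np.where(incl > 0, invpsi_sum / np.maximum(incl, 1.0), np.nan)

    diag.n_retained = n_ret
    exps = MCExpectations(
        incl_freq=incl_freq,
        mu_theta_marginal=mu_marg,
        mu_theta_nonzero=mu_nz,
        var_theta_bar=var_bar,
        log_psi_nonzero=logpsi_nz,
        inv_psi_nonzero=invpsi_nz,
        marg_inv_psi=invpsi_sum / n_ret,
        d_xi_mean=dxi_sum / n_ret,
        zt_sq_mean=ztsq_sum / n_ret,
        logp_theta_mean=logp_theta_sum / n_ret,
        sum_log_psi_mean=float(logpsi_sum.sum()) / n_ret,
        sum_inv_psi_mean=float(invpsi_sum.sum()) / n_ret,
        n_retained=n_ret,
        ever_included=incl > 0,
    )
    return exps, diag, state
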