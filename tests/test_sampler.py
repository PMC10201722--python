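"""Reversible-jump sampler: conditionals, proposal probabilities, moves."""

from collections import Counter

import numpy as np
import pytest

from cavimc.auxiliary import aux_sweep, init_auxiliary
from cavimc.sampler import (
    PhaseContext,
    collapsed_log_target,
    default_expectations,
    empty_state,
    run_mc_phase,
    theta_conditional_params,
    xi_inclusion_probs,
)
from conftest import make_toy_ctx
from oracles import (
    batch_means_se,
    batched_collapsed_log_target,
    config_quadrature_expectation,
    constrained_gls_mode,
)


def _aux_for(ctx, y, sweeps=2):
    kappa = float(np.exp(ctx.log_kappa))
    aux = init_auxiliary(ctx.d, ctx.a_psi, ctx.e_bpsi, kappa,
                         ctx.z_norm_sq, ctx.inv_sigma2)
    for _ in range(sweeps):
        aux_sweep(aux, ctx.Z, y, ctx.inv_sigma2, ctx.log_kappa,
                  ctx.log_1mkappa, ctx.a_psi, ctx.e_bpsi)
    return aux


class TestThetaConditional:
    def test_empty_model_is_dirac_at_zero(self, toy_ctx):
        ctx, _ = toy_ctx
        logt, cond, _, _ = collapsed_log_target(np.zeros(3, bool), np.zeros(3), ctx)
        assert cond is None and np.isfinite(logt)

    def test_single_active_excluded(self, toy_ctx):
        ctx, _ = toy_ctx
        xi = np.array([True, False, False])
        logt, *_ = collapsed_log_target(xi, np.array([1.0, 0, 0]), ctx)
        assert logt == -np.inf

    def test_pair_draws_are_exact_negatives(self, toy_ctx, rng):
        ctx, _ = toy_ctx
        cond, _, _ = theta_conditional_params(np.array([0, 1]), np.ones(2), ctx)
        for _ in range(20):
            draw = cond.sample(rng)
            assert abs(draw.sum()) < 1e-12

    def test_mean_matches_lagrange_oracle(self):
        """KKT oracle: the conditional mean is the constrained penalised GLS
        solution min 1/2 th' A th - b' th subject to sum th = 0."""
        r = np.random.default_rng(14)
        n, d = 18, 4
        Z = r.normal(size=(n, d))
        y = Z @ np.array([1.0, -0.4, -0.6, 0.0]) + 0.3 * r.normal(size=n)
        ctx = PhaseContext(Z=Z, G=Z.T @ Z, c=Z.T @ y,
                           z_norm_sq=np.einsum("ij,ij->j", Z, Z),
                           inv_sigma2=4.0, log_kappa=np.log(0.3),
                           log_1mkappa=np.log(0.7), a_psi=2.0,
                           e_log_bpsi=0.0, e_bpsi=1.0)
        active = np.array([0, 1, 2, 3])
        psi = np.array([0.7, 1.3, 0.5, 2.0])
        cond, _, prior_pinv = theta_conditional_params(active, psi, ctx)
        A = prior_pinv + ctx.inv_sigma2 * ctx.G
        b = ctx.inv_sigma2 * ctx.c
        ref = constrained_gls_mode(A, b)
        np.testing.assert_allclose(cond.mean, ref, atol=1e-10)
        assert abs(cond.mean.sum()) < 1e-10

    def test_collapsed_target_matches_independent_transcription(self, toy_ctx, rng):
        ctx, _ = toy_ctx
        for cfg in [(0, 1), (1, 2), (0, 1, 2)]:
            xi = np.zeros(3, bool)
            xi[list(cfg)] = True
            psi_a = rng.uniform(0.2, 3.0, size=len(cfg))
            psi = np.zeros(3)
            psi[list(cfg)] = psi_a
            ours = collapsed_log_target(xi, psi, ctx)[0]
            ref = batched_collapsed_log_target(cfg, psi_a[None, :], ctx)[0]
            np.testing.assert_allclose(ours, ref, atol=1e-9)


class TestInclusionProbs:
    def _base_exps(self, d):
        exps = default_expectations(d, 4.0)
        exps.incl_freq = np.full(d, 0.5)
        exps.ever_included = np.ones(d, bool)
        exps.mu_theta_nonzero = np.zeros(d)
        exps.mu_theta_marginal = np.zeros(d)
        exps.var_theta_bar = np.full(d, 0.5)
        exps.log_psi_nonzero = np.zeros(d)
        exps.inv_psi_nonzero = np.ones(d)
        return exps

    def test_monotone_in_conditional_mean_squared(self, toy_ctx):
        ctx, y = toy_ctx
        aux = _aux_for(ctx, y)
        probs = []
        for m in (0.0, 0.5, 1.0, 2.0):
            exps = self._base_exps(3)
            exps.mu_theta_nonzero[0] = m
            probs.append(xi_inclusion_probs(exps, aux, ctx)[0])
        assert np.all(np.diff(probs) > 0)

    def test_prior_odds_shift_raises_all(self, toy_ctx):
        ctx, y = toy_ctx
        aux = _aux_for(ctx, y)
        exps = self._base_exps(3)
        lo = xi_inclusion_probs(exps, aux, ctx)
        ctx_hi = PhaseContext(**{**ctx.__dict__, "log_kappa": ctx.log_kappa + 1.0})
        hi = xi_inclusion_probs(exps, aux, ctx_hi)
        assert np.all(hi > lo)

    def test_matches_literal_formula_transcription(self, toy_ctx, rng):
        """Independent scalar re-implementation of the univariate logistic
        approximation, both branches of the {d_xi} threshold."""
        from scipy.special import expit, gammaln
        ctx, y = toy_ctx
        aux = _aux_for(ctx, y)
        for d_bar in (3.4, 1.2):
            exps = self._base_exps(3)
            exps.d_xi_mean = d_bar
            exps.mu_theta_nonzero = rng.normal(size=3)
            exps.mu_theta_marginal = rng.normal(scale=0.3, size=3)
            exps.var_theta_bar = rng.uniform(0.2, 1.0, size=3)
            exps.log_psi_nonzero = rng.normal(size=3)
            exps.inv_psi_nonzero = rng.uniform(0.5, 2.0, size=3)
            ours = xi_inclusion_probs(exps, aux, ctx)
            for j in range(3):
                mu_nz = exps.mu_theta_nonzero[j]
                if d_bar >= 2.0:
                    others = sum(exps.mu_theta_marginal[k] for k in range(3) if k != j)
                    dot = (1 - 1 / d_bar) * mu_nz**2 - (2 / d_bar) * mu_nz * others
                else:
                    dot = mu_nz**2
                x = (ctx.log_1mkappa - dot / (2 * exps.var_theta_bar[j])
                     - 0.5 * np.log(exps.var_theta_bar[j])
                     + 0.5 * exps.log_psi_nonzero[j] - ctx.log_kappa
                     + gammaln(ctx.a_psi) - ctx.a_psi * ctx.e_log_bpsi
                     + (ctx.a_psi + 1) * exps.log_psi_nonzero[j]
                     + ctx.e_bpsi * exps.inv_psi_nonzero[j])
                np.testing.assert_allclose(ours[j], expit(-x), rtol=1e-12)


class TestMoves:
    def test_truncation_and_zero_sum_over_long_chain(self, toy_ctx, rng):
        ctx, y = toy_ctx
        aux = _aux_for(ctx, y)
        probs = xi_inclusion_probs(default_expectations(3, 2.0), aux, ctx)
        exps, diag, state = run_mc_phase(empty_state(3), probs, aux, ctx, 20_000,
                                         rng, keep_trace=True)
        assert diag.single_taxon_states == 0
        assert all(len(cfg) != 1 for cfg in diag.xi_trace)
        assert diag.max_abs_theta_sum < 1e-10
        assert np.all((exps.incl_freq >= 0) & (exps.incl_freq <= 1))
        assert abs(exps.mu_theta_marginal.sum()) < 1e-10

    def test_detailed_balance_flow_counts(self, toy_ctx, rng):
        """On a frozen toy target the empirical transition flow between any
        two configurations must balance its reverse."""
        ctx, y = toy_ctx
        aux = _aux_for(ctx, y)
        probs = xi_inclusion_probs(default_expectations(3, 2.0), aux, ctx)
        _, diag, _ = run_mc_phase(empty_state(3), probs, aux, ctx, 60_000, rng,
                                  burn_in_frac=0.1, keep_trace=True)
        trace = diag.xi_trace
        flows = Counter(zip(trace[:-1], trace[1:]))
        pairs = {tuple(sorted((a, b))) for (a, b) in flows if a != b}
        checked = 0
        for a, b in pairs:
            f, r = flows.get((a, b), 0), flows.get((b, a), 0)
            if f + r < 100:
                continue
            checked += 1
            assert abs(f - r) < 5 * np.sqrt(f + r), (a, b, f, r)
        assert checked >= 2

    def test_within_model_marginal_matches_quadrature(self, toy_ctx):
        """With xi frozen to a pair, the chain's E[log psi_j] must match the
        normalised restriction of the collapsed target, integrated
        numerically."""
        ctx, y = toy_ctx
        aux = _aux_for(ctx, y)
        cfg = (0, 1)
        state = empty_state(3)
        state.xi[list(cfg)] = True
        state.psi[list(cfg)] = 1.0
        rng = np.random.default_rng(77)
        n_it = 60_000
        log_psi0 = []
        # p_between = 0 freezes xi: only within-model psi moves occur
        from cavimc.sampler import _refresh_state, within_model_move
        _refresh_state(state, ctx)
        for it in range(n_it):
            within_model_move(state, aux, ctx, rng)
            if it >= n_it // 5:
                log_psi0.append(np.log(state.psi[0]))
        log_psi0 = np.asarray(log_psi0)
        ref = config_quadrature_expectation(
            cfg, ctx, lambda psi: np.log(psi[:, 0]))
        se = batch_means_se(log_psi0)
        assert abs(log_psi0.mean() - ref) < 3 * se + 1e-3

    def test_stationarity_invariant_to_doubling(self, toy_ctx):
        """Occupancy estimates agree between a chain and one twice as long."""
        ctx, y = toy_ctx
        aux = _aux_for(ctx, y)
        probs = xi_inclusion_probs(default_expectations(3, 2.0), aux, ctx)
        _, d1, _ = run_mc_phase(empty_state(3), probs, aux, ctx, 20_000,
                                np.random.default_rng(5), keep_trace=True)
        _, d2, _ = run_mc_phase(empty_state(3), probs, aux, ctx, 40_000,
                                np.random.default_rng(6), keep_trace=True)
        for cfg in {(), (0, 1), (0, 1, 2)}:
            p1 = np.mean([t == cfg for t in d1.xi_trace])
            p2 = np.mean([t == cfg for t in d2.xi_trace])
            se1 = batch_means_se(np.array([float(t == cfg) for t in d1.xi_trace]))
            se2 = batch_means_se(np.array([float(t == cfg) for t in d2.xi_trace]))
            assert abs(p1 - p2) < 4 * np.sqrt(se1**2 + se2**2) + 1e-3
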