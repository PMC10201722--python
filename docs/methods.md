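# Methods

## Model

Observed data: a response `y` (length n), a taxon count table closed to a
composition `Q` (n × d), optional standardised continuous covariates `X`
(n × s) and reference-coded categorical dummy blocks `W` (n × Σ m_g).
Zeros in the counts are replaced by a pseudo-count (default 0.5) before
closure; `Z = log Q`. The likelihood is the log-contrast model

    y = α·1 + X β + W ζ + Z θ + ε,   ε ~ N(0, σ² I),   Σ_j θ_j = 0.

The zero-sum constraint removes the dependence on a reference taxon: the
model is the alr regression reparameterised into d symmetric coefficients.

### Priors

* `θ | ψ, ξ`: singular multivariate normal spike-and-slab. With
  `T_k = I_k − J_k/k` the centering projector on the active set (size
  `k = d_ξ`), the active subvector is `SMVN(0, T_k diag(ψ_ξ) T_k)` —
  supported exactly on the sum-to-zero hyperplane (density w.r.t. the
  (k−1)-dimensional Hausdorff measure) — and inactive coordinates are point
  masses at zero. Per-taxon slab scales `ψ_j | ξ_j=1 ~ IG(a_ψ, b_ψ)` absorb
  the orders-of-magnitude spread of taxon abundances; `b_ψ ~ Gamma`.
  For two active taxa the prior covariance is ±[[½,−½],[−½,½]]: the
  coefficients are exact opposites (correlation of magnitude 1, unit-scale
  off-diagonal −1/d_ξ).
* `ξ | κ`: independent Bernoulli(κ) *truncated to Σ ξ_j ≠ 1* — a lone log
  abundance carries no relative information, so single-taxon models are
  excluded outright. `κ ~ Beta(a_κ, b_κ)` with `a_κ = 1`,
  `b_κ = (d − d*)/d` derived from `d*`, the prior expected number of
  selected taxa (default 6; the benchmark averages fits with 6 and 12).
* `β_s | γ_s`: Gaussian spike-and-slab, slab variance `w` shared across
  continuous covariates; `γ_s ~ Bern(ω)`, `ω ~ Beta(1,1)`,
  `w ~ IG(0.01, λ_w)`, `λ_w ~ Gamma(0.01, 0.01)`.
* `ζ_g | χ_g`: grouped spike-and-slab — the whole m_g-vector of a factor's
  dummy coefficients enters or leaves together (`χ_g ~ Bern(ϱ)`), slab
  `N(0, v I)`; hyperpriors mirror the continuous block. A 2-level factor
  reduces exactly to the continuous update with `v` in place of `w`.
* `σ² ~ IG(0.01, 0.01)`; `α` flat (its conjugate update is exact and the
  empty-model posterior mean is ȳ).

## Inference: CAVI with an embedded sampler

A structured mean-field family is used: each spike-and-slab pair
`(coefficient, indicator)` is one block (`q(β_s,γ_s) = q(β_s|γ_s)q(γ_s)`),
hyperparameters factorise, and `(θ, ψ, ξ)` is a single intractable block.
All unconstrained blocks have closed-form exponential-family updates
(Gaussian, inverse-gamma, beta, gamma); expectations of logs use digammas.
Marginal coefficient means are conditional means shrunk by the inclusion
probability.

One outer iteration runs:

1. **Auxiliary pseudo-updates.** An unconstrained surrogate model
   `(Ω_j, Δ_j, Υ_j)` per taxon — Gaussian spike-and-slab with its own IG
   slab scale — is updated analytically (all Ω/Υ first, then all Δ).
   Conditional (unshrunk) expectations parameterise the sampler's
   proposals: `q(Δ_j | Υ_j=1) = IG(½ + a_ψ, (σ²_Ω,j + μ²_Ω,j)/2 + E[b_ψ])`
   becomes the proposal for `ψ_j`. The surrogate's residual includes the
   intercept and `W` block (the source derivation omits them; it carried no
   such covariates in its experiments).
2. **MC phase.** The sampler targets the *collapsed* block posterior
   `q(ξ, ψ | y)`: conditional on `(ξ, ψ)`, `θ` is exactly Gaussian on the
   hyperplane — precision `(T_k D(ψ) T_k)⁺ + (σ⁻²) Z_ξᵀ Z_ξ` restricted to
   the hyperplane — and is integrated out in closed form, then redrawn by a
   Gibbs step each iteration. We use the exact restricted-precision
   conditional (its mean is the constrained penalised GLS solution; we
   verified the commonly printed unrestricted-inverse form differs and
   fails the KKT conditions). Moves: with probability `p_between = 0.5` a
   between-model reversible-jump move — birth/death (probability φ = 0.5)
   or swap — otherwise within-model Metropolis-Hastings on each active
   `ψ_j`. Because single-taxon models are excluded, the empty model is
   entered and left by *pair* death/birth moves; dimension matching is
   through the IG proposals (Jacobian 1). Birth targets are drawn with
   probabilities from a univariate logistic approximation of the collapsed
   target built from the previous phase's Monte Carlo expectations, with
   fallbacks for taxa not reliably visited (occupancy < 5%): prior IG
   moments for the ψ expectations, `1/(‖Z_j‖² (σ⁻²))` for the variance, and
   the auxiliary conditional mean `μ_Ω,j` for the coefficient mean. The
   first 20% of each phase is discarded; chains warm-start across outer
   iterations. Accumulated expectations (inclusion frequencies, conditional
   θ means/variances — Rao-Blackwellised from the exact conditional —
   ψ moments, `E‖Zθ‖²`) feed step 3.
3. **Analytic sweep** in dependency order: α, σ², each (β_s, γ_s), each
   (ζ_g, χ_g), then ω, w, λ_w, ϱ, v, λ_v, κ, b_ψ. The κ update ignores the
   truncation normaliser (an intractable constant); the truncation itself
   is enforced exactly in the sampler's support.
4. **ELBO.** All analytic terms are exact; the sampled block contributes
   plug-in Monte Carlo averages for `E log p(y|·)`, `E log p(θ|ψ,ξ)`,
   `E log p(ψ|ξ)`, `E log p(ξ|κ)`. The block's own entropy is omitted
   (intractable normaliser), so the trace is exact up to an additive term
   that is constant whenever the Monte Carlo samples are fixed — the
   coordinate-ascent monotonicity guarantee and convergence monitoring are
   unaffected, and no absolute ELBO value is ever interpreted.

**Schedule.** Defaults mirror the reference protocol: up to 25 outer
iterations, 5000 sampler iterations per phase escalating to 10,000 after
the 5th; convergence is declared when a 3-iteration running mean of the
ELBO moves by less than 0.1% (the trace fluctuates by Monte Carlo noise, so
a windowed rule replaces strict monotonicity). Scaled-down settings used in
the test suite: 8–12 outer iterations, 400/800 sampler iterations
(1500/3000 at d=200).

**Initialisation and restarts.** Free parameters start at seeded random
jitter around data-scaled values: σ² at the residual variance of a light
ridge fit of y on Z (the raw response variance starves the proposal
guidance of signal until the compositional block catches up), unit-scale
w/v/b_ψ, inclusion probabilities near their prior means. Draws straight
from the diffuse IG/gamma hyperpriors span tens of orders of magnitude and
destabilise the first sweep, so they are not used. The optimisation is
non-convex: `fit(n_runs=k)` runs k restarts and reports the one with the
best final ELBO (averaged over the last three iterations to damp Monte
Carlo noise). Restarts are the effective remedy for the occasional chain
stuck in a compensating sub-model (a stuck run's ELBO is far below a
healthy one's); the benchmark uses three, the worked example four. Identical seeds reproduce results bit-for-bit.

**Outputs.** Per-taxon inclusion probabilities `E[q(ξ_j|y)]` (final-phase
frequencies), model-averaged coefficient means (which inherit the zero-sum
constraint from every sample), covariate summaries, the ELBO trace and a
run manifest. Selection thresholds the inclusion probabilities at 0.5.

## Synthetic data

`simulate_dataset` emulates a taxon relative-abundance table via a
logistic-normal design: latent `O ~ N(μ_o, Σ_o)` rowwise, composition
`q_ij = exp(τ o_ij)/Σ_k exp(τ o_ik)` with τ = 2, `μ_oj = log(0.5 d)` for
the first five taxa (orders-of-magnitude abundance spread) and 0 otherwise,
`Σ_o = I` or AR(1) `ρ^|i−j|` (ρ ∈ {0, 0.2, 0.4}). Six taxa are associated,
coefficients (1, −1.5, 0.5, −1, 1.5, −0.5) on taxa 1–3 and 6–8: each pair
(p, p+5) carries opposite coefficients, so the model collapses exactly to a
three-term all-pairs log-ratio form
`y = Σ_p θ_p log(q_p / q_{p+5}) + ε`. The sign pattern matters more than it
looks: flipping pair 2 to (+1.5, −1.5) aligns the signal with the shared
softmax denominator of the dominant-abundance block and creates a dense
near-collinear direction that roughly halves every method's selection
accuracy — we keep the printed mixed-sign vector. Noise is calibrated from
`SNR = mean|θ_nonzero|/σ`, so SNR 0.5 ⇒ σ = 2 and SNR 2.5 ⇒ σ = 0.4; an
independent test split of 5 rows accompanies each dataset. Defaults n=100,
d ∈ {45, 200}.

What this emulates — and what it does not: real 16S tables have integer
counts with sampling zeros, taxonomic correlation structure beyond AR(1),
and unknown true supports. Passing benchmarks here demonstrates that the
estimator recovers a known sparse log-contrast signal under realistic
abundance heterogeneity, not that it resolves the harder identifiability
questions of real microbiome data.

## Benchmark metrics

TPR and FPR of the thresholded support; `L² = ‖θ̂ − θ‖²`; prediction error
`PE = mean (y_test − α̂ − Z_test θ̂)²` on the held-out split (θ̂ is the
model-averaged posterior mean; the fitted intercept, essentially zero here,
is included because it is part of the package's predictor); squared bias
aggregated across replicates as `Σ_j (mean_r θ̂_rj − θ_j)²`. Each replicate
is fitted with d\* = 6 and d\* = 12 and the metrics averaged. ROC curves
sweep the inclusion-probability threshold; the staircase AUC equals the
pairwise rank statistic.

A caution when comparing against the published benchmark tables: their L²
column is inconsistent with their own PE column under the stated generator
(constrained OLS on the true support achieves ‖θ̂−θ‖² ≈ 0.007 where ≈ 3.8
is printed for every method, and the printed values scale linearly rather
than quadratically in σ). This package reports the literal squared-error
loss.

## Numerical choices

* Eigenvalue cutoff for pseudo-inverses / pseudo-determinants: 1e-10 ×
  largest eigenvalue (T's null space is exact in theory; only rounding
  perturbs it). Off-support density evaluations return −∞ rather than
  raising, so samplers reject instead of crashing.
* Singular-normal sampling is by eigendecomposition: k−1 standard normals
  scaled by the nonzero eigenvalue roots and rotated back. Conditional
  means and θ draws are re-centred (mean subtracted) — a no-op in exact
  arithmetic that removes the rounding drift of ill-conditioned
  eigendecompositions, keeping every retained draw on the hyperplane to
  well below 1e-10.
* Proposal probabilities are clipped to [1e-12, 1 − 1e-12]; all logistic
  forms are evaluated with `expit` to avoid overflow.
* The expected active-set size `{d_ξ}` selects between the two printed
  branches of the proposal-probability formula; exactly 2 uses the ≥2
  branch (continuous there).
* `{μ_θj}` conditional averages are unweighted means over the iterations
  with `ξ_j = 1` (the source leaves the weighting unspecified).
* Within-model ψ proposals are componentwise with immediate accept/reject;
  the auxiliary model runs a single sweep per outer iteration (it is
  refined again by the full updates anyway).

## Known limitations

* Gaussian responses only; no missing-data handling (missing covariates are
  rejected); no phylogeny-structured or correlation-aware selection priors
  — performance degrades when compositional correlation is high and SNR is
  low, as the univariate proposal guidance loses its signal.
* The reported ELBO is a surrogate (sampled-block entropy omitted): valid
  for convergence monitoring and run ranking, meaningless in absolute
  terms.
* Inclusion probabilities are Monte Carlo frequencies from the final phase;
  with short chains they are themselves noisy — lengthen the schedule
  before interpreting borderline probabilities.
* The truncated-Bernoulli normaliser is ignored in κ's update; for very
  small d this slightly biases κ's posterior (the support truncation itself
  is always enforced exactly).
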