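# cavimc

Bayesian variable selection for **compositional covariates** — microbiome
relative abundances regressed against a continuous outcome — with exact
handling of the simplex geometry, fitted by **Monte Carlo coordinate-ascent
variational inference (CAVI-MC)**.

## Who this is for

Microbiome studies ask which taxa are associated with a phenotype (BMI,
disease markers, ...). Taxon tables are *compositional*: counts only carry
relative information, so ordinary regression on abundances is invalid. The
standard remedy is the log-contrast model

```
y = α·1 + X β + W ζ + Z θ + ε,   ε ~ N(0, σ² I),   Σ_j θ_j = 0
```

where `Z` holds log relative abundances (zeros replaced by a 0.5
pseudo-count, rows closed to sum to one), `X`/`W` are optional continuous
and dummy-coded categorical covariates, and the **sum-to-zero constraint**
on `θ` makes inference invariant to the choice of reference taxon.

`cavimc` puts a **singular multivariate normal spike-and-slab prior** on
`θ`: conditional on the inclusion vector `ξ` (truncated so a single taxon
can never be selected alone — one log abundance is meaningless without a
partner), the active coefficients live exactly on the sum-to-zero
hyperplane with covariance `T diag(ψ) T`, `T = I − J/d` the centering
projector. Per-taxon slab scales `ψ_j` (inverse-gamma, with a hierarchical
rate) absorb the orders-of-magnitude differences between taxon abundances.
Unconstrained blocks get conjugate spike-and-slab priors (per-covariate for
`β`, grouped for each categorical factor's `ζ_g`).

Everything except the `(θ, ψ, ξ)` block has a closed-form coordinate-ascent
variational update. That block is handled by an embedded **reversible-jump
MCMC** (birth/death/swap moves over taxon sets, Metropolis-Hastings on the
slab scales) whose proposals are guided by an auxiliary unconstrained model
fitted with fast *pseudo* variational updates. The sampler's Monte Carlo
expectations feed back into the analytic updates and the ELBO.

## Worked example

```python
import numpy as np
from cavimc import CompositionalRegression, ModelHyperparams, Schedule
from cavimc import SimulationSpec, simulate_dataset

# a synthetic 100-sample, 45-taxon dataset: six associated taxa, SNR 2.5
spec = SimulationSpec(n=100, d=45, snr=2.5)
bundle, theta_true, test = simulate_dataset(spec, rng=11)

model = CompositionalRegression(bundle, ModelHyperparams(d_star=6))
res = model.fit(seed=5, n_runs=4,
                schedule=Schedule(vi_iters=10, mcmc_init=400, mcmc_main=800))
print(res.summary())
```

prints (abridged):

```
CAVI-MC compositional regression
================================================
samples: 100   taxa: 45   continuous: 0   groups: 0
restarts: 4 (best run 0, final ELBO -92.866, converged: True)
intercept mean: 0.0737   sigma2 mean: 0.1435

top taxa by inclusion probability (threshold 0.5):
 * taxon_1              p= 1.000  theta=+0.9997
 * taxon_2              p= 1.000  theta=-1.4841
 * taxon_3              p= 1.000  theta=+0.4798
 * taxon_7              p= 1.000  theta=+1.5179
 * taxon_6              p= 1.000  theta=-1.0002
 * taxon_8              p= 1.000  theta=-0.5096
   taxon_45             p= 0.047  theta=-0.0015
```

The six truly associated taxa (1–3 and 6–8, true coefficients
1, −1.5, 0.5, −1, 1.5, −0.5) are recovered with inclusion probability ≈ 1
and model-averaged posterior means within a few hundredths of the truth;
the estimated noise variance 0.144 sits near the generating σ² = 0.16, and
every other taxon stays near zero. `res.select(0.5)`
returns the thresholded support, `res.supports()` shows that all four
random restarts agree, and `res.predict(test["Z"])` gives held-out
predictions. For real data, `CompositionalRegression.from_counts` accepts a
raw count `DataFrame` plus covariate tables, and the `cavimc` command-line
tool (`fit`, `simulate`, `benchmark`) drives the same pipeline from TSV/CSV
files and a YAML config.

The `run_benchmark` / `run_cell` functions replay the simulation study
(logistic-normal compositions, `SNR = mean|θ_nonzero| / σ`, metrics
TPR / FPR / L² / prediction error, fits averaged over prior model sizes
d\* ∈ {6, 12}).

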