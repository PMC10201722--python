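"""Model/Results facade for the CAVI-MC compositional regression.

Usage mirrors the fit interface of statsmodels-style packages::

    model = CompositionalRegression.from_counts(counts, y)
    res = model.fit(seed=1, n_runs=4)
    print(res.summary())
    support = res.select(threshold=0.5)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cavi
from ._design import CompositionTable, DesignBundle, build_bundle
from .priors import ModelHyperparams

__all__ = ["CompositionalRegression", "CAVIMCResults"]


class CompositionalRegression:
    """Bayesian log-contrast regression with spike-and-slab taxon selection.

    The response is modelled as ``y = alpha + X beta + W zeta + Z theta +
    eps`` with ``Z`` the log relative abundances and ``theta`` constrained
    to sum to zero, so inference is invariant to the choice of reference
    taxon.  A singular-normal spike-and-slab prior with per-taxon slab
    scales selects taxa; fitting is by coordinate-ascent variational
    inference with a reversible-jump MCMC step for the compositional block.
    """

    def __init__(self, bundle: DesignBundle, hyper: ModelHyperparams | None = None):
        self.bundle = bundle
        self.hyper = hyper or ModelHyperparams()

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray | pd.DataFrame,
        y: np.ndarray,
        continuous: pd.DataFrame | None = None,
        categorical: pd.DataFrame | None = None,
        pseudo_count: float = 0.5,
        log_response: bool = False,
        hyper: ModelHyperparams | None = None,
        reference_levels: dict[str, str] | None = None,
    ) -> "CompositionalRegression":
        """Build the model from a raw count table (samples x taxa)."""
        if isinstance(counts, pd.DataFrame):
            table = CompositionTable(
                counts=counts.to_numpy(dtype=float),
                taxon_ids=[str(c) for c in counts.columns],
                sample_ids=[str(i) for i in counts.index],
            )
        else:
            counts = np.asarray(counts, dtype=float)
            table = CompositionTable(
                counts=counts,
                taxon_ids=[f"taxon_{j + 1}" for j in range(counts.shape[1])],
                sample_ids=[f"sample_{i + 1}" for i in range(counts.shape[0])],
            )
        bundle = build_bundle(table, y, continuous, categorical,
                              pseudo_count=pseudo_count, log_response=log_response,
                              reference_levels=reference_levels)
        return cls(bundle, hyper)

    def fit(
        self,
        seed: int = 0,
        n_runs: int = 1,
        schedule: cavi.Schedule | None = None,
        keep_trace: bool = False,
    ) -> "CAVIMCResults":
        """Fit with ``n_runs`` random restarts; the run with the best final
        ELBO (average of the last few iterations, to damp Monte Carlo
        noise) provides the reported estimates."""
        schedule = schedule or cavi.Schedule()
        seeds = np.random.SeedSequence(seed).spawn(n_runs)
        runs = [
            cavi.fit_cavi_mc(self.bundle, self.hyper, schedule,
                             seed=np.random.default_rng(ss), keep_trace=keep_trace)
            for ss in seeds
        ]
        best = int(np.argmax([r.final_elbo for r in runs]))
        return CAVIMCResults(model=self, runs=runs, best_index=best)


@dataclass
class CAVIMCResults:
    """Fit results across random restarts; summaries come from the best run."""

    model: CompositionalRegression
    runs: list
    best_index: int = 0
    threshold: float = 0.5
    _best: cavi.FitResult = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._best = self.runs[self.best_index]

    # -- delegated summaries ------------------------------------------------
    @property
    def inclusion_prob(self) -> np.ndarray:
        return self._best.inclusion_prob

    @property
    def theta_mean(self) -> np.ndarray:
        return self._best.theta_mean

    @property
    def alpha_mean(self) -> float:
        return self._best.alpha_mean

    @property
    def sigma2_mean(self) -> float:
        return self._best.sigma2_mean

    @property
    def elbo_trace(self) -> np.ndarray:
        return self._best.elbo_trace

    @property
    def converged(self) -> bool:
        return self._best.converged

    @property
    def beta_summary(self):
        return self._best.beta_summary

    @property
    def zeta_summary(self):
        return self._best.zeta_summary

    def select(self, threshold: float | None = None) -> np.ndarray:
        return cavi.select_variables(self._best, self.threshold if threshold is None else threshold)

    def predict(self, Z_new: np.ndarray) -> np.ndarray:
        """Posterior-mean prediction for new log-composition rows."""
        return self.alpha_mean + np.asarray(Z_new, float) @ self.theta_mean

    def supports(self, threshold: float | None = None) -> list[tuple[int, ...]]:
        """Selected support of every restart (for stability checks)."""
        thr = self.threshold if threshold is None else threshold
        return [tuple(np.flatnonzero(r.inclusion_prob >= thr)) for r in self.runs]

    def taxon_table(self) -> pd.DataFrame:
        ids = self.model.bundle.taxon_ids
        return pd.DataFrame({
            "taxon": ids,
            "inclusion_prob": self.inclusion_prob,
            "theta_mean": self.theta_mean,
        })

    def summary(self, top: int = 10) -> str:
        b = self.model.bundle
        best = self._best
        lines = [
            "CAVI-MC compositional regression",
            "=" * 48,
            f"samples: {b.n}   taxa: {b.d}   continuous: {b.s}   groups: {b.G}",
            f"restarts: {len(self.runs)} (best run {self.best_index}, "
            f"final ELBO {best.final_elbo:.3f}, converged: {best.converged})",
            f"intercept mean: {self.alpha_mean:.4f}   sigma2 mean: {self.sigma2_mean:.4f}",
            "",
            f"top taxa by inclusion probability (threshold {self.threshold}):",
        ]
        tab = self.taxon_table().sort_values("inclusion_prob", ascending=False).head(top)
        for _, row in tab.iterrows():
            mark = "*" if row.inclusion_prob >= self.threshold else " "
            lines.append(
                f" {mark} {row.taxon:<20s} p={row.inclusion_prob:6.3f}  "
                f"theta={row.theta_mean:+.4f}"
            )
        if best.beta_summary is not None:
            lines.append("")
            lines.append("continuous covariates:")
            for i, row in best.beta_summary.iterrows():
                lines.append(f"   x{i}: mean={row['mean']:+.4f}  p={row.inclusion_prob:.3f}")
        return "\n".join(lines)
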