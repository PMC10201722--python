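"""Selection and estimation metrics for the simulation benchmark."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SelectionMetrics", "evaluate_selection", "roc_sweep", "roc_auc",
           "aggregate_bias2", "plot_roc"]


@dataclass
class SelectionMetrics:
    tpr: float | None   # None when no truly associated features exist
    fpr: float
    l2: float           # ||theta_hat - theta||^2
    pe: float           # mean squared prediction error on the held-out split

    def as_dict(self) -> dict:
        return {"tpr": self.tpr, "fpr": self.fpr, "l2": self.l2, "pe": self.pe}


def evaluate_selection(
    xi_hat: np.ndarray,
    theta_hat: np.ndarray,
    theta_true: np.ndarray,
    Z_test: np.ndarray,
    y_test: np.ndarray,
    intercept: float = 0.0,
) -> SelectionMetrics:
    """TPR/FPR of the selected support, squared-error loss of the
    coefficients and prediction error ``mean((y_test - alpha - Z theta)^2)``."""
    xi_hat = np.asarray(xi_hat).astype(bool)
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if not (xi_hat.shape == theta_hat.shape == theta_true.shape):
        raise ValueError("shape mismatch between estimates and truth")
    truth = theta_true != 0
    n_true = int(truth.sum())
    n_null = truth.size - n_true
    tpr = float(np.sum(xi_hat & truth) / n_true) if n_true else None
    fpr = float(np.sum(xi_hat & ~truth) / n_null) if n_null else 0.0
    l2 = float(np.sum((theta_hat - theta_true) ** 2))
    resid = np.asarray(y_test, float) - intercept - np.asarray(Z_test, float) @ theta_hat
    pe = float(resid @ resid / resid.size)
    return SelectionMetrics(tpr=tpr, fpr=fpr, l2=l2, pe=pe)


def roc_sweep(
    inclusion_prob: np.ndarray,
    theta_true: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> np.ndarray:
    """(FPR, TPR) staircase over a threshold grid (descending in threshold)."""
    probs = np.asarray(inclusion_prob, dtype=float)
    truth = np.asarray(theta_true, dtype=float) != 0
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    n_true = max(int(truth.sum()), 1)
    n_null = max(int((~truth).sum()), 1)
    pts = []
    for t in thresholds:
        sel = probs >= t
        pts.append((np.sum(sel & ~truth) / n_null, np.sum(sel & truth) / n_true))
    return np.asarray(pts)


def roc_auc(inclusion_prob: np.ndarray, theta_true: np.ndarray) -> float:
    """Area under the ROC staircase via the trapezoid rule on a fine grid."""
    pts = roc_sweep(inclusion_prob, theta_true,
                    np.unique(np.concatenate([[0.0, 1.0], inclusion_prob])))
    fpr, tpr = pts[:, 0], pts[:, 1]
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def plot_roc(inclusion_prob: np.ndarray, theta_true: np.ndarray, ax=None,
             label: str | None = None, mark_threshold: float | None = 0.5):
    """Plain ROC staircase of the inclusion probabilities; optionally marks
    the operating point at ``mark_threshold``."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = roc_sweep(inclusion_prob, theta_true)
    ax.step(pts[:, 0], pts[:, 1], where="post", label=label)
    if mark_threshold is not None:
        op = roc_sweep(inclusion_prob, theta_true, np.array([mark_threshold]))
        ax.plot(op[0, 0], op[0, 1], "o")
    ax.plot([0, 1], [0, 1], ls=":", lw=0.8, color="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend()
    return ax


def aggregate_bias2(theta_hats: np.ndarray, theta_true: np.ndarray) -> float:
    """Squared bias across replicates: sum_j (mean_r theta_hat_rj - theta_j)^2."""
    theta_hats = np.atleast_2d(np.asarray(theta_hats, dtype=float))
    diff = theta_hats.mean(axis=0) - np.asarray(theta_true, dtype=float)
    return float(np.sum(diff**2))
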