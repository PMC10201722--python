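"""Compositional preprocessing and regression design assembly.

Raw taxon counts carry only relative information: each sample is a point on
the simplex once closed to sum to one.  The pipeline here is the standard
one for log-contrast regression: replace zeros by a small pseudo-count
(0.5 by default), close each row, take elementwise logs to obtain the
``n x d`` compositional design ``Z``, and encode any unconstrained
covariates (standardised continuous columns ``X``, reference-coded dummy
groups ``W``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompositionTable",
    "DesignBundle",
    "replace_zeros_and_close",
    "build_log_design",
    "alr_transform",
    "encode_covariates",
    "read_counts",
    "build_bundle",
]


@dataclass
class CompositionTable:
    """A samples-by-taxa nonnegative abundance table."""

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n, d = self.counts.shape
        if n < 2 or d < 3:
            raise ValueError(f"need at least 2 samples and 3 taxa, got {n} x {d}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(self.taxon_ids) != d or len(self.sample_ids) != n:
            raise ValueError("label lengths do not match the count matrix")
        if len(set(self.taxon_ids)) != d:
            raise ValueError("duplicate taxon ids")


@dataclass
class DesignBundle:
    """Assembled regression design: response, log-composition and covariate blocks.

    ``Z`` holds log relative abundances (rows of ``exp(Z)`` sum to one when
    built from a closed composition); ``X`` is columnwise standardised;
    ``W`` stacks the dummy blocks of the categorical groups, whose widths
    are recorded in ``group_sizes``.
    """

    y: np.ndarray
    Z: np.ndarray
    X: np.ndarray | None = None
    W: np.ndarray | None = None
    group_sizes: tuple[int, ...] = ()
    taxon_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.Z = np.asarray(self.Z, dtype=float)
        n = self.y.shape[0]
        if self.Z.shape[0] != n:
            raise ValueError("Z and y disagree on the number of samples")
        if self.X is None or np.size(self.X) == 0:
            self.X = np.empty((n, 0))
        else:
            self.X = np.asarray(self.X, dtype=float)
        if self.W is None or np.size(self.W) == 0:
            self.W = np.empty((n, 0))
        else:
            self.W = np.asarray(self.W, dtype=float)
        self.group_sizes = tuple(int(m) for m in self.group_sizes)
        if sum(self.group_sizes) != self.W.shape[1]:
            raise ValueError("group_sizes do not sum to the number of W columns")
        if self.taxon_ids is None:
            self.taxon_ids = [f"taxon_{j + 1}" for j in range(self.Z.shape[1])]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def d(self) -> int:
        return self.Z.shape[1]

    @property
    def s(self) -> int:
        return self.X.shape[1]

    @property
    def G(self) -> int:
        return len(self.group_sizes)

    def group_slices(self) -> list[slice]:
        out, start = [], 0
        for m in self.group_sizes:
            out.append(slice(start, start + m))
            start += m
        return out


def replace_zeros_and_close(counts: np.ndarray, pseudo_count: float = 0.5) -> np.ndarray:
    """Replace zero entries by ``pseudo_count`` and close each row to sum to 1."""
    counts = np.asarray(counts, dtype=float)
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    zero_rows = np.flatnonzero(~np.any(counts > 0, axis=1))
    if zero_rows.size:
        raise ValueError(f"sample(s) {zero_rows.tolist()} contain only zeros")
    filled = np.where(counts == 0.0, pseudo_count, counts)
    return filled / filled.sum(axis=1, keepdims=True)


def build_log_design(Q: np.ndarray) -> np.ndarray:
    """Elementwise log of a strictly positive closed composition matrix."""
    Q = np.asarray(Q, dtype=float)
    if np.any(Q <= 0):
        raise ValueError("composition entries must be strictly positive; replace zeros first")
    return np.log(Q)


def alr_transform(Q: np.ndarray, reference: int) -> np.ndarray:
    """Additive log-ratio transform: ``log(q_j / q_ref)`` with the reference column omitted."""
    Q = np.asarray(Q, dtype=float)
    if np.any(Q <= 0):
        raise ValueError("composition entries must be strictly positive")
    d = Q.shape[1]
    if not 0 <= reference < d:
        raise IndexError(f"reference index {reference} out of range for d={d}")
    logQ = np.log(Q)
    keep = [j for j in range(d) if j != reference]
    return logQ[:, keep] - logQ[:, [reference]]


def encode_covariates(
    continuous: pd.DataFrame | None,
    categorical: pd.DataFrame | None,
    reference_levels: dict[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Standardise continuous covariates and dummy-code categorical groups.

    Each factor with ``m_g + 1`` levels yields ``m_g`` dummy columns coded
    against a reference level (first level in sorted order unless given in
    ``reference_levels``).  Missing values are rejected: the model has no
    missingness mechanism.
    """
    reference_levels = reference_levels or {}
    if continuous is not None and continuous.shape[1]:
        if continuous.isna().any().any():
            raise ValueError("missing values in continuous covariates")
        vals = continuous.to_numpy(dtype=float)
        sd = vals.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"constant continuous column(s): {list(continuous.columns[bad])}")
        X = (vals - vals.mean(axis=0)) / sd
    else:
        X = np.empty((len(continuous) if continuous is not None else 0, 0))

    blocks: list[np.ndarray] = []
    sizes: list[int] = []
    if categorical is not None and categorical.shape[1]:
        if categorical.isna().any().any():
            raise ValueError("missing values in categorical covariates")
        for col in categorical.columns:
            levels = sorted(categorical[col].astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"factor {col!r} has a single level")
            ref = str(reference_levels.get(col, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found in factor {col!r}")
            others = [lv for lv in levels if lv != ref]
            vals = categorical[col].astype(str).to_numpy()
            blocks.append(np.column_stack([(vals == lv).astype(float) for lv in others]))
            sizes.append(len(others))
    if blocks:
        W = np.hstack(blocks)
    else:
        nrows = X.shape[0] if X.size else (len(categorical) if categorical is not None else 0)
        W = np.empty((nrows, 0))
    return X, W, tuple(sizes)


def read_counts(path: str, sep: str | None = None, transpose: bool = False) -> CompositionTable:
    """Read a TSV/CSV count table (sample ids in the first column, taxon ids in the header)."""
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    if transpose:
        df = df.T
    return CompositionTable(
        counts=df.to_numpy(dtype=float),
        taxon_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )


def build_bundle(
    table: CompositionTable,
    y: np.ndarray,
    continuous: pd.DataFrame | None = None,
    categorical: pd.DataFrame | None = None,
    pseudo_count: float = 0.5,
    log_response: bool = False,
    reference_levels: dict[str, str] | None = None,
) -> DesignBundle:
    """Full preprocessing pipeline from a count table to a :class:`DesignBundle`."""
    Q = replace_zeros_and_close(table.counts, pseudo_count)
    Z = build_log_design(Q)
    y = np.asarray(y, dtype=float).ravel()
    if log_response:
        if np.any(y <= 0):
            raise ValueError("log-response requested but the response has nonpositive values")
        y = np.log(y)
    n = Z.shape[0]
    if continuous is not None or categorical is not None:
        X, W, sizes = encode_covariates(continuous, categorical, reference_levels)
        if X.size and X.shape[0] != n:
            raise ValueError("continuous covariates and counts disagree on sample count")
        if W.size and W.shape[0] != n:
            raise ValueError("categorical covariates and counts disagree on sample count")
    else:
        X, W, sizes = np.empty((n, 0)), np.empty((n, 0)), ()
    return DesignBundle(y=y, Z=Z, X=X, W=W, group_sizes=sizes, taxon_ids=list(table.taxon_ids))
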