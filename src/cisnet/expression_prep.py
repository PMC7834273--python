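"""Expression preprocessing: expressed-gene filtering, tissue-aware smooth
quantile (qsmooth-style) normalization, additive batch correction on the
log scale, and Pearson co-expression.

The smooth quantile normalization interpolates, per quantile, between full
quantile normalization (all samples share the reference distribution) and
within-group quantile normalization, weighting by how much of the total
variance at that quantile lies between groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genomic_io import ExpressionMatrix

__all__ = [
    "filter_expressed",
    "qsmooth_normalize",
    "remove_batch",
    "coexpression",
    "log_transform",
]


def filter_expressed(
    expr: ExpressionMatrix,
    min_samples: int = 3,
    min_count: float = 1,
) -> ExpressionMatrix:
    """Keep genes with count >= min_count in at least min_samples samples of
    at least one tissue."""
    tissues = expr.tissue.unique()
    for t in tissues:
        n = int((expr.tissue == t).sum())
        if n < min_samples:
            warnings.warn(
                f"tissue {t!r} has only {n} samples; it cannot qualify genes alone",
                stacklevel=2,
            )
    keep = np.zeros(expr.values.shape[0], dtype=bool)
    for t in tissues:
        cols = expr.tissue.index[expr.tissue == t]
        cols = [c for c in cols if c in expr.values.columns]
        n_ok = (expr.values[cols] >= min_count).sum(axis=1)
        keep |= (n_ok >= min_samples).to_numpy()
    return ExpressionMatrix(
        values=expr.values.loc[keep],
        tissue=expr.tissue,
        batch=expr.batch,
        replicate=expr.replicate,
    )


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with shrinking windows at the edges."""
    if window <= 1:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    n = len(x)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def qsmooth_normalize(
    expr: ExpressionMatrix,
    window_fraction: float = 0.05,
) -> ExpressionMatrix:
    """Tissue-aware smooth quantile normalization.

    For each quantile q, the normalized value is
    ``w_q * Qbar_q + (1 - w_q) * Qgroup_q`` with ``w_q = 1 - SSB_q / SST_q``
    (between-group over total sum of squares across samples at that
    quantile), smoothed by a running median over ``window_fraction`` of the
    quantiles.  Ties within a sample receive the mean of their normalized
    values, so within-sample rank order is preserved.
    """
    X = expr.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("qsmooth requires at least 2 samples")
    groups = expr.tissue.loc[expr.values.columns].to_numpy()

    order = np.argsort(X, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(X, order, axis=0)
    qbar = sorted_vals.mean(axis=1)

    unique_groups = pd.unique(groups)
    group_means = np.empty((n_genes, len(unique_groups)))
    group_sizes = np.empty(len(unique_groups))
    for gi, g in enumerate(unique_groups):
        cols = groups == g
        group_sizes[gi] = cols.sum()
        group_means[:, gi] = sorted_vals[:, cols].mean(axis=1)

    # variance decomposition across samples at each quantile
    sst = ((sorted_vals - qbar[:, None]) ** 2).sum(axis=1)
    ssb = (group_sizes[None, :] * (group_means - qbar[:, None]) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = 1.0 - ssb / sst
    w[~np.isfinite(w)] = 1.0  # SST == 0: all samples equal, weight irrelevant
    w = np.clip(w, 0.0, 1.0)
    window = max(1, int(round(window_fraction * n_genes)))
    if window % 2 == 0:
        window += 1
    w = _running_median(w, window)

    group_idx = {g: i for i, g in enumerate(unique_groups)}
    normalized_sorted = np.empty_like(sorted_vals)
    for s in range(n_samples):
        gm = group_means[:, group_idx[groups[s]]]
        # re-sort: the weighted blend can be locally non-monotone where the
        # weight swings between adjacent quantiles; assigning the sorted
        # blend to ranks guarantees within-sample rank preservation
        normalized_sorted[:, s] = np.sort(w * qbar + (1.0 - w) * gm)

    out = np.empty_like(X)
    for s in range(n_samples):
        out[order[:, s], s] = normalized_sorted[:, s]
        # average ties: equal input values get the mean normalized value
        col = X[:, s]
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < n_genes:
            sums = np.bincount(inv, weights=out[:, s])
            out[:, s] = sums[inv] / counts[inv]

    values = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(values, expr.tissue, expr.batch, expr.replicate)


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1), the scale on which the additive batch model operates."""
    values = np.log2(expr.values + 1.0)
    return ExpressionMatrix(values, expr.tissue, expr.batch, expr.replicate)


def remove_batch(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract per-gene least-squares batch effects while preserving tissue
    effects.

    Fits value ~ tissue indicators (cell means) + batch indicators (first
    batch as reference) per gene and subtracts the fitted batch term.
    Idempotent; a single batch is the identity transform.
    """
    samples = list(expr.values.columns)
    tissue = expr.tissue.loc[samples].to_numpy()
    batch = expr.batch.loc[samples].to_numpy()
    batches = pd.unique(batch)
    if len(batches) == 1:
        return ExpressionMatrix(
            expr.values.copy(), expr.tissue, expr.batch, expr.replicate
        )
    tissues = pd.unique(tissue)
    T = np.stack([(tissue == t).astype(float) for t in tissues], axis=1)
    B = np.stack([(batch == b).astype(float) for b in batches[1:]], axis=1)
    design = np.hstack([T, B])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "singular design: batch is confounded with tissue "
            f"(tissues={list(tissues)}, batches={list(batches)})"
        )
    Y = expr.values.to_numpy(dtype=float).T  # samples x genes
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    batch_coef = coef[len(tissues):]
    corrected = (Y - B @ batch_coef).T
    values = pd.DataFrame(corrected, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(values, expr.tissue, expr.batch, expr.replicate)


def coexpression(
    expr: ExpressionMatrix | pd.DataFrame, min_samples: int = 3
) -> pd.DataFrame:
    """Gene x gene Pearson correlation; constant genes get 0 off-diagonal
    and 1 on the diagonal.

    ``min_samples`` exists for the leave-one-out network extraction, which
    legitimately correlates over N-1 >= 2 samples.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    X = values.to_numpy(dtype=float)
    if X.shape[1] < min_samples:
        raise ValueError(f"co-expression requires at least {min_samples} samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=1))
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    Z = Xc / sd_safe[:, None]
    C = Z @ Z.T
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return pd.DataFrame(C, index=values.index, columns=values.index)
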