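"""Message-passing inference of an aggregate TF-gene network and
leave-one-out extraction of per-sample networks.

The aggregate network is estimated by iteratively reconciling three
matrices — a TF x gene working network W (seeded with the binary prior), a
TF x TF cooperativity matrix P (identity in the absence of protein-protein
interaction data), and a gene x gene co-expression matrix C — through
Tanimoto-similarity "responsibility" (R) and "availability" (A) messages:

    R = T(P, W)          how well TF cooperativity explains each edge
    A = T(W, C)          how well gene co-expression supports each edge
    W <- (1-a) W + a (R + A) / 2

with P and C relaxed toward the Tanimoto self-similarity of W after each
step.  Per-sample networks follow the leave-one-out linear interpolation
EW_s = N (W_all - W_-s) + W_-s, and sample edge weights are reported on the
softplus scale logEW = ln(exp(EW) + 1) with prior-zero edges forced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NetworkInferenceState",
    "SampleNetwork",
    "znormalize",
    "tanimoto",
    "panda",
    "lioness",
    "softplus_transform",
]


@dataclass
class NetworkInferenceState:
    W: np.ndarray
    P: np.ndarray
    C: np.ndarray
    alpha: float
    hamming: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


@dataclass
class SampleNetwork:
    sample_id: str
    EW: pd.DataFrame  # TF x gene raw edge weights
    logEW: pd.DataFrame  # softplus-transformed, prior-zero entries = 0


def znormalize(X: np.ndarray) -> np.ndarray:
    """(Z_rows + Z_cols) / sqrt(2), where Z_rows z-scores along each row and
    Z_cols along each column; a zero-variance row or column falls back to
    the z-score over all entries."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("znormalize requires a matrix with >=2 rows and columns")
    overall_sd = X.std()
    if overall_sd == 0:
        raise ValueError("cannot z-normalize an all-constant matrix")
    overall = (X - X.mean()) / overall_sd

    row_mean = X.mean(axis=1, keepdims=True)
    row_sd = X.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_rows = (X - row_mean) / row_sd
    bad_rows = (row_sd == 0).ravel()
    z_rows[bad_rows, :] = overall[bad_rows, :]

    col_mean = X.mean(axis=0, keepdims=True)
    col_sd = X.std(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_cols = (X - col_mean) / col_sd
    bad_cols = (col_sd == 0).ravel()
    z_cols[:, bad_cols] = overall[:, bad_cols]

    return (z_rows + z_cols) / np.sqrt(2.0)


def _heterogeneity_diagonal(S: np.ndarray, alpha: float, step: int) -> None:
    """Replace the diagonal of a self-similarity matrix in place.

    The Tanimoto self-similarity of a vector with itself equals its norm,
    which grows without bound as the working network inflates; the
    message-passing scheme instead puts an exponentially growing
    heterogeneity term (off-diagonal row std scaled by dimension and
    exp(2*alpha*step)) on the diagonal.  This is what drives the
    responsibility and availability messages toward W itself and hence the
    iteration to a fixed point.
    """
    n = S.shape[0]
    mask = np.eye(n, dtype=bool)
    off = np.where(mask, np.nan, S)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_std = np.nanstd(off, axis=1)
    row_std = np.nan_to_num(row_std, nan=1.0)
    S[mask] = row_std * n * np.exp(2.0 * alpha * step)


def tanimoto(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto similarity of the rows of X against the columns
    of Y: T_ij = (x_i . y_j) / sqrt(|x_i|^2 + |y_j|^2 - |x_i . y_j|).

    A pairing of two zero vectors is defined as 0.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[0]:
        raise ValueError(f"inner dimensions disagree: {X.shape} vs {Y.shape}")
    dot = X @ Y
    nx = (X**2).sum(axis=1)[:, None]
    ny = (Y**2).sum(axis=0)[None, :]
    denom_sq = nx + ny - np.abs(dot)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = dot / np.sqrt(denom_sq)
    T[~np.isfinite(T)] = 0.0
    return T


def panda(
    prior: np.ndarray,
    ppi: np.ndarray | None = None,
    coexpr: np.ndarray | None = None,
    alpha: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 200,
    return_state: bool = False,
) -> np.ndarray | NetworkInferenceState:
    """Run the message-passing update to convergence and return the
    aggregate TF x gene network.

    ``ppi`` defaults to the identity (no protein-protein interaction data);
    ``coexpr`` must be symmetric.  Convergence is declared when the mean
    absolute change of W drops below ``tol``.
    """
    prior = np.asarray(prior, dtype=float)
    n_tf, n_gene = prior.shape
    if prior.size == 0 or not prior.any():
        raise ValueError("prior is empty")
    P = np.eye(n_tf) if ppi is None else np.asarray(ppi, dtype=float)
    C = np.eye(n_gene) if coexpr is None else np.asarray(coexpr, dtype=float)
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("co-expression matrix must be symmetric")

    W = znormalize(prior)
    P = znormalize(P)
    C = znormalize(C)
    C = (C + C.T) / 2.0

    state = NetworkInferenceState(W=W, P=P, C=C, alpha=alpha)
    for it in range(1, max_iter + 1):
        R = tanimoto(P, W)
        A = tanimoto(W, C)
        W_new = (1.0 - alpha) * W + alpha * (R + A) / 2.0
        hamming = float(np.abs(W_new - W).mean())
        state.hamming.append(hamming)
        W = W_new

        PW = tanimoto(W, W.T)  # TF x TF, similarity over gene profiles
        _heterogeneity_diagonal(PW, alpha, it)
        CW = tanimoto(W.T, W)  # gene x gene, similarity over TF profiles
        _heterogeneity_diagonal(CW, alpha, it)
        P = (1.0 - alpha) * P + alpha * PW
        C = (1.0 - alpha) * C + alpha * CW

        state.n_iter = it
        if hamming < tol:
            state.converged = True
            break

    if not state.converged:
        warnings.warn(
            f"message passing did not converge in {max_iter} iterations "
            f"(last mean |dW| = {state.hamming[-1]:.3g})",
            stacklevel=2,
        )
    state.W, state.P, state.C = W, P, C
    if return_state:
        return state
    return W


def lioness(
    prior: np.ndarray,
    expression: pd.DataFrame,
    ppi: np.ndarray | None = None,
    alpha: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 200,
    tf_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> list[SampleNetwork]:
    """Extract one network per sample by the leave-one-out identity
    EW_s = N (W_all - W_-s) + W_-s.

    ``expression`` is a genes x samples frame restricted to the prior's
    genes; co-expression is recomputed from the remaining N-1 samples for
    each leave-one-out run while the prior and PPI are reused.
    """
    from .expression_prep import coexpression

    samples = list(expression.columns)
    N = len(samples)
    if N < 3:
        raise ValueError("leave-one-out extraction requires >= 3 samples")
    gene_ids = gene_ids if gene_ids is not None else list(expression.index)
    tf_ids = tf_ids if tf_ids is not None else [f"tf{i}" for i in range(prior.shape[0])]

    C_all = coexpression(expression).to_numpy()
    W_all = panda(prior, ppi, C_all, alpha=alpha, tol=tol, max_iter=max_iter)

    networks: list[SampleNetwork] = []
    mask = prior > 0
    for s in samples:
        rest = expression.drop(columns=[s])
        C_rest = coexpression(rest, min_samples=2).to_numpy()
        W_rest = panda(prior, ppi, C_rest, alpha=alpha, tol=tol, max_iter=max_iter)
        EW = N * (W_all - W_rest) + W_rest
        logEW = softplus_transform(EW, prior_mask=mask)
        networks.append(
            SampleNetwork(
                sample_id=s,
                EW=pd.DataFrame(EW, index=tf_ids, columns=gene_ids),
                logEW=pd.DataFrame(logEW, index=tf_ids, columns=gene_ids),
            )
        )
    return networks


def softplus_transform(
    EW: np.ndarray | pd.DataFrame, prior_mask: np.ndarray | None = None
) -> np.ndarray | pd.DataFrame:
    """Elementwise ln(exp(EW) + 1), overflow-safe; entries where the prior
    is zero are forced to 0."""
    values = EW.to_numpy() if isinstance(EW, pd.DataFrame) else np.asarray(EW, dtype=float)
    out = np.logaddexp(0.0, values)
    if prior_mask is not None:
        out = np.where(prior_mask, out, 0.0)
    if isinstance(EW, pd.DataFrame):
        return pd.DataFrame(out, index=EW.index, columns=EW.columns)
    return out
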