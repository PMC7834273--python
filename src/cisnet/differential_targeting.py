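"""Per-edge linear modeling of sample-network edge weights and gene-level
differential-targeting calls between two tissues.

Each prior edge's softplus weight is regressed on tissue-condition
indicators (cell-means coding, ordinary least squares); the husk-minus-
V2-IST contrast is tested with a two-sided t test and BH-corrected across
all fitted edges.  A gene is differentially targeted when at least one of
its edges is significant; its direction is the sign of the mean contrast
over those edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network_inference import SampleNetwork

__all__ = ["EdgeModelFit", "GeneTargetingCall", "fit_edge_models", "call_genes"]


@dataclass
class EdgeModelFit:
    tf_id: str
    gene_id: str
    beta: dict[str, float]  # per-tissue cell means
    contrast: float  # first tissue minus second tissue of the contrast
    t_stat: float
    p_value: float
    q_value: float
    resid_var: float


@dataclass
class GeneTargetingCall:
    gene_id: str
    direction: str  # {husk_up, v2ist_up, ns}
    n_significant_edges: int
    min_q: float


def _stack_edges(
    networks: Sequence[SampleNetwork],
) -> tuple[np.ndarray, list[tuple[str, str]], list[str]]:
    """Edge x sample matrix of logEW restricted to prior-nonzero edges."""
    first = networks[0].logEW
    mask = np.zeros(first.shape, dtype=bool)
    for net in networks:
        mask |= net.logEW.to_numpy() != 0
    tf_idx, gene_idx = np.nonzero(mask)
    edges = [(first.index[i], first.columns[j]) for i, j in zip(tf_idx, gene_idx)]
    data = np.stack(
        [net.logEW.to_numpy()[tf_idx, gene_idx] for net in networks], axis=1
    )
    sample_ids = [net.sample_id for net in networks]
    return data, edges, sample_ids


def fit_edge_models(
    sample_networks: Sequence[SampleNetwork],
    tissue_labels: pd.Series,
    contrast: tuple[str, str] = ("husk", "v2ist"),
) -> list[EdgeModelFit]:
    """OLS cell-means fit of logEW on tissue-condition per edge, with a
    two-sided t test on the ``contrast[0] - contrast[1]`` difference and BH
    correction across all fitted edges."""
    Y, edges, sample_ids = _stack_edges(sample_networks)
    tissues_per_sample = tissue_labels.loc[sample_ids].to_numpy()
    tissue_levels = list(pd.unique(tissues_per_sample))
    for t in contrast:
        if t not in tissue_levels:
            raise ValueError(f"contrast tissue {t!r} absent from samples")
        if (tissues_per_sample == t).sum() < 2:
            raise ValueError(f"tissue {t!r} has fewer than 2 replicates")

    n_samples = Y.shape[1]
    k = len(tissue_levels)
    df_resid = n_samples - k
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    group_masks = {t: tissues_per_sample == t for t in tissue_levels}
    group_n = {t: int(m.sum()) for t, m in group_masks.items()}
    means = {t: Y[:, m].mean(axis=1) for t, m in group_masks.items()}

    sse = np.zeros(Y.shape[0])
    for t, m in group_masks.items():
        sse += ((Y[:, m] - means[t][:, None]) ** 2).sum(axis=1)
    resid_var = sse / df_resid

    a, b = contrast
    diff = means[a] - means[b]
    se = np.sqrt(resid_var * (1.0 / group_n[a] + 1.0 / group_n[b]))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = diff / se
    # zero residual variance with zero difference: no evidence, p = 1
    t_stat[~np.isfinite(t_stat)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t_stat), df_resid)
    _, q, _, _ = multipletests(p, method="fdr_bh")

    fits = []
    for i, (tf, gene) in enumerate(edges):
        fits.append(
            EdgeModelFit(
                tf_id=tf,
                gene_id=gene,
                beta={t: float(means[t][i]) for t in tissue_levels},
                contrast=float(diff[i]),
                t_stat=float(t_stat[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                resid_var=float(resid_var[i]),
            )
        )
    return fits


def call_genes(
    edge_fits: Sequence[EdgeModelFit],
    q_threshold: float = 0.05,
    up_label: str = "husk_up",
    down_label: str = "v2ist_up",
) -> list[GeneTargetingCall]:
    """Gene-level calls: a gene is differentially targeted when >=1 of its
    edges has q < q_threshold; direction by majority sign of significant
    contrasts, exact ties called ns."""
    by_gene: dict[str, list[EdgeModelFit]] = {}
    for f in edge_fits:
        by_gene.setdefault(f.gene_id, []).append(f)

    calls = []
    for gene in sorted(by_gene):
        fits = by_gene[gene]
        sig = [f for f in fits if f.q_value < q_threshold]
        min_q = min(f.q_value for f in fits)
        if not sig:
            calls.append(GeneTargetingCall(gene, "ns", 0, min_q))
            continue
        n_pos = sum(1 for f in sig if f.contrast > 0)
        n_neg = sum(1 for f in sig if f.contrast < 0)
        if n_pos > n_neg:
            direction = up_label
        elif n_neg > n_pos:
            direction = down_label
        else:
            direction = "ns"
        calls.append(GeneTargetingCall(gene, direction, len(sig), min_q))
    return calls


def fits_to_frame(fits: Sequence[EdgeModelFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tf": [f.tf_id for f in fits],
            "gene": [f.gene_id for f in fits],
            "contrast": [f.contrast for f in fits],
            "t": [f.t_stat for f in fits],
            "p": [f.p_value for f in fits],
            "q": [f.q_value for f in fits],
            "resid_var": [f.resid_var for f in fits],
        }
    )
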