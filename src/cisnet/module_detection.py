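"""Differential-modularity detection of tissue-specific regulatory modules.

Tissue networks are replicate averages of per-sample softplus edge weights.
The differential-modularity matrix D compares a perturbed tissue network to
a baseline tissue network through the baseline's configuration-model
expectation:

    D_tg = w_tg^pert - s_t u_g / W_base

with s_t, u_g the baseline TF/gene strengths and W_base the total baseline
weight.  Communities of TFs and genes maximizing the summed within-
community D (normalized by total perturbed weight) are found by a seeded
Louvain-style search with restarts; modules are filtered on minimum TF and
gene content and matched between tissues by the jaccard index of their
gene sets (>= 0.5 classified as shared).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network_inference import SampleNetwork

__all__ = [
    "TissueNetwork",
    "ModulePartition",
    "Module",
    "ModuleMatch",
    "average_replicates",
    "diff_modularity_matrix",
    "detect_modules",
    "partition_score",
    "filter_modules",
    "match_modules",
    "top_connected_genes",
]


@dataclass
class TissueNetwork:
    tissue: str
    W: pd.DataFrame  # TF x gene mean logEW


@dataclass
class Module:
    module_id: int
    tfs: list[str]
    genes: list[str]


@dataclass
class ModulePartition:
    tf_ids: list[str]
    gene_ids: list[str]
    tf_community: np.ndarray  # community id per TF
    gene_community: np.ndarray
    score: float  # differential modularity M
    node_contribution: dict[str, float]  # per-node share of M

    def modules(self) -> list[Module]:
        out = []
        for cid in sorted(set(self.tf_community) | set(self.gene_community)):
            tfs = [t for t, c in zip(self.tf_ids, self.tf_community) if c == cid]
            genes = [g for g, c in zip(self.gene_ids, self.gene_community) if c == cid]
            out.append(Module(int(cid), tfs, genes))
        return out


@dataclass
class ModuleMatch:
    module_id: int
    best_match_id: int | None
    jaccard: float
    klass: str  # {shared, specific}


def average_replicates(
    sample_networks: Sequence[SampleNetwork],
    tissue_labels: pd.Series,
    tissue: str,
) -> TissueNetwork:
    """Elementwise mean of logEW over the tissue's replicate networks."""
    members = [
        net for net in sample_networks if tissue_labels.loc[net.sample_id] == tissue
    ]
    if not members:
        raise ValueError(f"no samples for tissue {tissue!r}")
    if len(members) < 2:
        raise ValueError(f"tissue {tissue!r} has fewer than 2 replicates")
    W = sum(net.logEW for net in members) / len(members)
    return TissueNetwork(tissue, W)


def diff_modularity_matrix(
    perturbed: TissueNetwork,
    baseline: TissueNetwork,
    prior_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """D_tg = w_tg^pert - s_t u_g / W with baseline strengths s, u and total
    baseline weight W.

    Prior-zero pairs carry no perturbed weight (their w_tg^pert is 0), so
    their D entries are the pure configuration-model penalty -s_t u_g / W;
    keeping that penalty is what gives community detection its resolution.
    Passing ``prior_mask`` zeroes those entries instead, which removes the
    penalty and tends to collapse detection into one giant module — it is
    available for diagnostics only.
    """
    if not perturbed.W.index.equals(baseline.W.index) or not perturbed.W.columns.equals(
        baseline.W.columns
    ):
        raise ValueError("perturbed and baseline networks have different node sets")
    wb = baseline.W.to_numpy()
    wp = perturbed.W.to_numpy()
    total = wb.sum()
    if total == 0:
        raise ValueError("baseline network has zero total weight")
    s = wb.sum(axis=1)
    u = wb.sum(axis=0)
    D = wp - np.outer(s, u) / total
    if prior_mask is not None:
        D = np.where(prior_mask, D, 0.0)
    return pd.DataFrame(D, index=perturbed.W.index, columns=perturbed.W.columns)


def partition_score(
    D: np.ndarray, tf_community: np.ndarray, gene_community: np.ndarray, norm: float
) -> float:
    """M(c) = (1/norm) sum of D_tg over pairs in the same community."""
    same = tf_community[:, None] == gene_community[None, :]
    return float((D * same).sum() / norm)


def detect_modules(
    D: pd.DataFrame,
    rng: np.random.Generator | None = None,
    n_restarts: int = 10,
    norm: float | None = None,
) -> ModulePartition:
    """Greedy Louvain-style maximization of the differential modularity on
    the bipartite TF-gene graph.

    Phases of local best-gain node moves alternate with community
    aggregation until no move improves M; the best of ``n_restarts`` seeded
    restarts is returned.  When nothing beats the trivial state (D <= 0
    everywhere), all nodes are returned as a single community.
    """
    rng = rng if rng is not None else np.random.default_rng()
    Dm = np.nan_to_num(D.to_numpy(), nan=0.0)
    n_tf, n_gene = Dm.shape
    if norm is None:
        norm = float(np.abs(Dm).sum())
        if norm == 0:
            norm = 1.0

    best: tuple[float, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        labels = _louvain_bipartite(Dm, rng)
        score = partition_score(Dm, labels[:n_tf], labels[n_tf:], norm)
        if best is None or score > best[0]:
            best = (score, labels)
    score, labels = best

    if score <= 0:
        # degenerate: no community structure exceeds the baseline expectation
        labels = np.zeros(n_tf + n_gene, dtype=int)
        score = partition_score(Dm, labels[:n_tf], labels[n_tf:], norm)

    labels = _relabel(labels)
    tf_comm, gene_comm = labels[:n_tf], labels[n_tf:]
    contribution = _node_contributions(Dm, tf_comm, gene_comm, norm, D.index, D.columns)
    return ModulePartition(
        tf_ids=list(D.index),
        gene_ids=list(D.columns),
        tf_community=tf_comm,
        gene_community=gene_comm,
        score=score,
        node_contribution=contribution,
    )


def _louvain_bipartite(D: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Louvain run on the bipartite weight matrix D; returns community
    labels for [TF nodes..., gene nodes...]."""
    n_tf, n_gene = D.shape
    n = n_tf + n_gene
    # adjacency between current supernodes (symmetric, bipartite weights);
    # node_groups tracks which original nodes each supernode contains
    adj = np.zeros((n, n))
    adj[:n_tf, n_tf:] = D
    adj[n_tf:, :n_tf] = D.T
    node_groups = [[i] for i in range(n)]

    while True:
        labels = _local_moves(adj, rng)
        n_comm = labels.max() + 1
        if n_comm == adj.shape[0]:
            break  # no merge happened
        # aggregate
        new_groups: list[list[int]] = [[] for _ in range(n_comm)]
        for node, lab in enumerate(labels):
            new_groups[lab].extend(node_groups[node])
        agg = np.zeros((n_comm, n_comm))
        np.add.at(agg, (labels[:, None], labels[None, :]), adj)
        adj = agg
        node_groups = new_groups
        if n_comm == 1:
            break

    out = np.empty(n, dtype=int)
    for cid, group in enumerate(node_groups):
        for orig in group:
            out[orig] = cid
    # refinement: single-node moves on the original graph escape local
    # optima created by block-level aggregation
    full = np.zeros((n, n))
    full[:n_tf, n_tf:] = D
    full[n_tf:, :n_tf] = D.T
    return _local_moves(full, rng, start=out)


def _local_moves(
    adj: np.ndarray, rng: np.random.Generator, start: np.ndarray | None = None
) -> np.ndarray:
    """Greedy best-gain local moves; within-community objective is the sum
    of adjacency weights inside communities (self-weights included once)."""
    n = adj.shape[0]
    labels = np.arange(n) if start is None else start.copy()
    improved = True
    sweep = 0
    while improved and sweep < 50:
        improved = False
        sweep += 1
        for node in rng.permutation(n):
            row = adj[node]
            cur = labels[node]
            # weight from this node to each community; the gain of moving to
            # community c is member_w[c] - member_w[cur] (self-loop excluded,
            # it is unaffected by the move)
            member_w = np.bincount(labels, weights=row, minlength=n)
            member_w[cur] -= row[node]
            loss = member_w[cur]
            member_w[cur] = -np.inf
            best_c = int(np.argmax(member_w))
            if member_w[best_c] - loss > 1e-12:
                labels[node] = best_c
                improved = True
    return _relabel(labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    uniq = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in uniq:
            uniq[lab] = len(uniq)
        out[i] = uniq[lab]
    return out


def _node_contributions(D, tf_comm, gene_comm, norm, tf_ids, gene_ids) -> dict[str, float]:
    """Each node's share of M: half the within-community weight incident to
    it (so contributions sum to M)."""
    same = tf_comm[:, None] == gene_comm[None, :]
    within = D * same
    contrib: dict[str, float] = {}
    tf_share = within.sum(axis=1) / (2.0 * norm)
    gene_share = within.sum(axis=0) / (2.0 * norm)
    for t, v in zip(tf_ids, tf_share):
        contrib[t] = float(v)
    for g, v in zip(gene_ids, gene_share):
        contrib[g] = float(v)
    return contrib


def filter_modules(
    partition: ModulePartition, min_tfs: int = 1, min_genes: int = 5
) -> list[Module]:
    """Modules with at least ``min_tfs`` TFs and ``min_genes`` genes; the
    raw partition is left untouched."""
    return [
        m
        for m in partition.modules()
        if len(m.tfs) >= min_tfs and len(m.genes) >= min_genes
    ]


def match_modules(
    modules_a: Sequence[Module], modules_b: Sequence[Module]
) -> list[ModuleMatch]:
    """Best jaccard match (on gene sets) in B for every module of A;
    jaccard >= 0.5 classifies the module as shared between tissues."""
    out = []
    for ma in modules_a:
        sa = set(ma.genes)
        best_j, best_id = 0.0, None
        for mb in modules_b:
            sb = set(mb.genes)
            union = sa | sb
            j = len(sa & sb) / len(union) if union else 0.0
            if j > best_j or best_id is None:
                best_j, best_id = j, mb.module_id
        klass = "shared" if best_j >= 0.5 else "specific"
        out.append(ModuleMatch(ma.module_id, best_id, best_j, klass))
    return out


def top_connected_genes(
    module: Module, tissue_network: TissueNetwork, k: int = 100
) -> list[str]:
    """Genes of a module ranked by total logEW to the module's TFs; top k,
    ties broken by gene id."""
    if not module.tfs:
        raise ValueError("module has no TFs")
    sub = tissue_network.W.loc[module.tfs, module.genes]
    totals = sub.sum(axis=0)
    ranked = sorted(module.genes, key=lambda g: (-totals[g], g))
    return ranked[:k]
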