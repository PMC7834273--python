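"""Build the binary TF x gene prior network from enhancer-gene proximity
and enhancer TFBS content.

A gene is a potential target of a TF when the TF has a retained binding
site in an enhancer whose boundary lies within a fixed window (default
250 kb) of the gene's TSS, regardless of gene orientation.  Each prior
edge is witnessed by one or more (TF, enhancer, gene) triples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import Enhancer, GeneModel, tss_distance
from .motif_scan import MotifHit

__all__ = [
    "PriorNetwork",
    "PriorSummary",
    "assign_targets",
    "build_prior",
    "summarize_prior",
    "write_prior_tsv",
]

DEFAULT_WINDOW = 250_000


@dataclass
class PriorNetwork:
    tf_ids: list[str]
    gene_ids: list[str]
    prior: np.ndarray  # TF x gene, {0,1}
    triples: list[tuple[str, str, str]]  # (tf, enhancer, gene)

    def __post_init__(self):
        assert self.prior.shape == (len(self.tf_ids), len(self.gene_ids))

    @property
    def n_edges(self) -> int:
        return int(self.prior.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.prior, index=self.tf_ids, columns=self.gene_ids)

    def enhancer_tfs(self) -> dict[str, set[str]]:
        """Distinct TFs with a retained hit per enhancer (from triples)."""
        out: dict[str, set[str]] = {}
        for tf, enh, _ in self.triples:
            out.setdefault(enh, set()).add(tf)
        return out

    def enhancer_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for _, enh, gene in self.triples:
            out.setdefault(enh, set()).add(gene)
        return out


@dataclass
class PriorSummary:
    enhancers_per_gene: pd.Series
    genes_per_enhancer: pd.Series
    tfs_per_gene: pd.Series
    genes_per_tf: pd.Series
    prop_single_enhancer: float
    prop_double_enhancer: float
    prop_multi_enhancer: float


def assign_targets(
    enhancers: Sequence[Enhancer],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> dict[str, list[str]]:
    """Candidate target genes per enhancer: every gene whose TSS lies within
    ``window`` bp (inclusive) of the enhancer boundary, orientation ignored.
    A TSS inside the enhancer counts as distance 0."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    out: dict[str, list[str]] = {}
    for enh in enhancers:
        hits = []
        for g in by_chrom.get(enh.interval.chrom, []):
            if tss_distance(enh.interval, g.tss) <= window:
                hits.append(g.gene_id)
        out[enh.enhancer_id] = sorted(hits)
    return out


def build_prior(
    targets: Mapping[str, Sequence[str]],
    retained_hits: Iterable[MotifHit],
    expressed_tfs: set[str],
    motif_to_tf: Mapping[str, str] | None = None,
) -> PriorNetwork:
    """Assemble the prior from enhancer->gene candidates and retained
    (q-filtered) motif hits.

    Enhancers with no hit from an expressed TF contribute nothing; TFs with
    zero surviving edges are dropped.  ``motif_to_tf`` maps hit motif ids to
    TF names (identity when omitted).
    """
    tf_by_enh: dict[str, set[str]] = {}
    for h in retained_hits:
        tf = motif_to_tf[h.motif_id] if motif_to_tf else h.motif_id
        if tf in expressed_tfs:
            tf_by_enh.setdefault(h.enhancer_id, set()).add(tf)

    triples: list[tuple[str, str, str]] = []
    for enh_id, tfs in sorted(tf_by_enh.items()):
        genes = targets.get(enh_id, [])
        for tf in sorted(tfs):
            for gene in genes:
                triples.append((tf, enh_id, gene))

    if not triples:
        raise ValueError("empty prior: no expressed-TF hit maps to any target gene")

    tf_ids = sorted({t for t, _, _ in triples})
    gene_ids = sorted({g for _, _, g in triples})
    tf_idx = {t: i for i, t in enumerate(tf_ids)}
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    prior = np.zeros((len(tf_ids), len(gene_ids)))
    for tf, _, gene in triples:
        prior[tf_idx[tf], gene_idx[gene]] = 1.0
    return PriorNetwork(tf_ids, gene_ids, prior, triples)


def summarize_prior(prior: PriorNetwork) -> PriorSummary:
    if prior.n_edges == 0:
        raise ValueError("cannot summarize an empty prior")
    enh_genes = prior.enhancer_genes()
    gene_enhancers: dict[str, set[str]] = {}
    for enh, genes in enh_genes.items():
        for g in genes:
            gene_enhancers.setdefault(g, set()).add(enh)

    enhancers_per_gene = pd.Series(
        {g: len(e) for g, e in gene_enhancers.items()}, dtype=int
    ).sort_index()
    genes_per_enhancer = pd.Series(
        {e: len(g) for e, g in enh_genes.items()}, dtype=int
    ).sort_index()
    tfs_per_gene = pd.Series(
        prior.prior.sum(axis=0), index=prior.gene_ids, dtype=int
    )
    genes_per_tf = pd.Series(
        prior.prior.sum(axis=1), index=prior.tf_ids, dtype=int
    )
    genes_per_tf = genes_per_tf[genes_per_tf > 0]

    n_genes = len(enhancers_per_gene)
    single = float((enhancers_per_gene == 1).sum()) / n_genes
    double = float((enhancers_per_gene == 2).sum()) / n_genes
    multi = float((enhancers_per_gene >= 3).sum()) / n_genes
    return PriorSummary(
        enhancers_per_gene=enhancers_per_gene,
        genes_per_enhancer=genes_per_enhancer,
        tfs_per_gene=tfs_per_gene,
        genes_per_tf=genes_per_tf,
        prop_single_enhancer=single,
        prop_double_enhancer=double,
        prop_multi_enhancer=multi,
    )


def write_prior_tsv(prior: PriorNetwork, edges_path, triples_path=None) -> None:
    with open(edges_path, "w") as fh:
        fh.write("tf\tgene\tweight\n")
        for i, tf in enumerate(prior.tf_ids):
            for j, gene in enumerate(prior.gene_ids):
                if prior.prior[i, j]:
                    fh.write(f"{tf}\t{gene}\t1\n")
    if triples_path is not None:
        with open(triples_path, "w") as fh:
            fh.write("tf\tenhancer\tgene\n")
            for tf, enh, gene in prior.triples:
                fh.write(f"{tf}\t{enh}\t{gene}\n")
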