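"""Score enhancer-gene pairs by average edge weight and call each
enhancer's most likely target gene.

For an enhancer e with T_e distinct TFs having a retained binding site in
it, the score of a candidate gene g is avgEW = (1/T_e) * sum over those
TFs of logEW(t, g) in one tissue network.  The top target of the enhancer
is the candidate with the highest avgEW; a call is "flanking" when the top
target is one of the two TSS-nearest genes (one per side) of the enhancer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genomic_io import Enhancer, GeneModel, tss_distance
from .module_detection import TissueNetwork
from .prior_builder import PriorNetwork

__all__ = [
    "EnhancerGeneScore",
    "TopTarget",
    "score_pairs",
    "call_top_targets",
    "flanking_fraction",
    "flanking_genes",
]


@dataclass
class EnhancerGeneScore:
    enhancer_id: str
    gene_id: str
    avgEW: float
    T_e: int


@dataclass
class TopTarget:
    enhancer_id: str
    gene_id: str
    is_flanking: bool


def score_pairs(
    tissue_network: TissueNetwork,
    prior: PriorNetwork,
) -> list[EnhancerGeneScore]:
    """avgEW for every (enhancer, candidate gene) pair witnessed by the
    prior's triples; each TF counts once regardless of hit multiplicity."""
    W = tissue_network.W
    enh_tfs = prior.enhancer_tfs()
    enh_genes = prior.enhancer_genes()
    scores: list[EnhancerGeneScore] = []
    for enh_id in sorted(enh_genes):
        tfs = sorted(enh_tfs.get(enh_id, ()))
        if not tfs:
            raise AssertionError(
                f"enhancer {enh_id} has candidate genes but no TFs; "
                "it should have been dropped upstream"
            )
        sub = W.loc[tfs]
        for gene in sorted(enh_genes[enh_id]):
            avg = float(sub[gene].mean())
            scores.append(EnhancerGeneScore(enh_id, gene, avg, len(tfs)))
    return scores


def flanking_genes(
    enhancer: Enhancer, genes: Sequence[GeneModel]
) -> set[str]:
    """The (up to) two TSS-nearest genes of an enhancer, one per side;
    genes whose TSS lies inside the enhancer count as flanking."""
    inside: list[tuple[int, str]] = []
    left: list[tuple[int, str]] = []
    right: list[tuple[int, str]] = []
    iv = enhancer.interval
    for g in genes:
        if g.interval.chrom != iv.chrom:
            continue
        d = tss_distance(iv, g.tss)
        if d == 0:
            inside.append((0, g.gene_id))
        elif g.tss < iv.start:
            left.append((d, g.gene_id))
        else:
            right.append((d, g.gene_id))
    out = {gid for _, gid in inside}
    for side in (left, right):
        if side:
            out.add(min(side)[1])
    return out


def call_top_targets(
    scores: Sequence[EnhancerGeneScore],
    enhancers: Sequence[Enhancer],
    genes: Sequence[GeneModel],
) -> list[TopTarget]:
    """Per enhancer, the candidate gene with maximal avgEW; ties broken by
    smaller TSS distance, then by gene id."""
    enh_by_id = {e.enhancer_id: e for e in enhancers}
    gene_by_id = {g.gene_id: g for g in genes}
    by_enh: dict[str, list[EnhancerGeneScore]] = {}
    for s in scores:
        by_enh.setdefault(s.enhancer_id, []).append(s)

    out: list[TopTarget] = []
    for enh_id in sorted(by_enh):
        enh = enh_by_id[enh_id]

        def _key(s: EnhancerGeneScore):
            d = tss_distance(enh.interval, gene_by_id[s.gene_id].tss)
            return (-s.avgEW, d, s.gene_id)

        best = min(by_enh[enh_id], key=_key)
        flank = flanking_genes(enh, genes)
        out.append(TopTarget(enh_id, best.gene_id, best.gene_id in flank))
    return out


def flanking_fraction(top_targets: Sequence[TopTarget]) -> float:
    """Fraction of enhancers whose top target is an immediately flanking
    gene."""
    if not top_targets:
        raise ValueError("no top targets")
    return sum(t.is_flanking for t in top_targets) / len(top_targets)


def scores_to_frame(scores: Sequence[EnhancerGeneScore]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "enhancer": [s.enhancer_id for s in scores],
            "gene": [s.gene_id for s in scores],
            "avgEW": [s.avgEW for s in scores],
            "T_e": [s.T_e for s in scores],
        }
    )
    df["rank"] = df.groupby("enhancer")["avgEW"].rank(ascending=False, method="first")
    return df
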