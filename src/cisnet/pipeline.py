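"""End-to-end orchestration: from a synthetic (or on-disk) dataset through
motif scanning, prior construction, network inference, differential
targeting, module detection, enhancer scoring and TE analysis, with a
summary report.

The in-memory entry point is :func:`run_all`; the CLI wraps stage-wise
execution with on-disk artifacts and manifest-based caching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import (
    differential_targeting as dt,
    enhancer_scoring as es,
    expression_prep as ep,
    module_detection as md,
    motif_scan as ms,
    network_inference as ni,
    prior_builder as pb,
    te_enrichment as te,
)
from .genomic_io import ExpressionMatrix
from .synthetic_data import SyntheticDataset

__all__ = ["PipelineParams", "PipelineResult", "run_all", "report"]


@dataclass
class PipelineParams:
    """All thresholds of the analysis, with their conventional defaults."""

    scan_p: float = 1e-4  # scanner reporting threshold
    hit_q: float = 0.01  # TFBS retention q-value cutoff
    window: int = 250_000  # enhancer-TSS candidate window, bp
    fdr: float = 0.05  # differential-targeting gene-call threshold
    jaccard: float = 0.5  # shared/specific module classification
    min_module_tfs: int = 1
    min_module_genes: int = 5
    alpha: float = 0.1  # message-passing update rate
    tol: float = 1e-3
    max_iter: int = 200
    coverage_shuffles: int = 100  # per-enhancer dinucleotide shuffles
    te_resamples: int = 200  # matched-interval chi-squared resamples
    kmer_range: tuple[int, int] = (9, 15)
    kmer_e: float = 1e-4
    elim_cutoff: float = 0.01
    contrast: tuple[str, str] = ("husk", "v2ist")
    seed: int = 0


@dataclass
class PipelineResult:
    params: PipelineParams
    retained_hits: list = field(default_factory=list)
    coverage: list = field(default_factory=list)
    enrichment: dict = field(default_factory=dict)
    prior: object = None
    prior_summary: object = None
    expression: object = None  # normalized, batch-corrected, log scale
    sample_networks: list = field(default_factory=list)
    tissue_networks: dict = field(default_factory=dict)
    edge_fits: list = field(default_factory=list)
    gene_calls: list = field(default_factory=list)
    partitions: dict = field(default_factory=dict)  # tissue -> ModulePartition
    modules: dict = field(default_factory=dict)  # tissue -> filtered [Module]
    matches: dict = field(default_factory=dict)  # tissue -> [ModuleMatch]
    scores: dict = field(default_factory=dict)  # tissue -> [EnhancerGeneScore]
    top_targets: dict = field(default_factory=dict)  # tissue -> [TopTarget]
    te_overlap: list = field(default_factory=list)
    te_chisq: object = None
    kmer_motifs: list = field(default_factory=list)


def scan_stage(
    dataset: SyntheticDataset, params: PipelineParams, rng: np.random.Generator,
    run_coverage: bool = True,
) -> tuple[list, list, dict]:
    """PWM scan of all enhancer sequences; retention at q < hit_q; coverage
    significance against dinucleotide shuffles; differential enrichment of
    husk-specific vs the second tissue's specific enhancers."""
    sequences = {e.enhancer_id: e.sequence for e in dataset.enhancers}
    background = ms.batch_background(sequences.values())
    pwms = [ms.build_log_odds(m, background) for m in dataset.motifs]
    hits = ms.scan_batch(sequences, pwms, p_threshold=params.scan_p)
    retained = [h for h in hits if h.q_value < params.hit_q]

    coverage = []
    if run_coverage:
        for enh in dataset.enhancers:
            coverage.append(
                ms.coverage_significance(
                    enh, pwms, n_shuffles=params.coverage_shuffles, rng=rng,
                    p_threshold=params.scan_p,
                )
            )

    by_seq: dict[str, set[str]] = {e.enhancer_id: set() for e in dataset.enhancers}
    for h in retained:
        by_seq[h.enhancer_id].add(h.motif_id)
    primary = {
        e.enhancer_id: by_seq[e.enhancer_id]
        for e in dataset.enhancers
        if e.tissue_class == "husk_specific"
    }
    background_set = {
        e.enhancer_id: by_seq[e.enhancer_id]
        for e in dataset.enhancers
        if e.tissue_class == "v2ist_specific"
    }
    enrichment = ms.differential_enrichment(
        primary, background_set, [m.motif_id for m in dataset.motifs]
    )
    return retained, coverage, enrichment


def prior_stage(
    dataset: SyntheticDataset,
    retained_hits: Sequence,
    params: PipelineParams,
    expressed_genes: set | None = None,
) -> tuple[pb.PriorNetwork, pb.PriorSummary, set]:
    """Candidate targets are restricted to genes surviving the expression
    filter; TFs count as expressed when their coding gene has >= 1 count in
    >= 1 sample."""
    if expressed_genes is None:
        expressed_genes = set(
            ep.filter_expressed(dataset.expression).values.index
        )
    detectable = set(
        dataset.expression.values.index[(dataset.expression.values >= 1).any(axis=1)]
    )
    motif_to_tf = {m.motif_id: m.tf_name for m in dataset.motifs}
    expressed_tfs = {
        tf for tf, gene in dataset.truth.tf_genes.items() if gene in detectable
    }
    targets = pb.assign_targets(dataset.enhancers, dataset.genes, window=params.window)
    targets = {
        enh: [g for g in genes if g in expressed_genes]
        for enh, genes in targets.items()
    }
    prior = pb.build_prior(targets, retained_hits, expressed_tfs, motif_to_tf)
    return prior, pb.summarize_prior(prior), expressed_tfs


def expression_stage(dataset: SyntheticDataset) -> ExpressionMatrix:
    filtered = ep.filter_expressed(dataset.expression)
    normalized = ep.qsmooth_normalize(filtered)
    logged = ep.log_transform(normalized)
    return ep.remove_batch(logged)


def inference_stage(
    prior: pb.PriorNetwork, expression: ExpressionMatrix, params: PipelineParams
) -> list[ni.SampleNetwork]:
    genes = [g for g in prior.gene_ids if g in expression.values.index]
    if len(genes) < len(prior.gene_ids):
        missing = set(prior.gene_ids) - set(genes)
        raise ValueError(f"prior genes missing from expression: {sorted(missing)[:5]}")
    expr = expression.values.loc[prior.gene_ids]
    return ni.lioness(
        prior.prior,
        expr,
        alpha=params.alpha,
        tol=params.tol,
        max_iter=params.max_iter,
        tf_ids=prior.tf_ids,
        gene_ids=prior.gene_ids,
    )


def module_stage(
    sample_networks: Sequence[ni.SampleNetwork],
    tissue_labels: pd.Series,
    prior: pb.PriorNetwork,
    params: PipelineParams,
    rng: np.random.Generator,
) -> tuple[dict, dict, dict, dict]:
    a, b = params.contrast
    nets = {
        t: md.average_replicates(sample_networks, tissue_labels, t) for t in (a, b)
    }
    partitions, modules = {}, {}
    for pert, base in ((a, b), (b, a)):
        D = md.diff_modularity_matrix(nets[pert], nets[base])
        part = md.detect_modules(D, rng=rng)
        partitions[pert] = part
        modules[pert] = md.filter_modules(
            part, min_tfs=params.min_module_tfs, min_genes=params.min_module_genes
        )
    matches = {
        a: md.match_modules(modules[a], modules[b]),
        b: md.match_modules(modules[b], modules[a]),
    }
    return nets, partitions, modules, matches


def scoring_stage(
    tissue_networks: dict,
    prior: pb.PriorNetwork,
    dataset: SyntheticDataset,
) -> tuple[dict, dict]:
    scores, tops = {}, {}
    for tissue, net in tissue_networks.items():
        sc = es.score_pairs(net, prior)
        scores[tissue] = sc
        tops[tissue] = es.call_top_targets(sc, dataset.enhancers, dataset.genes)
    return scores, tops


def te_stage(
    dataset: SyntheticDataset, params: PipelineParams, rng: np.random.Generator
) -> tuple[list, object, list]:
    subjects = {e.enhancer_id: e.interval for e in dataset.enhancers}
    overlap = te.annotate_overlap(subjects, dataset.te_features, level="order")

    by_class: dict[str, dict] = {}
    for e in dataset.enhancers:
        by_class.setdefault(e.tissue_class, {})[e.enhancer_id] = e.interval
    chisq = te.resampled_chisq(
        by_class,
        dataset.te_features,
        dataset.chrom_lengths,
        dataset.genes,
        n=params.te_resamples,
        rng=rng,
        level="order",
    )

    # k-mer discovery in MITE sequences overlapping husk-specific enhancers,
    # against dinucleotide-shuffled backgrounds
    husk = [e for e in dataset.enhancers if e.tissue_class == "husk_specific"]
    mite_seqs = []
    for t in dataset.te_features:
        if t.te_order != "MITE":
            continue
        if any(t.interval.overlaps(e.interval) for e in husk):
            seq = dataset.genome[t.interval.chrom][t.interval.start : t.interval.end]
            mite_seqs.append(seq)
    kmers = []
    if mite_seqs:
        background = [
            ms.dinuc_shuffle_segmented(s, rng) for s in mite_seqs for _ in range(2)
        ]
        kmers = te.kmer_enrichment(
            mite_seqs, background, k_range=params.kmer_range,
            e_threshold=params.kmer_e,
        )
    return overlap, chisq, kmers


def run_all(
    dataset: SyntheticDataset,
    params: PipelineParams | None = None,
    run_coverage: bool = True,
    run_te: bool = True,
) -> PipelineResult:
    params = params if params is not None else PipelineParams()
    rng = np.random.default_rng(params.seed)
    result = PipelineResult(params=params)

    result.retained_hits, result.coverage, result.enrichment = scan_stage(
        dataset, params, rng, run_coverage=run_coverage
    )
    result.expression = expression_stage(dataset)
    result.prior, result.prior_summary, _ = prior_stage(
        dataset, result.retained_hits, params,
        expressed_genes=set(result.expression.values.index),
    )
    result.sample_networks = inference_stage(result.prior, result.expression, params)

    tissue_labels = result.expression.tissue
    result.edge_fits = dt.fit_edge_models(
        result.sample_networks, tissue_labels, contrast=params.contrast
    )
    result.gene_calls = dt.call_genes(result.edge_fits, q_threshold=params.fdr)

    (
        result.tissue_networks,
        result.partitions,
        result.modules,
        result.matches,
    ) = module_stage(result.sample_networks, tissue_labels, result.prior, params, rng)

    result.scores, result.top_targets = scoring_stage(
        result.tissue_networks, result.prior, dataset
    )

    if run_te:
        result.te_overlap, result.te_chisq, result.kmer_motifs = te_stage(
            dataset, params, rng
        )
    return result


def report(result: PipelineResult, dataset: SyntheticDataset) -> dict:
    """Paper-style summary statistics of a pipeline run."""
    summary = result.prior_summary
    calls_up = [c for c in result.gene_calls if c.direction == "husk_up"]
    calls_down = [c for c in result.gene_calls if c.direction == "v2ist_up"]
    a, b = result.params.contrast

    out = {
        "prior": {
            "n_tfs": len(result.prior.tf_ids),
            "n_genes": len(result.prior.gene_ids),
            "n_edges": result.prior.n_edges,
            "mean_targets_per_enhancer": float(summary.genes_per_enhancer.mean()),
            "mean_tfs_per_gene": float(summary.tfs_per_gene.mean()),
            "mean_genes_per_tf": float(summary.genes_per_tf.mean()),
            "prop_single_enhancer": summary.prop_single_enhancer,
            "prop_double_enhancer": summary.prop_double_enhancer,
            "prop_multi_enhancer": summary.prop_multi_enhancer,
        },
        "scan": {
            "n_retained_hits": len(result.retained_hits),
            "n_enhancers_with_hits": len(
                {h.enhancer_id for h in result.retained_hits}
            ),
            "n_significant_coverage": sum(
                1 for c in result.coverage if c.empirical_p <= 0.05
            ),
        },
        "differential_targeting": {
            "n_genes_up_" + a: len(calls_up),
            "n_genes_up_" + b: len(calls_down),
            "n_edges_tested": len(result.edge_fits),
        },
        "modules": {
            t: {
                "n_detected": len(result.partitions[t].modules()),
                "n_retained": len(result.modules[t]),
                "n_shared": sum(1 for m in result.matches[t] if m.klass == "shared"),
                "n_specific": sum(
                    1 for m in result.matches[t] if m.klass == "specific"
                ),
            }
            for t in result.modules
        },
        "top_targets": {
            t: {
                "n_enhancers": len(tt),
                "flanking_fraction": es.flanking_fraction(tt),
            }
            for t, tt in result.top_targets.items()
        },
    }
    if result.te_chisq is not None:
        out["te"] = {
            "observed_chi2": result.te_chisq.observed_chi2,
            "empirical_p": result.te_chisq.empirical_p,
            "n_discovered_motifs": len(result.kmer_motifs),
        }
    return out
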