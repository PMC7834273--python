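"""Synthetic multi-chromosome dataset with full ground truth.

The generator emulates the data shapes of an enhancer-aware regulatory
study: a small genome with evenly spaced genes, enhancers lying within
250 kb of their target genes' TSSs, TE features partially overlapping
enhancers (MITE-like elements carrying a planted 15-mer), sharp planted
PWM instances inside enhancers, and a tissue x replicate expression matrix
whose co-expression follows planted TF-gene modules.

Planted modules occupy contiguous "territories" of consecutive gene slots,
with the module's enhancers confined to the territory interior so the
250-kb candidate windows mostly contain module genes — the way regulatory
domains concentrate around their enhancers.  Expression is built on the
log2 scale: gene baseline, plus a per-sample module latent shared by the
module's genes in the tissues where the module is active (sign-flipped for
the targets of a repressor TF), plus a batch shift and lognormal noise;
counts are round(2^x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    Enhancer,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    MotifMatrix,
    TEFeature,
)

__all__ = [
    "ModulePlan",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_genome",
    "plant_enhancers",
    "simulate_expression",
    "generate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ModulePlan:
    module_id: str
    tf_names: list[str]
    n_genes: int
    n_enhancers: int
    active_tissues: list[str]
    effect: float
    repressor: bool = False
    tissue_class: str = "shared"


@dataclass
class SyntheticConfig:
    """Default scale: 3 x 12 Mb chromosomes, 1,200 genes at ~30 kb spacing
    (about 17 candidate genes per 250-kb enhancer window), 120 enhancers,
    33 TF motifs, 8 planted modules, 13 tissues / 45 samples."""

    seed: int = 0
    n_chrom: int = 3
    chrom_length: int = 12_000_000
    genes_per_chrom: int = 400
    gene_length: int = 2_000
    n_tfs: int = 64
    tfs_per_module: int = 6
    motif_length_range: tuple[int, int] = (13, 16)
    motif_dominant_prob: float = 0.98
    n_instances_per_tf: int = 2  # homotypic site pairs per enhancer
    n_background_enhancers: int = 90
    enhancer_length_range: tuple[int, int] = (600, 1800)
    module_block_genes: int = 60
    module_enhancers: int = 10
    module_interior_margin: int = 5  # gene slots kept enhancer-free at block edges
    effect: float = 2.0
    latent_mean: float = 1.0
    latent_sd: float = 0.5
    noise_sd: float = 0.25
    baseline_range: tuple[float, float] = (3.0, 8.0)
    batch_shift: float = 0.8
    gc: float = 0.47
    # tissues: the two contrasted ones get 6 replicates, the rest 3 (45 total)
    tissues: tuple[str, ...] = (
        "husk", "v2ist", "leaf", "root", "internode", "silk", "tassel",
        "ear", "seed17", "seed35", "hypocotyl", "endosperm", "embryo",
    )
    replicates: tuple[int, ...] = (6, 6, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3)
    n_te: int = 200
    te_frac_overlap: float = 0.4
    te_length_range: tuple[int, int] = (200, 2500)
    mite_15mer: str = "GTCACGTGACTTGCA"
    n_unexpressed_tfs: int = 1
    window: int = 250_000

    @classmethod
    def small(cls, seed: int = 0) -> "SyntheticConfig":
        """Reduced geometry (3 x 3 Mb, 480 genes, 44 enhancers, 20 TFs) for
        fast smoke runs; same module structure and tissue design."""
        return cls(
            seed=seed,
            chrom_length=3_000_000,
            genes_per_chrom=160,
            gene_length=1_000,
            n_tfs=20,
            tfs_per_module=2,
            n_background_enhancers=12,
            enhancer_length_range=(400, 900),
            module_block_genes=20,
            module_enhancers=4,
            module_interior_margin=3,
            n_te=60,
        )

    def module_plans(self) -> list[ModulePlan]:
        """8 modules: 3 specific to each contrasted tissue (one with a
        repressor TF on each side, keeping total activation balanced
        between the contrasted tissues), 2 shared."""
        plans = []
        specs = [
            ("H1", ["husk"], "husk_specific", False),
            ("H2", ["husk"], "husk_specific", False),
            ("H3", ["husk"], "husk_specific", True),
            ("V1", ["v2ist"], "v2ist_specific", False),
            ("V2", ["v2ist"], "v2ist_specific", False),
            ("V3", ["v2ist"], "v2ist_specific", True),
            ("S1", ["husk", "v2ist", "leaf"], "shared", False),
            ("S2", ["husk", "v2ist", "root"], "shared", False),
        ]
        k = self.tfs_per_module
        for i, (mid, tissues, klass, repressor) in enumerate(specs):
            plans.append(
                ModulePlan(
                    module_id=mid,
                    tf_names=[f"TF{k * i + j + 1:03d}" for j in range(k)],
                    n_genes=self.module_block_genes,
                    n_enhancers=self.module_enhancers,
                    active_tissues=list(tissues),
                    effect=self.effect,
                    repressor=repressor,
                    tissue_class=klass,
                )
            )
        return plans


@dataclass
class GroundTruth:
    enhancer_targets: dict  # enhancer id -> list of true target gene ids
    modules: list  # dicts: module_id, tfs, genes, enhancers, tissues, repressor
    diff_genes: dict  # tissue -> genes more strongly targeted there
    motif_instances: list  # (enhancer_id, motif_id, start_in_enhancer, strand)
    te_placements: list  # (chrom, start, end, order, superfamily, family)
    batch_labels: dict  # sample -> batch
    tf_genes: dict  # TF name -> coding gene id
    unexpressed_tfs: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["motif_instances"] = [tuple(x) for x in d["motif_instances"]]
        d["te_placements"] = [tuple(x) for x in d["te_placements"]]
        return cls(**d)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict  # chrom -> sequence string
    genes: list  # GeneModel
    enhancers: list  # Enhancer, sequences populated
    te_features: list  # TEFeature
    motifs: list  # MotifMatrix
    expression: ExpressionMatrix
    truth: GroundTruth

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


# ---------------------------------------------------------------------------
# genome scaffold


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _make_motif(rng: np.random.Generator, motif_id: str, tf_name: str,
                length: int, dominant: float) -> MotifMatrix:
    counts = np.zeros((4, length))
    total = 100
    for j in range(length):
        dom = int(rng.integers(4))
        base = np.full(4, total * (1 - dominant) / 3)
        base[dom] = total * dominant
        counts[:, j] = base
    return MotifMatrix(motif_id, counts, tf_name=tf_name)


def _sample_motif_instance(rng: np.random.Generator, motif: MotifMatrix) -> str:
    freqs = motif.counts / motif.counts.sum(axis=0, keepdims=True)
    return "".join(
        "ACGT"[rng.choice(4, p=freqs[:, j])] for j in range(motif.length)
    )


@dataclass
class _Layout:
    """Gene grid and module block assignment shared by the generator steps."""

    gene_positions: dict  # gene_id -> (chrom, slot, tss)
    module_blocks: dict  # module_id -> (chrom, first_slot, last_slot)
    spacing: int


def _build_layout(config: SyntheticConfig) -> _Layout:
    spacing = config.chrom_length // (config.genes_per_chrom + 1)
    if spacing <= config.gene_length + 1000:
        raise ValueError("gene placement too dense for the chromosome length")
    gene_positions: dict[str, tuple[str, int, int]] = {}
    gid = 0
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        for slot in range(config.genes_per_chrom):
            tss = (slot + 1) * spacing
            gene_positions[f"g{gid:05d}"] = (chrom, slot, tss)
            gid += 1

    plans = config.module_plans()
    block = config.module_block_genes
    gap = 10  # background slots between blocks (> window / spacing)
    module_blocks: dict[str, tuple[str, int, int]] = {}
    per_chrom = max(1, int(np.ceil(len(plans) / config.n_chrom)))
    idx = 0
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        start_slot = 20
        for _ in range(per_chrom):
            if idx >= len(plans):
                break
            end_slot = start_slot + block - 1
            if end_slot >= config.genes_per_chrom - 20:
                raise ValueError("module blocks do not fit on the chromosome")
            module_blocks[plans[idx].module_id] = (chrom, start_slot, end_slot)
            start_slot = end_slot + 1 + gap + int(np.ceil(
                config.window / (config.chrom_length // (config.genes_per_chrom + 1))
            ))
            idx += 1
    if idx < len(plans):
        raise ValueError("not all module blocks could be placed")
    return _Layout(gene_positions, module_blocks, spacing)


def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict, list[GeneModel], _Layout]:
    """Random background genome with genes placed on an even grid (strands
    alternating); returns mutable chromosome arrays for later planting."""
    layout = _build_layout(config)
    genome = {
        f"chr{c + 1}": _random_sequence(rng, config.chrom_length, config.gc)
        for c in range(config.n_chrom)
    }
    genes: list[GeneModel] = []
    for gene_id, (chrom, slot, tss) in layout.gene_positions.items():
        strand = "+" if slot % 2 == 0 else "-"
        if strand == "+":
            iv = GenomicInterval(chrom, tss, tss + config.gene_length, strand, gene_id)
        else:
            iv = GenomicInterval(chrom, tss - config.gene_length + 1, tss + 1, strand, gene_id)
        genes.append(GeneModel(gene_id, iv))
    return genome, genes, layout


# ---------------------------------------------------------------------------
# enhancers and motif planting


def plant_enhancers(
    config: SyntheticConfig,
    rng: np.random.Generator,
    genome: dict,
    layout: _Layout,
    motifs: list[MotifMatrix],
) -> tuple[list[Enhancer], list, dict]:
    """Place module enhancers inside module-block interiors and background
    enhancers in inter-block space; write sampled PWM instances into the
    genome.  Returns enhancers (sequences filled in later), planted motif
    instance records, and the enhancer -> module map."""
    plans = {p.module_id: p for p in config.module_plans()}
    motif_by_tf = {m.tf_name: m for m in motifs}
    spacing = layout.spacing

    enhancers: list[Enhancer] = []
    instances: list[tuple[str, str, int, str]] = []
    enhancer_module: dict[str, str] = {}
    eid = 0

    def _place_between_slots(chrom: str, slot: int, length: int) -> GenomicInterval:
        # between gene at `slot` and gene at `slot + 1`, clear of gene bodies
        lo = (slot + 1) * spacing + config.gene_length + 500
        hi = (slot + 2) * spacing - config.gene_length - 500 - length
        start = int(rng.integers(lo, max(lo + 1, hi)))
        return GenomicInterval(chrom, start, start + length)

    for module_id, (chrom, first, last) in layout.module_blocks.items():
        plan = plans[module_id]
        margin = config.module_interior_margin
        interior = list(range(first + margin, last - margin))
        slots = rng.choice(interior, size=plan.n_enhancers, replace=False)
        for slot in np.sort(slots):
            length = int(rng.integers(*config.enhancer_length_range))
            iv = _place_between_slots(chrom, int(slot), length)
            enh_id = f"e{eid:04d}"
            eid += 1
            enh = Enhancer(enh_id, iv, plan.tissue_class)
            enhancers.append(enh)
            enhancer_module[enh_id] = module_id
            # homotypic instances of each module TF's motif, non-overlapping
            offset = int(rng.integers(10, 40))
            for tf in plan.tf_names:
                motif = motif_by_tf[tf]
                for _ in range(config.n_instances_per_tf):
                    site = _sample_motif_instance(rng, motif)
                    strand = "+" if rng.random() < 0.5 else "-"
                    written = site if strand == "+" else _revcomp(site)
                    pos = iv.start + offset
                    if pos + len(written) > iv.end:
                        raise ValueError(
                            "enhancer too short for the planted site load; "
                            "increase enhancer_length_range"
                        )
                    genome[chrom][pos : pos + len(written)] = np.frombuffer(
                        written.encode(), dtype=np.uint8
                    )
                    instances.append((enh_id, motif.motif_id, offset, strand))
                    offset += motif.length + int(rng.integers(5, 20))

    # background enhancers with decoy-TF motifs, outside module windows
    decoy_tfs = [m for m in motifs if not any(
        m.tf_name in p.tf_names for p in plans.values()
    )]
    # background enhancers stay out of the blocks themselves (plus a small
    # buffer); their 250-kb windows may still reach module genes, which
    # yields realistic decoy-TF edges onto module genes
    blocked = {}
    for chrom, first, last in layout.module_blocks.values():
        blocked.setdefault(chrom, []).append((first - 2, last + 2))
    chrom_names = sorted(genome)
    for _ in range(config.n_background_enhancers):
        for _try in range(100):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            slot = int(rng.integers(5, config.genes_per_chrom - 6))
            if any(a <= slot <= b for a, b in blocked.get(chrom, ())):
                continue
            break
        length = int(rng.integers(*config.enhancer_length_range))
        iv = _place_between_slots(chrom, slot, length)
        enh_id = f"e{eid:04d}"
        eid += 1
        klass = ("husk_specific", "v2ist_specific", "shared")[int(rng.integers(3))]
        enhancers.append(Enhancer(enh_id, iv, klass))
        enhancer_module[enh_id] = ""
        offset = int(rng.integers(10, 40))
        n_decoy = min(4, len(decoy_tfs))
        for motif in rng.choice(len(decoy_tfs), size=n_decoy, replace=False):
            m = decoy_tfs[int(motif)]
            for _ in range(config.n_instances_per_tf):
                site = _sample_motif_instance(rng, m)
                strand = "+" if rng.random() < 0.5 else "-"
                written = site if strand == "+" else _revcomp(site)
                pos = iv.start + offset
                if pos + len(written) > iv.end:
                    raise ValueError(
                        "enhancer too short for the planted site load; "
                        "increase enhancer_length_range"
                    )
                genome[iv.chrom][pos : pos + len(written)] = np.frombuffer(
                    written.encode(), dtype=np.uint8
                )
                instances.append((enh_id, m.motif_id, offset, strand))
                offset += m.length + int(rng.integers(5, 20))
    return enhancers, instances, enhancer_module


def _revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# transposable elements


def _place_tes(
    config: SyntheticConfig,
    rng: np.random.Generator,
    genome: dict,
    enhancers: list,
) -> list[TEFeature]:
    """TE features: a configured fraction overlap enhancers (MITEs biased
    toward husk-specific enhancers); MITE-like elements carry the planted
    15-mer."""
    plan = [
        ("TIR", ("DTM", "DTC", "DTH"), 0.3),
        ("LTR", ("RLG", "RLC"), 0.3),
        ("MITE", ("Pif/Harbinger", "Tourist", "Stowaway"), 0.4),
    ]
    chrom_names = sorted(genome)
    husk_enh = [e for e in enhancers if e.tissue_class == "husk_specific"]
    out: list[TEFeature] = []
    fam_counter = 0
    for order, superfamilies, order_frac in plan:
        n = int(round(config.n_te * order_frac))
        for i in range(n):
            length = int(rng.integers(*config.te_length_range))
            if order == "MITE":
                length = int(rng.integers(150, 600))  # MITEs are short
            overlap = rng.random() < config.te_frac_overlap
            if overlap and enhancers:
                pool = husk_enh if (order == "MITE" and rng.random() < 0.8 and husk_enh) else enhancers
                enh = pool[int(rng.integers(len(pool)))]
                anchor = int(
                    rng.integers(
                        max(0, enh.interval.start - length + 50),
                        enh.interval.end - 50,
                    )
                )
                chrom = enh.interval.chrom
                start = max(0, anchor)
            else:
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                start = int(rng.integers(0, len(genome[chrom]) - length))
            end = min(start + length, len(genome[chrom]))
            if order == "MITE":
                # Pif/Harbinger-like families dominate the MITE complement
                sf = superfamilies[int(rng.choice(3, p=[0.7, 0.2, 0.1]))]
            else:
                sf = superfamilies[int(rng.integers(len(superfamilies)))]
            fam = f"{sf.replace('/', '')}{fam_counter:04d}"
            fam_counter += 1
            out.append(
                TEFeature(GenomicInterval(chrom, start, end), order, sf, fam)
            )
            if order == "MITE" and sf == "Pif/Harbinger":
                kmer = config.mite_15mer.encode()
                pos = start + 5
                if pos + len(kmer) < end:
                    genome[chrom][pos : pos + len(kmer)] = np.frombuffer(
                        kmer, dtype=np.uint8
                    )
    return out


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SyntheticConfig,
    rng: np.random.Generator,
    gene_ids: Sequence[str],
    module_genes: dict,
    tf_genes: dict,
    unexpressed_tfs: Sequence[str],
) -> ExpressionMatrix:
    """Counts matrix on the configured tissue x replicate design.

    log2 expression = baseline + sum over modules active in the sample's
    tissue of effect * latent(sample), shared by the module's genes
    (negated for a repressor module's targets), plus the batch shift and
    Gaussian log-scale (lognormal) noise; counts = round(2^x).
    """
    plans = {p.module_id: p for p in config.module_plans()}
    samples, tissues, reps, batches = [], [], [], []
    for tissue, n_rep in zip(config.tissues, config.replicates):
        for r in range(1, n_rep + 1):
            samples.append(f"{tissue}_{r}")
            tissues.append(tissue)
            reps.append(str(r))
            batches.append("PE" if r % 2 == 1 else "SE")

    n_genes, n_samples = len(gene_ids), len(samples)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    baseline = rng.uniform(*config.baseline_range, size=n_genes)
    X = np.tile(baseline[:, None], (1, n_samples))

    for module_id, plan in plans.items():
        rows = np.array([gene_index[g] for g in module_genes[module_id]])
        tf_rows = np.array([gene_index[tf_genes[t]] for t in plan.tf_names])
        sign = -1.0 if plan.repressor else 1.0
        for s, tissue in enumerate(tissues):
            if tissue not in plan.active_tissues:
                continue
            latent = rng.normal(config.latent_mean, config.latent_sd)
            X[rows, s] += sign * plan.effect * latent
            X[tf_rows, s] += plan.effect * latent

    shift = np.array([config.batch_shift if b == "SE" else 0.0 for b in batches])
    X += shift[None, :]
    X += rng.normal(0.0, config.noise_sd, size=X.shape)

    for tf in unexpressed_tfs:
        X[gene_index[tf_genes[tf]], :] = -10.0  # rounds to zero counts

    counts = np.round(np.power(2.0, X)).astype(int)
    values = pd.DataFrame(counts, index=list(gene_ids), columns=samples)
    meta_index = pd.Index(samples)
    return ExpressionMatrix(
        values=values,
        tissue=pd.Series(tissues, index=meta_index),
        batch=pd.Series(batches, index=meta_index),
        replicate=pd.Series(reps, index=meta_index),
    )


# ---------------------------------------------------------------------------
# top-level generation


def generate_dataset(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate the full dataset deterministically from config.seed (or the
    ``seed`` override)."""
    config = config if config is not None else SyntheticConfig()
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)

    # motif library: module TFs first (TF001..TF016), then decoys
    motifs = []
    for i in range(config.n_tfs):
        tf = f"TF{i + 1:03d}"
        length = int(rng.integers(*config.motif_length_range))
        motifs.append(
            _make_motif(rng, f"M{i + 1:03d}", tf, length, config.motif_dominant_prob)
        )

    genome, genes, layout = generate_genome(config, rng)
    enhancers, instances, enhancer_module = plant_enhancers(
        config, rng, genome, layout, motifs
    )
    te_features = _place_tes(config, rng, genome, enhancers)

    # finalize genome to strings and fill enhancer sequences
    genome_str = {c: arr.tobytes().decode("ascii") for c, arr in genome.items()}
    for enh in enhancers:
        enh.sequence = genome_str[enh.interval.chrom][
            enh.interval.start : enh.interval.end
        ]

    # module gene sets from the layout blocks
    slot_to_gene = {
        (chrom, slot): gid for gid, (chrom, slot, _) in layout.gene_positions.items()
    }
    module_genes: dict[str, list[str]] = {}
    for module_id, (chrom, first, last) in layout.module_blocks.items():
        module_genes[module_id] = [
            slot_to_gene[(chrom, s)] for s in range(first, last + 1)
        ]

    # TF coding genes: background genes well away from module blocks
    plans = config.module_plans()
    used = {g for gs in module_genes.values() for g in gs}
    background_genes = [g.gene_id for g in genes if g.gene_id not in used]
    tf_gene_ids = list(
        np.array(background_genes)[
            rng.choice(len(background_genes), size=config.n_tfs, replace=False)
        ]
    )
    tf_genes = {f"TF{i + 1:03d}": tf_gene_ids[i] for i in range(config.n_tfs)}
    unexpressed = [f"TF{config.n_tfs - i:03d}" for i in range(config.n_unexpressed_tfs)]

    expression = simulate_expression(
        config,
        rng,
        [g.gene_id for g in genes],
        module_genes,
        tf_genes,
        unexpressed,
    )

    # ground truth
    gene_tss = {g.gene_id: g.tss for g in genes}
    from .genomic_io import tss_distance

    gene_by_id = {g.gene_id: g for g in genes}
    enhancer_targets: dict[str, list[str]] = {}
    for enh in enhancers:
        mod = enhancer_module[enh.enhancer_id]
        if not mod:
            continue
        targets = [
            g
            for g in module_genes[mod]
            if tss_distance(enh.interval, gene_tss[g]) <= config.window
        ]
        enhancer_targets[enh.enhancer_id] = sorted(targets)

    diff_genes = {"husk": [], "v2ist": []}
    modules_truth = []
    for plan in plans:
        modules_truth.append(
            {
                "module_id": plan.module_id,
                "tfs": plan.tf_names,
                "genes": module_genes[plan.module_id],
                "enhancers": sorted(
                    e for e, m in enhancer_module.items() if m == plan.module_id
                ),
                "tissues": plan.active_tissues,
                "repressor": plan.repressor,
                "tissue_class": plan.tissue_class,
            }
        )
        # expected direction of differential targeting: an activator module
        # raises edge weights in its active tissue; a repressor module's
        # targets anti-correlate with the TF there, so their inferred edge
        # weights are LOWER in the active tissue than elsewhere
        if plan.tissue_class == "husk_specific":
            key = "v2ist" if plan.repressor else "husk"
            diff_genes[key].extend(module_genes[plan.module_id])
        elif plan.tissue_class == "v2ist_specific":
            key = "husk" if plan.repressor else "v2ist"
            diff_genes[key].extend(module_genes[plan.module_id])

    truth = GroundTruth(
        enhancer_targets=enhancer_targets,
        modules=modules_truth,
        diff_genes=diff_genes,
        motif_instances=instances,
        te_placements=[
            (t.interval.chrom, t.interval.start, t.interval.end, t.te_order,
             t.te_superfamily, t.te_family)
            for t in te_features
        ],
        batch_labels=dict(
            zip(expression.sample_ids, expression.batch.loc[expression.sample_ids])
        ),
        tf_genes=tf_genes,
        unexpressed_tfs=unexpressed,
    )
    return SyntheticDataset(
        config=config,
        genome=genome_str,
        genes=genes,
        enhancers=enhancers,
        te_features=te_features,
        motifs=motifs,
        expression=expression,
        truth=truth,
    )
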