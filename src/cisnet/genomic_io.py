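"""Readers, writers and coordinate arithmetic for the genomic formats the
pipeline touches.

All coordinates are held internally as 0-based half-open intervals; GFF3
(1-based inclusive) is converted at the boundary.  BED columns 2/3 are taken
verbatim as 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Enhancer",
    "TEFeature",
    "MotifMatrix",
    "ExpressionMatrix",
    "TE_VOCABULARY",
    "read_intervals",
    "write_bed",
    "read_gene_tss",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_fasta",
    "write_fasta",
    "extract_sequences",
    "nearest_tss_distance",
    "read_expression_tsv",
]

TISSUE_CLASSES = ("husk_specific", "v2ist_specific", "shared")

# Controlled vocabulary for transposable-element annotation: order -> superfamilies.
TE_VOCABULARY: dict[str, tuple[str, ...]] = {
    "TIR": ("DTM", "DTC", "DTH", "DTT", "DTA"),
    "LTR": ("RLG", "RLC", "RLX"),
    "MITE": ("Pif/Harbinger", "Tourist", "Stowaway"),
    "LINE": ("RIL", "RIT"),
    "Helitron": ("DHH",),
}
_SUPERFAMILY_TO_ORDER = {sf: order for order, sfs in TE_VOCABULARY.items() for sf in sfs}


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    attributes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene with a strand-derived transcription start site.

    TSS is interval.start on the + strand and interval.end - 1 on the -
    strand (0-based position of the first transcribed base).
    """

    gene_id: str
    interval: GenomicInterval
    tss: int = -1

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand required to define TSS")
        expected = (
            self.interval.start if self.interval.strand == "+" else self.interval.end - 1
        )
        if self.tss == -1:
            object.__setattr__(self, "tss", expected)
        elif self.tss != expected:
            raise ValueError(f"gene {self.gene_id}: tss inconsistent with strand")


@dataclass
class Enhancer:
    enhancer_id: str
    interval: GenomicInterval
    tissue_class: str
    sequence: str | None = None

    def __post_init__(self):
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        if self.sequence is not None and len(self.sequence) != self.interval.length:
            raise ValueError(
                f"enhancer {self.enhancer_id}: sequence length "
                f"{len(self.sequence)} != interval length {self.interval.length}"
            )


@dataclass(frozen=True)
class TEFeature:
    interval: GenomicInterval
    te_order: str
    te_superfamily: str
    te_family: str

    def __post_init__(self):
        if self.te_order not in TE_VOCABULARY:
            raise ValueError(f"unknown TE order {self.te_order!r}")
        if self.te_superfamily not in TE_VOCABULARY[self.te_order]:
            raise ValueError(
                f"superfamily {self.te_superfamily!r} not in order {self.te_order}"
            )


@dataclass
class MotifMatrix:
    """Position frequency matrix of base counts, rows ordered A, C, G, T."""

    motif_id: str
    counts: np.ndarray
    tf_name: str = ""
    tf_family: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"motif {self.motif_id}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id}: L >= 1 required")
        if np.any(self.counts < 0):
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError(f"motif {self.motif_id}: column with zero total count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata."""

    values: pd.DataFrame  # genes x samples
    tissue: pd.Series  # indexed by sample
    batch: pd.Series
    replicate: pd.Series | None = None

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicated gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated sample ids")
        for meta, label in ((self.tissue, "tissue"), (self.batch, "batch")):
            missing = set(self.values.columns) - set(meta.index)
            if missing:
                raise ValueError(f"samples missing {label} label: {sorted(missing)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# readers / writers


def read_intervals(path, format: str = "BED"):
    """Read a BED file into GenomicInterval objects, or a TE table into
    TEFeature objects.

    The TE table dialect is a tab table with columns
    chrom, start, end, te_order, te_superfamily, te_family (header optional,
    detected from the first line).
    """
    path = Path(path)
    if format == "BED":
        return _read_bed(path)
    if format == "TE_table":
        return _read_te_table(path)
    raise ValueError(f"unknown interval format {format!r}")


def _read_bed(path: Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            try:
                iv = GenomicInterval(
                    fields[0], start, end, strand, name,
                    attributes={"extra": fields[6:]} if len(fields) > 6 else {},
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def _read_te_table(path: Path) -> list[TEFeature]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] in ("chrom", "chr"):  # header row
                continue
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 TE-table columns")
            chrom, start, end, order, superfamily, family = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if order in ("", ".") and superfamily in _SUPERFAMILY_TO_ORDER:
                order = _SUPERFAMILY_TO_ORDER[superfamily]
            try:
                out.append(TEFeature(iv, order, superfamily, family))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_gene_tss(path) -> list[GeneModel]:
    """Read gene features from a GFF3 file, deriving the TSS from strand.

    GFF3 coordinates are 1-based inclusive and converted to 0-based
    half-open on read.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != "gene":
                continue
            chrom, start1, end1, strand = fields[0], fields[3], fields[4], fields[6]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: gene without strand (TSS undefined)"
                )
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: gene without ID attribute")
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand, gene_id)
            genes.append(GeneModel(gene_id, iv))
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tcisnet\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )


def read_jaspar_pfm(path) -> list[MotifMatrix]:
    """Read JASPAR-style position frequency matrices.

    Accepts both the bracketed 4-row format::

        >MA0001.1 AGL3
        A [ 0 3 79 ... ]
        C [94 75 4 ... ]
        ...

    and the plain 4-row count format without base labels.
    """
    motifs: list[MotifMatrix] = []
    header = None
    rows: list[tuple[str | None, list[float]]] = []

    def _flush():
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise ValueError(f"motif {header[0]}: expected 4 base rows, got {len(rows)}")
        labels = [r[0] for r in rows]
        if all(lab is not None for lab in labels):
            if sorted(labels) != ["A", "C", "G", "T"]:
                raise ValueError(f"motif {header[0]}: missing base row in {labels}")
            order = [labels.index(b) for b in "ACGT"]
        else:
            order = [0, 1, 2, 3]  # unlabeled rows assumed A,C,G,T
        counts = np.array([rows[i][1] for i in order], dtype=float)
        motifs.append(MotifMatrix(header[0], counts, tf_name=header[1]))
        header, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else "")
            else:
                label = None
                body = line
                if line[0] in "ACGTacgt" and (len(line) == 1 or not line[1].isdigit()):
                    label = line[0].upper()
                    body = line[1:]
                body = body.replace("[", " ").replace("]", " ")
                try:
                    values = [float(x) for x in body.split()]
                except ValueError as exc:
                    raise ValueError(f"non-numeric count in motif block: {line!r}") from exc
                rows.append((label, values))
    _flush()
    return motifs


def write_jaspar_pfm(motifs: Iterable[MotifMatrix], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            name = f" {m.tf_name}" if m.tf_name else ""
            fh.write(f">{m.motif_id}{name}\n")
            for base, row in zip("ACGT", m.counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def extract_sequences(intervals: Sequence[GenomicInterval], genome: dict[str, str]) -> list[str]:
    """Extract interval sequences from a genome dict (chrom -> sequence)."""
    out = []
    for iv in intervals:
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom} not in genome")
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end")
        out.append(chrom_seq[iv.start : iv.end])
    return out


def nearest_tss_distance(
    interval: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[int, str]:
    """Distance from an interval to the nearest gene TSS on its chromosome.

    A TSS inside [start, end) gives distance 0; otherwise the distance is
    from the TSS to the nearer interval boundary.  Ties are broken by the
    lexicographically smaller gene_id.  Strand of the interval is ignored.
    """
    candidates = [g for g in genes if g.interval.chrom == interval.chrom]
    if not candidates:
        raise ValueError(f"no genes on chromosome {interval.chrom}")
    best: tuple[int, str] | None = None
    for g in candidates:
        d = tss_distance(interval, g.tss)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    return best


def tss_distance(interval: GenomicInterval, tss: int) -> int:
    """Boundary-to-TSS distance; 0 when the TSS lies within the interval."""
    if interval.start <= tss < interval.end:
        return 0
    if tss < interval.start:
        return interval.start - tss
    return tss - interval.end


def read_expression_tsv(counts_path, metadata_path) -> ExpressionMatrix:
    """Read a genes x samples counts TSV plus a sample metadata TSV with
    columns sample_id, tissue, replicate, batch."""
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    for col in ("tissue", "batch"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
    meta = meta.loc[values.columns]
    return ExpressionMatrix(
        values=values,
        tissue=meta["tissue"],
        batch=meta["batch"],
        replicate=meta["replicate"] if "replicate" in meta.columns else None,
    )


def write_expression_tsv(expr: ExpressionMatrix, counts_path, metadata_path) -> None:
    expr.values.to_csv(counts_path, sep="\t")
    meta = pd.DataFrame(
        {
            "tissue": expr.tissue,
            "replicate": expr.replicate
            if expr.replicate is not None
            else pd.Series("1", index=expr.tissue.index),
            "batch": expr.batch,
        }
    )
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")
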