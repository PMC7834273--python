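import numpy as np
import pytest

from cisnet import genomic_io as gio


def test_bed_coordinates_are_half_open(tmp_path):
    bed = tmp_path / "a.bed"
    bed.write_text("chr1\t100\t200\te1\n")
    (iv,) = gio.read_intervals(bed)
    assert (iv.chrom, iv.start, iv.end, iv.name) == ("chr1", 100, 200, "e1")
    assert iv.length == 100


def test_bed_reversed_coordinates_error(tmp_path):
    bed = tmp_path / "a.bed"
    bed.write_text("chr1\t200\t100\n")
    with pytest.raises(ValueError, match="1"):  # error names the line
        gio.read_intervals(bed)


def test_bed_roundtrip_preserves_coordinates(tmp_path):
    intervals = [
        gio.GenomicInterval("chr1", 5, 50, "+", "a"),
        gio.GenomicInterval("chr2", 0, 7, "-", "b"),
    ]
    path = tmp_path / "rt.bed"
    gio.write_bed(intervals, path)
    back = gio.read_intervals(path)
    assert [(i.chrom, i.start, i.end, i.strand, i.name) for i in back] == [
        (i.chrom, i.start, i.end, i.strand, i.name) for i in intervals
    ]


def test_te_table_vocabulary(tmp_path):
    path = tmp_path / "te.tsv"
    path.write_text(
        "chrom\tstart\tend\tte_order\tte_superfamily\tte_family\n"
        "chr1\t10\t500\tTIR\tDTM\tDTM001\n"
    )
    (te,) = gio.read_intervals(path, format="TE_table")
    assert te.te_order == "TIR" and te.te_superfamily == "DTM"
    bad = tmp_path / "bad.tsv"
    bad.write_text("chr1\t10\t500\tTIR\tRLG\tX\n")  # RLG is an LTR superfamily
    with pytest.raises(ValueError):
        gio.read_intervals(bad, format="TE_table")


def test_gff3_tss_from_strand(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tx\tgene\t101\t200\t.\t+\t.\tID=gp\n"
        "chr1\tx\tgene\t101\t200\t.\t-\t.\tID=gm\n"
    )
    genes = {g.gene_id: g for g in gio.read_gene_tss(gff)}
    assert genes["gp"].interval.start == 100 and genes["gp"].tss == 100
    assert genes["gm"].interval.end == 200 and genes["gm"].tss == 199


@pytest.mark.parametrize(
    "body,err",
    [
        ("chr1\tx\tgene\t101\t200\t.\t.\t.\tID=g1\n", "strand"),
        ("chr1\tx\tgene\t101\t200\t.\t+\t.\tID=g1\nchr1\tx\tgene\t301\t400\t.\t+\t.\tID=g1\n", "duplicate"),
    ],
)
def test_gff3_errors(tmp_path, body, err):
    gff = tmp_path / "g.gff3"
    gff.write_text(body)
    with pytest.raises(ValueError, match=err):
        gio.read_gene_tss(gff)


def test_jaspar_read_write_roundtrip(tmp_path):
    path = tmp_path / "m.pfm"
    path.write_text(
        ">MA0001.1 TF1\n"
        "A [ 1 2 3 4 5 6 7 8 ]\n"
        "C [ 0 1 0 1 0 1 0 1 ]\n"
        "G [ 2 2 2 2 2 2 2 2 ]\n"
        "T [ 1 0 1 0 1 0 1 0 ]\n"
        ">MA0002.1 TF2\n"
        "A [ 9 0 ]\nC [ 0 9 ]\nG [ 1 1 ]\nT [ 0 0 ]\n"
    )
    motifs = gio.read_jaspar_pfm(path)
    assert [m.motif_id for m in motifs] == ["MA0001.1", "MA0002.1"]
    assert motifs[0].length == 8 and motifs[1].length == 2
    out = tmp_path / "out.pfm"
    gio.write_jaspar_pfm(motifs, out)
    again = gio.read_jaspar_pfm(out)
    np.testing.assert_array_equal(again[0].counts, motifs[0].counts)


def test_jaspar_zero_column_rejected(tmp_path):
    path = tmp_path / "z.pfm"
    path.write_text(">M1\nA [ 1 0 ]\nC [ 1 0 ]\nG [ 1 0 ]\nT [ 1 0 ]\n")
    with pytest.raises(ValueError, match="zero"):
        gio.read_jaspar_pfm(path)


def _gene(gene_id, chrom, tss, strand="+"):
    if strand == "+":
        iv = gio.GenomicInterval(chrom, tss, tss + 100, "+", gene_id)
    else:
        iv = gio.GenomicInterval(chrom, tss - 99, tss + 1, "-", gene_id)
    return gio.GeneModel(gene_id, iv)


@pytest.mark.parametrize(
    "tss_list,expected",
    [
        ([1500], (0, "g0")),  # containment
        ([2500], (500, "g0")),
        ([500, 2600], (500, "g0")),  # min(500, 600)
    ],
)
def test_nearest_tss_distance(tss_list, expected):
    iv = gio.GenomicInterval("chr1", 1000, 2000)
    genes = [_gene(f"g{i}", "chr1", t) for i, t in enumerate(tss_list)]
    assert gio.nearest_tss_distance(iv, genes) == expected


def test_nearest_tss_no_genes_on_chrom_is_an_error():
    iv = gio.GenomicInterval("chr9", 0, 10)
    with pytest.raises(ValueError, match="chr9"):
        gio.nearest_tss_distance(iv, [_gene("g0", "chr1", 5)])


def test_nearest_tss_ignores_interval_strand():
    genes = [_gene("g0", "chr1", 5000, "-")]
    a = gio.nearest_tss_distance(gio.GenomicInterval("chr1", 1000, 2000, "+"), genes)
    b = gio.nearest_tss_distance(gio.GenomicInterval("chr1", 1000, 2000, "-"), genes)
    assert a == b


def test_extract_sequences_matches_interval_length():
    genome = {"chr1": "ACGTACGTACGT"}
    ivs = [gio.GenomicInterval("chr1", 2, 7)]
    (seq,) = gio.extract_sequences(ivs, genome)
    assert seq == "GTACG" and len(seq) == ivs[0].length


def test_expression_matrix_rejects_duplicates():
    import pandas as pd

    values = pd.DataFrame(
        [[1, 2], [3, 4]], index=["g1", "g1"], columns=["s1", "s2"]
    )
    meta = pd.Series(["t1", "t2"], index=["s1", "s2"])
    with pytest.raises(ValueError, match="duplicated gene"):
        gio.ExpressionMatrix(values, meta, meta)
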