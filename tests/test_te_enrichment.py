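import numpy as np
import pytest

from cisnet import te_enrichment as te
from cisnet.genomic_io import GeneModel, GenomicInterval, MotifMatrix, TEFeature
from cisnet.motif_scan import revcomp


def _te(chrom, start, end, order="TIR", sf="DTM", fam="f1"):
    return TEFeature(GenomicInterval(chrom, start, end), order, sf, fam)


def test_annotate_overlap_categories():
    subjects = {
        "full": GenomicInterval("chr1", 100, 200),
        "none": GenomicInterval("chr1", 10_000, 10_100),
        "multi": GenomicInterval("chr1", 500, 700),
    }
    tes = [
        _te("chr1", 0, 300),  # covers "full"
        _te("chr1", 450, 600, order="TIR"),
        _te("chr1", 650, 800, order="LTR", sf="RLG"),
    ]
    out = {o.subject_id: o for o in te.annotate_overlap(subjects, tes)}
    assert out["full"].te_category == "TIR" and out["full"].covered_fraction == 1.0
    assert out["none"].te_category == "None" and out["none"].covered_fraction == 0.0
    assert out["multi"].te_category == "Multiple"
    assert out["multi"].covered_fraction == pytest.approx((100 + 50) / 200)


def _grid_genes(chrom_lengths, step=40_000):
    genes, gid = [], 0
    for chrom, length in chrom_lengths.items():
        for pos in range(20_000, length - 500, step):
            genes.append(
                GeneModel(
                    gid and f"g{gid}" or "g0",
                    GenomicInterval(chrom, pos, pos + 500, "+", f"g{gid}"),
                )
            )
            gid += 1
    return genes


def test_sample_matched_constraints_and_determinism():
    chrom_lengths = {"chr1": 500_000, "chr2": 500_000}
    genes = _grid_genes(chrom_lengths)
    subjects = {
        "a": GenomicInterval("chr1", 100_000, 100_300),
        "b": GenomicInterval("chr2", 250_000, 251_000),
    }
    from cisnet.genomic_io import nearest_tss_distance

    out1 = te.sample_matched(subjects, chrom_lengths, genes, np.random.default_rng(0))
    out2 = te.sample_matched(subjects, chrom_lengths, genes, np.random.default_rng(0))
    for sid, iv in out1.items():
        orig = subjects[sid]
        assert iv.length == orig.length
        assert iv.chrom == orig.chrom
        d_orig, _ = nearest_tss_distance(orig, genes)
        d_new, _ = nearest_tss_distance(iv, genes)
        assert te._log2_bin(d_new) == te._log2_bin(d_orig)
        # determinism under the same seed
        assert (out2[sid].start, out2[sid].end) == (iv.start, iv.end)


def test_chisq_odds_ratio_and_degenerate_table():
    tab = np.array([[20.0, 80.0], [10.0, 90.0]])
    a, b, c, d = 20, 80, 10, 90
    assert (a * d) / (b * c) == pytest.approx(2.25)
    # observed equal to expected proportions -> chi2 = 0
    assert te._pearson_chi2(np.array([[10, 20], [20, 40]])) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        te._pearson_chi2(np.zeros((2, 2)))


def test_resampled_chisq_enrichment_detected():
    """TEs piled onto one class's intervals: small empirical p and OR > 1."""
    rng = np.random.default_rng(1)
    chrom_lengths = {"chr1": 600_000}
    genes = _grid_genes(chrom_lengths)
    husk, v2 = {}, {}
    for i in range(15):
        start = 30_000 + i * 35_000
        husk[f"h{i}"] = GenomicInterval("chr1", start, start + 400)
        v2[f"v{i}"] = GenomicInterval("chr1", start + 5_000, start + 5_400)
    tes = [
        _te("chr1", iv.start - 50, iv.end + 50, order="MITE", sf="Tourist")
        for iv in husk.values()
    ]
    result = te.resampled_chisq(
        {"husk_specific": husk, "v2ist_specific": v2},
        tes, chrom_lengths, genes, n=99, rng=rng, level="order",
    )
    assert result.empirical_p <= 0.05
    assert result.odds_ratios[("husk_specific", "MITE")] > 1


def test_kmer_canonical_collapse_and_identical_sets():
    seqs = ["ACGTACGTACGTACG" * 2] * 5
    assert te.canonical_kmer("ACGTACGTA") == te.canonical_kmer(revcomp("ACGTACGTA"))
    out = te.kmer_enrichment(seqs, seqs, k_range=(9, 9), e_threshold=1e-4)
    assert out == []


def test_kmer_planted_motif_recovered():
    rng = np.random.default_rng(2)
    planted = "GTCACGTGACTTGCA"  # 15-mer
    targets, background = [], []
    for i in range(30):
        bg = "".join("ACGT"[j] for j in rng.integers(0, 4, 120))
        targets.append(bg[:50] + planted + bg[50:])
        background.append("".join("ACGT"[j] for j in rng.integers(0, 4, 135)))
    motifs = te.kmer_enrichment(targets, background, k_range=(15, 15))
    assert motifs
    best = motifs[0]
    assert best.e_value <= 1e-4
    canon = te.canonical_kmer(planted)
    assert any(te.canonical_kmer(m) == canon for m in best.members)


def test_kmer_longer_than_sequences_warns():
    with pytest.warns(UserWarning, match="skipped"):
        out = te.kmer_enrichment(["ACGTACGT"], ["TTTTACGT"], k_range=(9, 9))
    assert out == []


def _kmer_motif(seq):
    counts = np.zeros((4, len(seq)))
    for j, b in enumerate(seq):
        counts["ACGT".index(b), j] = 10
    counts += 0.5
    return te.KmerMotif(seq, counts, p=1e-6, e_value=1e-5, members=[seq])


def test_compare_to_known_identical_and_revcomp():
    seq = "GTCACGTTGACGT"
    cand = _kmer_motif(seq)
    known = [MotifMatrix("MA1", _kmer_motif(seq).counts)]
    (hit,) = te.compare_to_known(cand, known, rng=np.random.default_rng(3), n_perm=500)
    assert hit.score > 0.95
    assert hit.p_value <= 0.01
    rc = _kmer_motif(revcomp(seq))
    (hit_rc,) = te.compare_to_known(rc, known, rng=np.random.default_rng(3), n_perm=500)
    assert hit_rc.score == pytest.approx(hit.score, abs=1e-9)


def test_compare_to_known_uniform_candidate_skipped():
    counts = np.full((4, 10), 2.0)
    cand = te.KmerMotif("N" * 10, counts, p=1e-6, e_value=1e-5)
    out = te.compare_to_known(
        cand, [MotifMatrix("MA1", np.full((4, 10), 3.0))],
        rng=np.random.default_rng(4), n_perm=50,
    )
    assert out == []  # all columns zero-variance -> comparison skipped


def test_superfamily_association_odds_ratio():
    presence = {"motifX": {}}
    labels = {}
    eid = 0
    for sf, pres, n in [("Pif/Harbinger", True, 20), ("Pif/Harbinger", False, 5),
                        ("Tourist", True, 10), ("Tourist", False, 40)]:
        for _ in range(n):
            presence["motifX"][f"e{eid}"] = pres
            labels[f"e{eid}"] = sf
            eid += 1
    res = te.superfamily_association(presence, labels)
    r = res[("motifX", "Pif/Harbinger")]
    assert r["odds_ratio"] == pytest.approx((20 * 40) / (5 * 10))
    assert res[("motifX", "Tourist")]["odds_ratio"] < 1
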