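import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from cisnet import motif_scan as ms
from cisnet.genomic_io import Enhancer, GenomicInterval, MotifMatrix


def _pfm(counts, motif_id="m"):
    return MotifMatrix(motif_id, np.asarray(counts, dtype=float))


def test_log_odds_formula():
    # column counts (8,0,0,0), pseudocount 0.1, uniform background:
    # freq_A = (8 + 0.1*0.25) / (8 + 0.1); log2(freq/0.25) ~ 1.9866
    pfm = _pfm([[8.0], [0.0], [0.0], [0.0]])
    pwm = ms.build_log_odds(pfm, pseudocount=0.1)
    expected = np.log2((8.025 / 8.1) / 0.25)
    assert abs(pwm.log_odds[0, 0] - expected) < 1e-9
    assert abs(expected - 1.987) < 1e-3


def test_log_odds_uniform_counts_are_zero():
    pwm = ms.build_log_odds(_pfm([[5, 5], [5, 5], [5, 5], [5, 5]]))
    np.testing.assert_allclose(pwm.log_odds, 0.0, atol=1e-12)


def test_log_odds_requires_positive_pseudocount_and_background():
    with pytest.raises(ValueError):
        ms.build_log_odds(_pfm([[1], [1], [1], [1]]), pseudocount=0.0)
    with pytest.raises(ValueError):
        ms.build_log_odds(
            _pfm([[1], [1], [1], [1]]), background=[0.5, 0.5, 0.0, 0.0]
        )


def test_pvalue_single_column_max():
    pwm = ms.build_log_odds(_pfm([[9], [0], [0], [0]]))
    max_score = int(pwm.int_scores.max())
    assert float(pwm.pvalue(max_score)) == 0.25
    table = ms.score_pvalue_table(pwm)
    assert table["p"][0] == 1.0  # minimum score has tail probability 1
    assert np.all(np.diff(table["p"]) <= 1e-15)  # monotone non-increasing


def test_scan_finds_consensus_and_reverse_complement():
    counts = np.array(
        [[9, 0, 0, 0, 0, 9], [0, 9, 0, 0, 9, 0], [0, 0, 9, 9, 0, 0], [0, 0, 0, 0, 0, 0]]
    )
    pwm = ms.build_log_odds(_pfm(counts))
    consensus = pwm.consensus()
    assert consensus == "ACGGCA"
    hits = ms.scan("TT" + consensus + "TT", pwm, p_threshold=1e-3)
    assert any(h.start == 2 and h.strand == "+" for h in hits)
    rc_hits = ms.scan("TT" + ms.revcomp(consensus) + "TT", pwm, p_threshold=1e-3)
    assert any(h.start == 2 and h.strand == "-" for h in rc_hits)
    # strand symmetry: same best score
    assert max(h.score for h in hits) == max(h.score for h in rc_hits)


def test_scan_skips_n_windows_and_short_sequences():
    pwm = ms.build_log_odds(_pfm(np.full((4, 4), 2.0)))
    assert ms.scan("N" * 30, pwm, p_threshold=1.0) == []
    assert ms.scan("ACG", pwm, p_threshold=1.0) == []  # motif longer than seq


def test_batch_bh_q_matches_reference_when_all_windows_reported():
    """With the reporting threshold at 1, every scanned window is a hit and
    the in-house BH must equal the reference implementation."""
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    pwm = ms.build_log_odds(_pfm(rng.integers(1, 20, size=(4, 5))))
    hits = ms.scan_batch({"s1": seq}, [pwm], p_threshold=1.0)
    p = np.array([h.p_value for h in hits])
    q_ref = multipletests(p, method="fdr_bh")[1]
    q_ours = np.array([h.q_value for h in hits])
    np.testing.assert_allclose(q_ours, q_ref, atol=1e-12)
    # q monotone in p within the motif
    order = np.argsort(p)
    assert np.all(np.diff(q_ours[order]) >= -1e-12)


def test_dinuc_shuffle_trivial_and_errors(rng):
    assert ms.dinuc_shuffle("AAAA", rng) == "AAAA"
    with pytest.raises(ValueError):
        ms.dinuc_shuffle("A", rng)
    with pytest.raises(ValueError):
        ms.dinuc_shuffle("ACGN", rng)


def test_dinuc_shuffle_specific_counts(rng):
    seq = "ACGCGT"
    expected = {"AC": 1, "CG": 2, "GC": 1, "GT": 1}
    for _ in range(1000):
        out = ms.dinuc_shuffle(seq, rng)
        got = {}
        for a, b in zip(out, out[1:]):
            got[a + b] = got.get(a + b, 0) + 1
        assert got == expected


def test_segmented_shuffle_keeps_n_positions(rng):
    seq = "ACGTACGTNNACGT"
    out = ms.dinuc_shuffle_segmented(seq, rng)
    assert len(out) == len(seq)
    assert out[8:10] == "NN"
    assert sorted(out) == sorted(seq)


def test_coverage_significance_formula(rng):
    pwm = ms.build_log_odds(_pfm(np.full((4, 4), 2.0)))
    enh = Enhancer(
        "e1", GenomicInterval("chr1", 0, 40), "shared",
        "".join("ACGT"[i] for i in rng.integers(0, 4, 40)),
    )
    res = ms.coverage_significance(enh, [pwm], n_shuffles=1, rng=rng, p_threshold=0.0)
    # zero hits anywhere: observed coverage 0, every shuffle ties -> p = 1
    assert res.observed_coverage_bp == 0
    assert res.empirical_p == 1.0


def test_coverage_significance_detects_planted_consensus(rng):
    counts = np.zeros((4, 12))
    consensus_idx = rng.integers(0, 4, 12)
    counts[consensus_idx, np.arange(12)] = 9
    counts += 0.2
    pwm = ms.build_log_odds(MotifMatrix("m", counts))
    consensus = pwm.consensus()
    background = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    seq = background[:90] + consensus + consensus + background[90:]
    enh = Enhancer("e1", GenomicInterval("chr1", 0, len(seq)), "shared", seq)
    res = ms.coverage_significance(enh, [pwm], n_shuffles=100, rng=rng)
    assert res.observed_coverage_bp >= 12
    assert res.empirical_p <= 0.05


def test_differential_enrichment_odds_ratio_and_na():
    primary = {f"p{i}": ({"m1"} if i < 30 else set()) for i in range(100)}
    background = {f"b{i}": ({"m1"} if i < 10 else set()) for i in range(100)}
    res = ms.differential_enrichment(primary, background, ["m1", "m2"])
    assert abs(res["m1"]["odds_ratio"] - (30 * 90) / (70 * 10)) < 1e-9
    assert res["m2"]["na"] is True
    with pytest.raises(ValueError):
        ms.differential_enrichment({}, background, ["m1"])


def test_differential_enrichment_equal_rates_not_significant():
    primary = {f"p{i}": ({"m1"} if i < 20 else set()) for i in range(100)}
    background = {f"b{i}": ({"m1"} if i < 20 else set()) for i in range(100)}
    res = ms.differential_enrichment(primary, background, ["m1"])
    assert abs(res["m1"]["odds_ratio"] - 1.0) < 1e-9
    assert res["m1"]["p"] >= 0.5


def test_hits_tsv_roundtrip(tmp_path):
    hits = [
        ms.MotifHit("m1", "e1", 5, "+", 8.1, 1e-5, q_value=1e-3, length=10),
        ms.MotifHit("m2", "e2", 0, "-", 6.0, 2e-4, q_value=0.02, length=8),
    ]
    path = tmp_path / "hits.tsv"
    ms.write_hits_tsv(hits, path)
    back = ms.read_hits_tsv(path)
    assert [(h.motif_id, h.enhancer_id, h.start, h.strand, h.length) for h in back] == [
        (h.motif_id, h.enhancer_id, h.start, h.strand, h.length) for h in hits
    ]
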