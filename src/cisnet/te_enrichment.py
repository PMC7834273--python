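"""Transposable-element overlap annotation and enrichment analysis, plus
k-mer motif discovery in TE-derived sequences.

Enrichment of TE classes among tissue-specific enhancers is tested with a
Pearson chi-squared statistic whose null distribution is obtained by
resampling matched random intervals — same length, same chromosome, and
same nearest-TSS distance (log2 bin) as each observed interval — and
re-annotating them against the TE features.

Motif discovery is k-mer over-representation: sequence-level counts of
reverse-complement-collapsed k-mers, a one-sided Fisher test against
background sequences, an E-value correction by the number of k-mers tested,
and greedy merging of overlapping enriched k-mers into IUPAC consensus
motifs with count matrices.  Candidate motifs are compared to known PFMs by
mean column correlation over ungapped alignments with a column-permutation
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genomic_io import GeneModel, GenomicInterval, MotifMatrix, TEFeature
from .motif_scan import revcomp

__all__ = [
    "TEOverlap",
    "ChiSqEnrichment",
    "KmerMotif",
    "MotifComparison",
    "annotate_overlap",
    "sample_matched",
    "resampled_chisq",
    "kmer_enrichment",
    "compare_to_known",
    "superfamily_association",
]

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class TEOverlap:
    subject_id: str
    te_category: str  # an order/superfamily label, or "None"/"Multiple"
    covered_fraction: float


@dataclass
class ChiSqEnrichment:
    contingency: "np.ndarray"
    tissue_classes: list[str]
    te_classes: list[str]
    observed_chi2: float
    null_chi2: np.ndarray
    empirical_p: float
    odds_ratios: dict[tuple[str, str], float]


@dataclass
class KmerMotif:
    consensus: str
    counts: np.ndarray  # 4 x L
    p: float
    e_value: float
    members: list[str] = field(default_factory=list)
    n_target_seqs: int = 0


@dataclass
class MotifComparison:
    candidate_id: str
    known_id: str
    offset: int
    orientation: str
    score: float
    p_value: float


# ---------------------------------------------------------------------------
# overlap annotation


def _interval_union_coverage(
    subject: GenomicInterval, features: Sequence[GenomicInterval]
) -> int:
    """bp of the subject covered by the union of features."""
    spans = []
    for f in features:
        if f.chrom != subject.chrom:
            continue
        lo, hi = max(f.start, subject.start), min(f.end, subject.end)
        if lo < hi:
            spans.append((lo, hi))
    if not spans:
        return 0
    spans.sort()
    covered = 0
    cur_lo, cur_hi = spans[0]
    for lo, hi in spans[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return covered


def annotate_overlap(
    subjects: Mapping[str, GenomicInterval],
    te_features: Sequence[TEFeature],
    level: str = "order",
) -> list[TEOverlap]:
    """Annotate each subject interval with its TE overlap category.

    ``level`` selects the classification label ("order" or "superfamily").
    "None" means no TE overlap; "Multiple" means TEs from >= 2 distinct
    categories overlap the subject.
    """
    if level not in ("order", "superfamily"):
        raise ValueError("level must be 'order' or 'superfamily'")
    out = []
    for sid, iv in subjects.items():
        overlapping = [t for t in te_features if t.interval.overlaps(iv)]
        covered = _interval_union_coverage(iv, [t.interval for t in overlapping])
        frac = covered / iv.length
        cats = {
            t.te_order if level == "order" else t.te_superfamily for t in overlapping
        }
        if not cats:
            category = "None"
        elif len(cats) == 1:
            category = next(iter(cats))
        else:
            category = "Multiple"
        out.append(TEOverlap(sid, category, frac))
    return out


# ---------------------------------------------------------------------------
# matched-interval resampling


def _log2_bin(distance: int) -> int:
    return int(np.floor(np.log2(distance + 1)))


def sample_matched(
    subjects: Mapping[str, GenomicInterval],
    chrom_lengths: Mapping[str, int],
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> dict[str, GenomicInterval]:
    """Random intervals matched to each subject on length, chromosome, and
    nearest-TSS distance (same log2 bin).

    Rejection sampling up to ``max_tries`` per subject; if no candidate
    falls in the target bin, the candidate with the nearest log2 distance
    is used (nearest-feasible fallback).
    """
    from .genomic_io import nearest_tss_distance

    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.interval.chrom, [])
    for g in genes:
        tss_by_chrom[g.interval.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    def _nearest_distance(chrom: str, start: int, end: int) -> int:
        tss = tss_by_chrom.get(chrom)
        if tss is None or len(tss) == 0:
            raise ValueError(f"no genes on chromosome {chrom}")
        inside = (tss >= start) & (tss < end)
        if inside.any():
            return 0
        left = tss[tss < start]
        right = tss[tss >= end]
        cands = []
        if len(left):
            cands.append(start - left[-1])
        if len(right):
            cands.append(right[0] - end)
        return int(min(cands))

    out: dict[str, GenomicInterval] = {}
    failures = []
    for sid, iv in subjects.items():
        L = iv.length
        chrom_len = chrom_lengths[iv.chrom]
        if chrom_len < L:
            failures.append(sid)
            continue
        target_bin = _log2_bin(_nearest_distance(iv.chrom, iv.start, iv.end))
        best: tuple[int, GenomicInterval] | None = None
        found = None
        for _ in range(max_tries):
            start = int(rng.integers(0, chrom_len - L + 1))
            d = _nearest_distance(iv.chrom, start, start + L)
            b = _log2_bin(d)
            if b == target_bin:
                found = GenomicInterval(iv.chrom, start, start + L, name=sid)
                break
            gap = abs(b - target_bin)
            if best is None or gap < best[0]:
                best = (gap, GenomicInterval(iv.chrom, start, start + L, name=sid))
        if found is None:
            if best is None:
                failures.append(sid)
                continue
            found = best[1]
        out[sid] = found
    if failures:
        raise ValueError(f"could not place matched intervals for: {failures}")
    return out


def _pearson_chi2(table: np.ndarray) -> float:
    """Pearson chi-squared statistic; cells with zero expectation contribute
    nothing (their observed count is necessarily zero)."""
    table = np.asarray(table, dtype=float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0:
        raise ValueError("empty contingency table")
    expected = rowsum @ colsum / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (table - expected) ** 2 / expected
    return float(np.nansum(terms))


def resampled_chisq(
    subjects_by_class: Mapping[str, Mapping[str, GenomicInterval]],
    te_features: Sequence[TEFeature],
    chrom_lengths: Mapping[str, int],
    genes: Sequence[GeneModel],
    n: int = 1000,
    rng: np.random.Generator | None = None,
    level: str = "superfamily",
) -> ChiSqEnrichment:
    """Chi-squared test of tissue-class x TE-class association with a
    matched-resampling null.

    ``subjects_by_class`` maps tissue class -> {subject id -> interval}.
    For each of ``n`` resamples, every subject is replaced by a matched
    random interval and the chi-squared statistic recomputed;
    empirical_p = (1 + #{null >= observed}) / (n + 1).
    """
    rng = rng if rng is not None else np.random.default_rng()
    classes = sorted(subjects_by_class)
    if len(classes) < 2:
        raise ValueError("need >= 2 tissue classes")

    def _table(per_class_subjects: Mapping[str, Mapping[str, GenomicInterval]]):
        cats_per_class = {}
        for cls in classes:
            annos = annotate_overlap(per_class_subjects[cls], te_features, level=level)
            cats_per_class[cls] = [a.te_category for a in annos]
        te_classes = sorted({c for v in cats_per_class.values() for c in v})
        tab = np.zeros((len(classes), len(te_classes)))
        for i, cls in enumerate(classes):
            for cat in cats_per_class[cls]:
                tab[i, te_classes.index(cat)] += 1
        return tab, te_classes

    observed_table, te_classes = _table(subjects_by_class)
    if len(te_classes) < 2:
        raise ValueError("need >= 2 TE classes in the observed annotation")
    observed = _pearson_chi2(observed_table)

    null = np.empty(n)
    for i in range(n):
        resampled = {
            cls: sample_matched(subjects_by_class[cls], chrom_lengths, genes, rng)
            for cls in classes
        }
        tab, _ = _table(resampled)
        null[i] = _pearson_chi2(tab)
    empirical_p = (1 + int((null >= observed).sum())) / (n + 1)

    # focal-class vs rest x focal-TE vs rest odds ratios
    odds: dict[tuple[str, str], float] = {}
    total = observed_table.sum()
    for i, cls in enumerate(classes):
        for j, te in enumerate(te_classes):
            a = observed_table[i, j]
            b = observed_table[i].sum() - a
            c = observed_table[:, j].sum() - a
            d = total - a - b - c
            odds[(cls, te)] = float((a * d) / (b * c)) if b * c > 0 else float("inf")
    return ChiSqEnrichment(
        contingency=observed_table,
        tissue_classes=classes,
        te_classes=te_classes,
        observed_chi2=observed,
        null_chi2=null,
        empirical_p=empirical_p,
        odds_ratios=odds,
    )


# ---------------------------------------------------------------------------
# k-mer motif discovery


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return min(kmer, rc)


def _seqs_containing(seqs: Sequence[str], k: int) -> dict[str, int]:
    """Number of sequences containing each canonical k-mer."""
    counts: dict[str, int] = {}
    for seq in seqs:
        seen: set[str] = set()
        su = seq.upper()
        for i in range(len(su) - k + 1):
            w = su[i : i + k]
            if all(c in "ACGT" for c in w):
                seen.add(canonical_kmer(w))
        for w in seen:
            counts[w] = counts.get(w, 0) + 1
    return counts


def _kmers_similar(a: str, b: str, max_offset: int = 2) -> bool:
    """Overlapping relation used for merging: some (possibly reverse-
    complement) alignment with |offset| <= max_offset matches on at least
    len - 2 overlapping positions."""
    k = len(a)
    for cand in (b, revcomp(b)):
        for off in range(-max_offset, max_offset + 1):
            matches = 0
            overlap = 0
            for i in range(k):
                j = i + off
                if 0 <= j < k:
                    overlap += 1
                    if a[i] == cand[j]:
                        matches += 1
            if overlap and matches >= k - 2:
                return True
    return False


def _merge_to_motif(
    kmers: list[str], occurrences: Mapping[str, int]
) -> tuple[str, np.ndarray]:
    """Align members to the first (seed) k-mer at their best offset and build
    an occurrence-weighted count matrix and IUPAC consensus."""
    seed = kmers[0]
    k = len(seed)
    counts = np.zeros((4, k))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for kmer in kmers:
        best = None
        for cand in (kmer, revcomp(kmer)):
            for off in range(-2, 3):
                matches = sum(
                    1 for i in range(k) if 0 <= i + off < k and seed[i] == cand[i + off]
                )
                if best is None or matches > best[0]:
                    best = (matches, cand, off)
        _, cand, off = best
        w = occurrences.get(kmer, 1)
        for i in range(k):
            j = i + off
            if 0 <= j < k:
                counts[base_idx[cand[j]], i] += w
    consensus = []
    for col in range(k):
        colsum = counts[:, col].sum()
        if colsum == 0:
            consensus.append("N")
            continue
        present = frozenset(
            b for b, i in base_idx.items() if counts[i, col] >= 0.25 * colsum
        )
        consensus.append(_IUPAC.get(present, "N"))
    return "".join(consensus), counts


def kmer_enrichment(
    target_seqs: Sequence[str],
    background_seqs: Sequence[str],
    k_range: tuple[int, int] = (9, 15),
    e_threshold: float = 1e-4,
) -> list[KmerMotif]:
    """k-mer over-representation in target vs background sequences.

    Per k, sequence-level canonical k-mer counts are compared by a one-
    sided Fisher exact test; E = p * (number of distinct k-mers tested at
    that k).  k-mers with E <= ``e_threshold`` are greedily merged into
    IUPAC consensus motifs (seeded by the most significant k-mer).
    """
    if not target_seqs or not background_seqs:
        raise ValueError("target and background sets must be non-empty")
    n_t, n_b = len(target_seqs), len(background_seqs)
    motifs: list[KmerMotif] = []
    shortest = min(len(s) for s in list(target_seqs) + list(background_seqs))
    for k in range(k_range[0], k_range[1] + 1):
        if k > shortest:
            import warnings

            warnings.warn(f"k={k} exceeds the shortest sequence; skipped", stacklevel=2)
            continue
        t_counts = _seqs_containing(target_seqs, k)
        b_counts = _seqs_containing(background_seqs, k)
        tested = set(t_counts) | set(b_counts)
        m = len(tested)
        # one-sided Fisher == hypergeometric upper tail, vectorized over k-mers
        words = list(t_counts)
        a_vec = np.array([t_counts[w] for w in words])
        c_vec = np.array([b_counts.get(w, 0) for w in words])
        p_vec = stats.hypergeom.sf(a_vec - 1, n_t + n_b, a_vec + c_vec, n_t)
        enriched: list[tuple[float, float, str, int]] = []
        for w, a, p in zip(words, a_vec, p_vec):
            e = float(p) * m
            if e <= e_threshold:
                enriched.append((e, float(p), w, int(a)))
        enriched.sort()
        used: set[str] = set()
        for e, p, w, a in enriched:
            if w in used:
                continue
            members = [w]
            used.add(w)
            for e2, p2, w2, a2 in enriched:
                if w2 not in used and _kmers_similar(w, w2):
                    members.append(w2)
                    used.add(w2)
            occurrences = {m_: t_counts.get(m_, 1) for m_ in members}
            consensus, counts = _merge_to_motif(members, occurrences)
            motifs.append(
                KmerMotif(
                    consensus=consensus,
                    counts=counts,
                    p=p,
                    e_value=e,
                    members=members,
                    n_target_seqs=a,
                )
            )
    return motifs


# ---------------------------------------------------------------------------
# comparison of candidate motifs to known PFMs


def _column_freqs(counts: np.ndarray) -> np.ndarray:
    colsum = counts.sum(axis=0, keepdims=True)
    colsum = np.where(colsum == 0, 1.0, colsum)
    return counts / colsum


def _alignment_score(
    cand: np.ndarray, known: np.ndarray, offset: int, min_cols: int = 5
) -> float | None:
    """Mean Pearson correlation of aligned frequency columns; None when
    fewer than ``min_cols`` usable columns align (zero-variance columns are
    excluded)."""
    Lc, Lk = cand.shape[1], known.shape[1]
    cols = []
    for i in range(Lc):
        j = i + offset
        if 0 <= j < Lk:
            x, y = cand[:, i], known[:, j]
            if x.std() == 0 or y.std() == 0:
                continue
            cols.append(float(np.corrcoef(x, y)[0, 1]))
    if len(cols) < min_cols:
        return None
    return float(np.mean(cols))


def compare_to_known(
    candidate: KmerMotif,
    known: Sequence[MotifMatrix],
    rng: np.random.Generator | None = None,
    n_perm: int = 1000,
    p_threshold: float = 0.01,
    candidate_id: str = "",
) -> list[MotifComparison]:
    """Best ungapped alignment of a candidate motif against each known PFM
    (both orientations, all offsets), scored by mean column correlation;
    significance by permutation of the known motif's columns with +1
    pseudocounts.  Comparisons with p <= ``p_threshold`` are returned."""
    rng = rng if rng is not None else np.random.default_rng()
    cand_f = _column_freqs(candidate.counts)
    cand_rc = cand_f[::-1, ::-1]
    out: list[MotifComparison] = []
    cid = candidate_id or candidate.consensus
    for km in known:
        known_f = _column_freqs(km.counts)
        best: tuple[float, int, str] | None = None
        for orientation, cf in (("+", cand_f), ("-", cand_rc)):
            for offset in range(-(cf.shape[1] - 1), known_f.shape[1]):
                s = _alignment_score(cf, known_f, offset)
                if s is not None and (best is None or s > best[0]):
                    best = (s, offset, orientation)
        if best is None:
            continue
        score, offset, orientation = best
        exceed = 0
        Lk = known_f.shape[1]
        for _ in range(n_perm):
            perm = known_f[:, rng.permutation(Lk)]
            b: float | None = None
            for orientation2, cf in (("+", cand_f), ("-", cand_rc)):
                for off in range(-(cf.shape[1] - 1), Lk):
                    s = _alignment_score(cf, perm, off)
                    if s is not None and (b is None or s > b):
                        b = s
            if b is not None and b >= score:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
        if p <= p_threshold:
            out.append(MotifComparison(cid, km.motif_id, offset, orientation, score, p))
    return out


# ---------------------------------------------------------------------------
# motif x TE-superfamily association


def superfamily_association(
    motif_presence: Mapping[str, Mapping[str, bool]],
    superfamily_labels: Mapping[str, str],
) -> dict[tuple[str, str], dict]:
    """Per motif and focal superfamily, a 2x2 Fisher test of motif presence
    in that superfamily's elements vs all others.

    ``motif_presence`` maps motif id -> {element id -> bool};
    ``superfamily_labels`` maps element id -> superfamily.
    """
    superfamilies = sorted(set(superfamily_labels.values()))
    if len(superfamilies) < 2:
        raise ValueError("need >= 2 superfamilies")
    results: dict[tuple[str, str], dict] = {}
    for motif, presence in motif_presence.items():
        for sf in superfamilies:
            a = sum(
                1 for e, v in presence.items() if v and superfamily_labels[e] == sf
            )
            b = sum(
                1 for e, v in presence.items() if not v and superfamily_labels[e] == sf
            )
            c = sum(
                1 for e, v in presence.items() if v and superfamily_labels[e] != sf
            )
            d = sum(
                1 for e, v in presence.items() if not v and superfamily_labels[e] != sf
            )
            if a + b == 0 or c + d == 0 or a + c == 0:
                import warnings

                warnings.warn(
                    f"degenerate table for motif {motif} x {sf}; reported as NA",
                    stacklevel=2,
                )
                results[(motif, sf)] = {"odds_ratio": float("nan"), "p": float("nan")}
                continue
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            results[(motif, sf)] = {"odds_ratio": float(odds), "p": float(p),
                                    "table": [[a, b], [c, d]]}
    return results
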