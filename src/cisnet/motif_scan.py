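"""PWM scanning of enhancer sequences with exact p-values, BH q-values,
dinucleotide-shuffle coverage significance and differential motif
enrichment between two enhancer sets.

Scores are log2 odds of the motif model against a 0-order background,
discretized on a fixed grid so that the null score distribution — and hence
an exact p-value for every attainable score — can be computed by dynamic
programming over motif columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genomic_io import Enhancer, MotifMatrix

__all__ = [
    "PWM",
    "MotifHit",
    "CoverageTestResult",
    "build_log_odds",
    "score_pvalue_table",
    "scan",
    "scan_batch",
    "dinuc_shuffle",
    "coverage_significance",
    "differential_enrichment",
    "batch_background",
    "write_hits_tsv",
    "read_hits_tsv",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
UNIFORM_BACKGROUND = np.full(4, 0.25)
DEFAULT_GRANULARITY = 1e-3
_MAX_TABLE_SIZE = 5_000_000


@dataclass
class PWM:
    """Log-odds position weight matrix with its score-distribution table."""

    motif_id: str
    log_odds: np.ndarray  # 4 x L, log2
    background: np.ndarray
    pseudocount: float
    granularity: float = DEFAULT_GRANULARITY
    # integer-grid representation and exact tail probabilities, built lazily
    _int_scores: np.ndarray | None = field(default=None, repr=False)
    _tail: dict | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.log_odds.argmax(axis=0))

    @property
    def int_scores(self) -> np.ndarray:
        if self._int_scores is None:
            self._int_scores = np.rint(self.log_odds / self.granularity).astype(np.int64)
        return self._int_scores

    def pvalue(self, int_score: np.ndarray | int) -> np.ndarray:
        """Exact P(score >= s) under the 0-order background for integer-grid
        scores."""
        if self._tail is None:
            self._tail = _tail_distribution(self.int_scores, self.background)
        offsets, tail = self._tail["offsets"], self._tail["tail"]
        idx = np.clip(np.asarray(int_score) - offsets[0], 0, len(tail) - 1)
        p = tail[idx]
        # scores above the attainable maximum have probability 0
        p = np.where(np.asarray(int_score) > offsets[1], 0.0, p)
        return p


@dataclass
class MotifHit:
    motif_id: str
    enhancer_id: str
    start: int  # 0-based, in the forward strand of the scanned sequence
    strand: str
    score: float
    p_value: float
    q_value: float = float("nan")

    @property
    def end(self) -> int:  # populated by scan; motif length stored alongside
        return self.start + self.length

    length: int = 0


@dataclass
class CoverageTestResult:
    enhancer_id: str
    observed_coverage_bp: int
    null_coverages: np.ndarray
    empirical_p: float


def build_log_odds(
    pfm: MotifMatrix,
    background: np.ndarray | Sequence[float] = UNIFORM_BACKGROUND,
    pseudocount: float = 0.1,
    granularity: float = DEFAULT_GRANULARITY,
) -> PWM:
    """Convert a position frequency matrix to a log2-odds PWM.

    freq[b,j] = (counts[b,j] + pseudocount * background[b]) / (colsum_j + pseudocount)
    log_odds[b,j] = log2(freq[b,j] / background[b])
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    background = np.asarray(background, dtype=float)
    if background.shape != (4,):
        raise ValueError("background must be a 4-vector")
    if np.any(background <= 0):
        raise ValueError("background contains a zero entry")
    if abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    freq = (counts + pseudocount * background[:, None]) / (colsum + pseudocount)
    log_odds = np.log2(freq / background[:, None])
    return PWM(pfm.motif_id, log_odds, background, pseudocount, granularity)


def _tail_distribution(int_scores: np.ndarray, background: np.ndarray) -> dict:
    """Exact null distribution of the total integer score by column-wise
    convolution; returns the upper-tail P(score >= s) on the attainable
    integer range."""
    L = int_scores.shape[1]
    lo = int(int_scores.min(axis=0).sum())
    hi = int(int_scores.max(axis=0).sum())
    size = hi - lo + 1
    if size > _MAX_TABLE_SIZE:
        raise ValueError(
            f"score table of size {size} exceeds limit; use a larger granularity"
        )
    dist = np.zeros(size)
    dist[0] = 1.0  # distribution of (partial score - running minimum)
    offset = 0
    for j in range(L):
        col = int_scores[:, j]
        cmin = int(col.min())
        new = np.zeros(size)
        for b in range(4):
            shift = int(col[b]) - cmin
            if background[b] > 0.0:
                new[shift:] += background[b] * dist[: size - shift if shift else size]
        dist = new
        offset += cmin
    # dist[i] = P(total == lo' + i) with lo' == lo by construction
    tail = np.cumsum(dist[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return {"offsets": (lo, hi), "tail": tail}


def score_pvalue_table(pwm: PWM, granularity: float | None = None) -> dict:
    """Mapping from integer-grid score to exact p-value.

    Returns a dict with keys ``scores`` (integer grid values, ascending) and
    ``p`` (P(score >= s)); the tail is monotone non-increasing.
    """
    if granularity is not None and granularity != pwm.granularity:
        if granularity <= 0:
            raise ValueError("granularity must be > 0")
        pwm = PWM(pwm.motif_id, pwm.log_odds, pwm.background, pwm.pseudocount, granularity)
    d = _tail_distribution(pwm.int_scores, pwm.background)
    lo, hi = d["offsets"]
    return {"scores": np.arange(lo, hi + 1), "p": d["tail"], "granularity": pwm.granularity}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGTN to 0..3, with N (or any ambiguity code) as 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _window_scores(encoded: np.ndarray, int_scores: np.ndarray) -> np.ndarray:
    """Integer scores of all windows; windows containing N get INT_MIN."""
    L = int_scores.shape[1]
    n_win = len(encoded) - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    valid = (windows != 4).all(axis=1)
    scores = np.full(n_win, np.iinfo(np.int64).min, dtype=np.int64)
    if valid.any():
        w = windows[valid].astype(np.int64)
        scores[valid] = int_scores[w, np.arange(L)].sum(axis=1)
    return scores


def scan(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    sequence_id: str = "",
) -> list[MotifHit]:
    """Scan both strands of one sequence; return hits with p <= p_threshold.

    q-values are NaN here; assign them per motif across a batch with
    :func:`scan_batch`.  Hit start coordinates are always on the forward
    strand.  Windows containing N are skipped.
    """
    L = pwm.length
    if L > len(sequence):
        return []
    enc = encode_sequence(sequence)
    rc_int_scores = pwm.int_scores[::-1, ::-1]  # reverse complement matrix
    hits: list[MotifHit] = []
    for strand, iscores in (("+", pwm.int_scores), ("-", rc_int_scores)):
        win = _window_scores(enc, iscores)
        valid = win > np.iinfo(np.int64).min
        if not valid.any():
            continue
        pvals = np.ones(len(win))
        pvals[valid] = pwm.pvalue(win[valid])
        keep = valid & (pvals <= p_threshold)
        for i in np.flatnonzero(keep):
            hits.append(
                MotifHit(
                    motif_id=pwm.motif_id,
                    enhancer_id=sequence_id,
                    start=int(i),
                    strand=strand,
                    score=float(win[i] * pwm.granularity),
                    p_value=float(pvals[i]),
                    length=L,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def count_windows(sequence: str, motif_length: int) -> int:
    """Number of scored windows (both strands, N-free)."""
    enc = encode_sequence(sequence)
    L = motif_length
    if L > len(enc):
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    return 2 * int((windows != 4).all(axis=1).sum())


def scan_batch(
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    p_threshold: float = 1e-4,
) -> list[MotifHit]:
    """Scan a batch of sequences with a set of PWMs and assign BH q-values
    per motif over all scanned windows of the batch (both strands).

    The BH correction uses the full number of scanned windows as the number
    of tests; unreported windows all have p above the reporting threshold,
    so the ranks of reported p-values are their ranks among all windows.
    """
    hits: list[MotifHit] = []
    for pwm in pwms:
        motif_hits: list[MotifHit] = []
        n_tests = 0
        for seq_id, seq in sequences.items():
            n_tests += count_windows(seq, pwm.length)
            motif_hits.extend(scan(seq, pwm, p_threshold, sequence_id=seq_id))
        _assign_bh(motif_hits, n_tests)
        hits.extend(motif_hits)
    return hits


def _assign_bh(hits: list[MotifHit], n_tests: int) -> None:
    """Benjamini-Hochberg q-values for the m smallest of n_tests p-values."""
    if not hits:
        return
    p = np.array([h.p_value for h in hits])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n_tests / (np.arange(len(p)) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    for idx, qi in zip(order, q):
        hits[idx].q_value = float(qi)


def batch_background(sequences: Iterable[str]) -> np.ndarray:
    """0-order base frequencies of a sequence batch (N ignored)."""
    counts = np.zeros(4)
    for seq in sequences:
        enc = encode_sequence(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)
    if counts.sum() == 0:
        return UNIFORM_BACKGROUND.copy()
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# dinucleotide shuffling (Altschul-Erickson)


def dinuc_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving exact dinucleotide counts and both
    endpoints (Altschul-Erickson Eulerian-path shuffle).

    Only defined on unambiguous A/C/G/T input; segment N-containing
    sequences with :func:`dinuc_shuffle_segmented`.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    if any(c not in "ACGT" for c in seq):
        raise ValueError("dinucleotide shuffle requires pure ACGT input")
    vertices = sorted(set(seq))
    if len(vertices) == 1:
        return seq
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    first, last = seq[0], seq[-1]

    # choose a random last-exit edge per vertex (except the terminal vertex)
    # such that the last-exit edges form a tree rooted at the terminal vertex
    non_terminal = [v for v in vertices if v != last and edges[v]]
    for _ in range(10_000):
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in non_terminal}
        if _connects_to(last_exit, non_terminal, last):
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("failed to sample a valid Eulerian arborescence")

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_exit:
            rest.remove(last_exit[v])
        rng.shuffle(rest)
        if v in last_exit:
            rest.append(last_exit[v])
        shuffled[v] = rest

    out = [first]
    pos = {v: 0 for v in vertices}
    cur = first
    total = len(seq) - 1
    for _ in range(total):
        nxt = shuffled[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _connects_to(last_exit: dict[str, str], sources: list[str], target: str) -> bool:
    for v in sources:
        seen = set()
        cur = v
        while cur != target:
            if cur in seen or cur not in last_exit:
                return False
            seen.add(cur)
            cur = last_exit[cur]
    return True


def dinuc_shuffle_segmented(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle each maximal ACGT run independently, leaving other characters
    (N etc.) in place."""
    seq = sequence.upper()
    out = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] in "ACGT":
            j = i
            while j < n and seq[j] in "ACGT":
                j += 1
            run = seq[i:j]
            out.append(dinuc_shuffle(run, rng) if len(run) >= 2 else run)
            i = j
        else:
            out.append(seq[i])
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# coverage significance


def hit_coverage(hits: Iterable[MotifHit], seq_length: int) -> int:
    """Union length (bp) of hit spans within one sequence."""
    covered = np.zeros(seq_length, dtype=bool)
    for h in hits:
        covered[h.start : h.start + h.length] = True
    return int(covered.sum())


def coverage_significance(
    enhancer: Enhancer,
    pwms: Sequence[PWM],
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    p_threshold: float = 1e-4,
) -> CoverageTestResult:
    """Empirical significance of TFBS coverage against dinucleotide-shuffled
    versions of the enhancer.

    empirical_p = (1 + #{shuffles with coverage >= observed}) / (n_shuffles + 1).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    if enhancer.sequence is None:
        raise ValueError(f"enhancer {enhancer.enhancer_id} has no sequence")
    seq = enhancer.sequence

    def _coverage(s: str) -> int:
        hits = []
        for pwm in pwms:
            hits.extend(scan(s, pwm, p_threshold))
        return hit_coverage(hits, len(s))

    observed = _coverage(seq)
    null = np.empty(n_shuffles, dtype=int)
    for i in range(n_shuffles):
        null[i] = _coverage(dinuc_shuffle_segmented(seq, rng))
    empirical_p = (1 + int((null >= observed).sum())) / (n_shuffles + 1)
    return CoverageTestResult(enhancer.enhancer_id, observed, null, empirical_p)


# ---------------------------------------------------------------------------
# differential enrichment (AME-style sequence-level Fisher test)


def differential_enrichment(
    primary_hits_by_seq: Mapping[str, set[str]],
    background_hits_by_seq: Mapping[str, set[str]],
    motifs: Sequence[str],
) -> dict[str, dict]:
    """One-sided Fisher exact test of motif presence in primary vs background
    sequence sets, Bonferroni-corrected over tested motifs.

    Arguments map sequence id -> set of motif ids with >=1 retained hit.
    Motifs present in neither set are reported as NA and do not count toward
    the Bonferroni factor.
    """
    if not primary_hits_by_seq or not background_hits_by_seq:
        raise ValueError("primary and background sets must be non-empty")
    n_p, n_b = len(primary_hits_by_seq), len(background_hits_by_seq)
    results: dict[str, dict] = {}
    tested = []
    for motif in motifs:
        a = sum(1 for s in primary_hits_by_seq.values() if motif in s)
        c = sum(1 for s in background_hits_by_seq.values() if motif in s)
        if a == 0 and c == 0:
            results[motif] = {"odds_ratio": float("nan"), "p": float("nan"),
                              "p_bonferroni": float("nan"), "na": True}
            continue
        table = [[a, n_p - a], [c, n_b - c]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        results[motif] = {"odds_ratio": float(odds), "p": float(p), "na": False,
                          "table": table}
        tested.append(motif)
    m = len(tested)
    for motif in tested:
        results[motif]["p_bonferroni"] = min(1.0, results[motif]["p"] * m)
    return results


# ---------------------------------------------------------------------------
# TSV interchange (FIMO-like layout)


def write_hits_tsv(hits: Sequence[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tsequence_id\tstart\tstop\tstrand\tscore\tp\tq\n")
        for h in hits:
            fh.write(
                f"{h.motif_id}\t{h.enhancer_id}\t{h.start}\t{h.start + h.length}\t"
                f"{h.strand}\t{h.score:.4f}\t{h.p_value:.6g}\t{h.q_value:.6g}\n"
            )


def read_hits_tsv(path) -> list[MotifHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            start, stop = int(f[idx["start"]]), int(f[idx["stop"]])
            hits.append(
                MotifHit(
                    motif_id=f[idx["motif_id"]],
                    enhancer_id=f[idx["sequence_id"]],
                    start=start,
                    strand=f[idx["strand"]],
                    score=float(f[idx["score"]]),
                    p_value=float(f[idx["p"]]),
                    q_value=float(f[idx["q"]]),
                    length=stop - start,
                )
            )
    return hits
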