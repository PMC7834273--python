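# Methods

`cisnet` reconstructs tissue-specific transcription-factor (TF) → gene
regulatory networks from enhancer sequence content and multi-tissue
expression data, and derives from them differential targeting calls,
tissue-specific regulatory modules, enhancer top-target assignments and
transposable-element (TE) enrichment statistics.  This note documents the
models, the tunable parameters, the synthetic data the package is
validated on, and the numerical choices made where the design was open.

## 1. Motif scanning (`motif_scan`)

Position frequency matrices are converted to log2-odds PWMs with a
pseudocount proportional to the background frequency:

    freq[b,j]     = (counts[b,j] + c * bg[b]) / (colsum_j + c)
    log_odds[b,j] = log2(freq[b,j] / bg[b])

with pseudocount `c = 0.1` and a 0-order background estimated from the
scanned sequence batch (configurable to uniform).  Scores are discretized
on a fixed grid (granularity 1e-3 bits) so the exact null score
distribution — and hence an exact p-value P(score ≥ s) for every
attainable score — is obtained by convolving per-column score
distributions.  Both strands are scanned; windows containing N are
skipped.  Hits are reported at p ≤ 1e-4 (the conventional scanner default)
and q-values are assigned per motif by Benjamini–Hochberg over **all**
scanned windows of the batch; the number of tests is the number of scored
windows, and since every unreported window has p above the reporting
threshold, ranks of reported p-values are exact.  Retention for all
downstream steps is q < 0.01.  A consequence worth remembering: with
~3×10^5 windows per motif, q < 0.01 admits on the order of 0.2 false
windows per motif — downstream structures must be robust to occasional
spurious TF–enhancer assignments, which drove the module-size choice of
the synthetic data (section 10 below).

TFBS coverage significance per enhancer compares the union length of hit
spans against dinucleotide-shuffled versions of the enhancer
(Altschul–Erickson Eulerian-path shuffle: exact dinucleotide counts and
both endpoints preserved; N-containing sequences are shuffled per maximal
ACGT run).  The empirical p uses add-one smoothing,
p = (1 + #{null ≥ observed}) / (n + 1), so it is never exactly zero.  The
operation default is 1,000 shuffles per enhancer; the orchestrated
pipeline uses 100 per enhancer as its problem size.  Differential motif
enrichment between two enhancer sets is a one-sided Fisher exact test on
sequence-level presence/absence, Bonferroni-corrected over tested motifs;
motifs absent from both sets are reported NA and excluded from the
correction factor.

## 2. Expression preprocessing (`expression_prep`)

Genes are kept when they have count ≥ 1 in ≥ 3 samples of at least one
tissue ("expressed" is deliberately minimal; both thresholds are
arguments).  Normalization is tissue-aware smooth quantile normalization:
at each quantile the normalized value interpolates between the overall
mean quantile (full quantile normalization) and the tissue-group mean
quantile, with weight w_q = 1 − SSB_q/SST_q smoothed by a running median
over 5% of the quantiles.  The weighted blend can be locally non-monotone
where w swings between adjacent quantiles, so the blended vector is
re-sorted before assignment to ranks — this guarantees within-sample rank
preservation at the cost of a (tiny) reordering of nearly-tied normalized
values.  Ties in the input receive the mean of their normalized values.

Batch correction operates on log2(x+1): per gene, ordinary least squares
on tissue cell-mean indicators plus batch indicators (first batch as
reference); the fitted batch term is subtracted, tissue terms are left
untouched.  The transform is exactly idempotent and errors when batch is
confounded with tissue.  Co-expression is plain Pearson correlation;
constant genes get 0 off-diagonal (1 on the diagonal).

## 3. Prior construction (`prior_builder`)

A gene is a candidate target of an enhancer when its TSS lies within
250 kb (inclusive) of the enhancer boundary, regardless of orientation; a
TSS inside the enhancer counts as distance 0.  Distance is
boundary-to-TSS.  The binary TF×gene prior sets an edge when the TF has a
retained (q < 0.01) binding site in an enhancer with that gene in its
window; each edge is witnessed by one or more (TF, enhancer, gene)
triples, which are kept as first-class output.  Enhancers with no
expressed-TF hit and TFs with no surviving edge are dropped ("expressed"
for a TF = its coding gene has count ≥ 1 in ≥ 1 sample).  Candidate
targets are restricted to genes surviving the expression filter.

## 4. Network inference (`network_inference`)

The aggregate network is estimated by message passing over three
z-normalized matrices — the prior W (TF×gene), TF cooperativity P
(identity, absent protein–protein interaction data) and gene co-expression
C — using the continuous Tanimoto similarity

    T(x, y) = x·y / sqrt(|x|² + |y|² − |x·y|).

Per iteration: responsibility R = T(P, W), availability A = T(W, C),
W ← (1−α)W + α(R+A)/2, then P and C relax toward the Tanimoto
self-similarity of W.  The self-similarity diagonal (which equals the
vector norm and would inflate P and C without bound, destabilizing the
iteration) is replaced by a heterogeneity term: the off-diagonal row
standard deviation scaled by the matrix dimension and exp(2α·step).  As
this diagonal grows it drives R and A toward W itself, which is precisely
what makes the iteration contract; convergence is declared when
mean|ΔW| < 1e-3 (α = 0.1, ≤ 200 iterations).  α = 0 returns the
z-normalized prior unchanged.

Per-sample networks use the leave-one-out identity
EW_s = N·(W_all − W_−s) + W_−s, with co-expression recomputed from the
remaining N−1 samples and the prior/PPI fixed.  Sample edge weights are
reported on the softplus scale logEW = ln(exp(EW)+1) (computed as
logaddexp, overflow-safe), with prior-zero entries forced to 0.  The
aggregate network is left untransformed.

## 5. Differential targeting (`differential_targeting`)

Each prior edge's logEW is regressed on tissue-condition indicators
(cell-means coding, OLS, vectorized closed form; cross-checked against
statsmodels in the tests), with a two-sided t test on the husk − V2-IST
contrast and BH correction across all fitted edges.  A gene is
differentially targeted when ≥ 1 of its edges is significant; direction is
the majority sign of its significant contrasts, exact ties → not
significant.  The default gene-call threshold is q < 0.05 (exposed as
`fdr`; the stricter 0.01 used for hit retention is equally valid and both
appear in practice).  Plain OLS was chosen over moderated (empirical
Bayes) variance: with 32 residual degrees of freedom, moderation changes
little, and the closed form keeps the 200-permutation null exercises
cheap.  Two caveats the tests quantify: a gene's leave-one-out edge
weights are correlated across samples, so its edges are far from
independent tests; and null edge t-statistics are mildly overdispersed
(sd ≈ 1.5), because within-tissue variance differs between tissues with
and without active regulatory programs while OLS pools it.

## 6. Module detection (`module_detection`)

Tissue networks are replicate means of logEW.  The differential-modularity
matrix compares a perturbed tissue network against a baseline tissue
network through the baseline's configuration model:

    D_tg = w_tg^pert − s_t u_g / W_base

with s, u the baseline TF/gene strengths and W_base its total weight.
Prior-zero pairs carry w^pert = 0, so their D is the pure negative
penalty −s_t u_g / W_base; retaining that penalty is what gives the
community search its resolution (zeroing those entries removes all cost
of merging and collapses everything into one module).  Communities of TFs
and genes maximizing the normalized within-community sum of D are found by
a seeded Louvain-style search — greedy best-gain node moves, community
aggregation, repeat — followed by a single-node refinement pass on the
original graph (which recovers the exhaustive optimum on ≤10-node test
instances), best of 10 restarts.  If no structure beats the baseline
expectation the trivial one-community partition is returned.  Modules with
≥ 1 TF and ≥ 5 genes are retained; each tissue's modules are matched to
the other tissue's by the jaccard index of gene sets, with jaccard ≥ 0.5
classified shared (the boundary value counts as shared).  Both
orientations are run: husk perturbed vs V2-IST baseline, and vice versa.

## 7. Enhancer scoring (`enhancer_scoring`)

For enhancer e with T_e distinct TFs carrying retained sites in it, the
score of candidate gene g is avgEW = (1/T_e) Σ_t logEW(t, g) in one
tissue network — TFs count once regardless of hit multiplicity.  The top
target is the argmax over the enhancer's ≤250-kb candidates, ties broken
by smaller TSS distance then gene id.  A top target is "flanking" when it
is one of the two TSS-nearest genes of the enhancer (one per side; a TSS
inside the enhancer counts).

## 8. TE enrichment and motif discovery (`te_enrichment`)

Enhancer-level TE annotation uses orders (TIR/LTR/MITE/...), with "None"
for no overlap and "Multiple" for ≥ 2 distinct orders; covered fraction is
the union coverage.  Class enrichment is a Pearson χ² on the tissue-class
× TE-class table; the null distribution resamples, per subject, a random
interval with identical length and chromosome and the same nearest-TSS
distance (log2 bin — exact distance matching is generally infeasible;
rejection sampling with a 200-try cap and nearest-feasible fallback).
Empirical p again uses add-one smoothing.  Odds ratios come from the 2×2
collapse (focal class vs rest × focal TE vs rest).

Motif discovery in TE sequences is k-mer over-representation (k = 9–15):
sequence-level counts of reverse-complement-collapsed k-mers, a one-sided
Fisher (hypergeometric tail, vectorized) against background sequences,
E = p × number of distinct k-mers tested at that k, threshold E ≤ 1e-4;
overlapping enriched k-mers (offset ≤ 2, ≥ k−2 matching positions,
either orientation) are merged into an IUPAC consensus with an
occurrence-weighted count matrix.  This deliberately replaces
expectation-maximization motif discovery: on sequence sets of this size
the planted signal is a literal repeated word, and k-mer enrichment is
transparent and exactly testable.  Note the E-value threshold needs
enough target sequences to be attainable at all — with < ~10 target
sequences even a perfectly clean k-mer cannot reach E ≤ 1e-4.  Candidate
motifs are compared to known PFMs by the mean Pearson correlation of
aligned frequency columns over all ungapped offsets and both orientations
(≥ 5 usable columns; zero-variance columns excluded), with significance
from 1,000 column-order permutations of the known motif (add-one
smoothing), kept at p ≤ 0.01.

## 9. GO enrichment (`go_enrichment`)

Annotations are closed under the true-path rule, then terms are tested
deepest-first with one-sided hypergeometric tests; when a term is
significant at the elimination cutoff (0.01), its genes are removed from
all ancestors' gene sets before those are tested.  With a flat DAG or
cutoff 0 the procedure is exactly classic Fisher.  No multiple-testing
correction is applied (the tests are not independent); instead reported
terms need p ≤ 0.01 and ≥ 5 interest genes.  For modules with more than
100 genes, the interest set is the 100 genes most connected to the
module's TFs; the universe is the prior's gene set.

## 10. Synthetic data (`synthetic_data`)

The generator emulates the structure of an enhancer-centred regulatory
study at desk scale.  Default geometry: 3 chromosomes × 12 Mb, 1,200
genes on a ~30 kb grid (so a 250-kb window holds ~17 candidate genes,
matching the ~10–40 targets per enhancer seen in real intergenic space),
170 enhancers (80 in modules + 90 background), 64 sharp PWMs of length
13–16 (dominant base 0.98), 200 TEs, and 13 tissues × 3–6 replicates = 45
samples (the two contrasted tissues get 6 each).

Eight regulatory modules are planted in contiguous "territories" of 60
consecutive gene slots: 3 specific to each contrasted tissue (one
repressor-flagged on each side, keeping total activation balanced between
the contrasted tissues — an unbalanced design induces a global shift of
all edge contrasts through normalization and inference), and 2 shared
modules also active in one additional tissue.  Each module has 6 TFs and
10 enhancers confined to the territory interior, so candidate windows
consist mostly of module genes with a modest spill of neighbours.  Module
enhancers carry two sampled instances of each module TF's motif
(homotypic pairs); background enhancers carry decoy-TF sites.  Module
sizes matter twice: 60-gene territories with 6 TFs give gene degrees
(~6.7 TFs per gene) in the regime of real priors, and make the
configuration-model penalty large enough that a single spurious
TF–enhancer hit (expected at the 1% hit FDR) cannot fuse two planted
modules.  One decoy TF's coding gene is forced to zero counts to exercise
the expressed-TF filter.

Expression is built on the log2 scale: gene baseline ~ U(3,8); for every
module active in the sample's tissue, a per-sample latent N(1, 0.5)
scaled by effect 2.0 is added to the module's genes (negated for a
repressor's targets, positive for the TF genes themselves); a +0.8 batch
shift on "SE" samples (assigned by replicate parity, so batch is never
confounded with tissue); N(0, 0.25) log-scale noise; counts = round(2^x).
This produces within-module correlations ≥ 0.7 in active tissues,
repressor anti-correlation, and an on/off pattern across 13 tissues that
drives the leave-one-out networks exactly as multi-tissue designs do.
MITE-like TEs preferentially overlap husk-specific enhancers and
Pif/Harbinger elements (70% of MITEs, as that superfamily dominates real
MITE complements) carry a planted 15-mer.

What the generator does **not** emulate: count dispersion
(counts are rounded lognormals, not negative binomial — the pipeline
consumes normalized values, not dispersion), realistic TE sequence
evolution, linkage between enhancer classes and chromatin context, or
motif information-content heterogeneity.  Passing recovery tests
therefore show the pipeline's logic is sound under clean planted
structure; they do not certify performance on real tissue data.

## 11. Problem sizes and runtime

The default synthetic run (scan + prior + 46 network fits + differential +
modules + scoring) takes ~2 minutes on one CPU; the test suite ~5 minutes;
the acceptance script ~5 minutes.  Scaled-down choices made for these
runs, all exposed as parameters: 100 coverage shuffles per enhancer (vs
the 1,000 default of the operation), 200 χ² resamples in the pipeline (vs
1,000), 100 label permutations in the acceptance script, and the χ²
calibration test at 99 resamples × 200 repetitions.

## 12. Known limitations

- Power of the differential-targeting test at small effects is bounded by
  the BH threshold under sparse alternatives: at a 2-residual-sd contrast
  with 6v6 replicates the gene-level detection rate is ~0.83, and the
  correlation of a gene's edges means multiple edges add little.
- A false motif hit (expected at the 1% FDR over ~3×10^5 windows per
  motif) creates a full set of enhancer-window edges; small, weakly
  penalized modules can be fused by such a bridge.  At default scale the
  planted modules are robust to single bridges, but this failure mode is
  intrinsic to binary priors.
- The empirical p-values (coverage, χ², motif comparison) have resolution
  1/(n+1); raise the resample counts for smaller p.
- The message-passing scale grows with matrix dimension (Tanimoto of
  z-scored vectors); edge weights are comparable within a run, not across
  priors of different sizes.
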