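# Methods

This note documents the conventions, statistical choices and synthetic
data design behind `chirswitch`, and what the test suite does and does
not establish.

## Coordinates, centers and matching

All intervals are 0-based, half-open (BED convention). Every feature has
a *center*: a supplied summit when available (narrowPeak column 10),
otherwise `floor((start+end)/2)`. All proximity rules in the package are
center-distance rules with **inclusive** boundaries — "within 150 bp"
means distance ≤ 150 — because the downstream biology (a shared binding
site, a shared loop anchor) is about the same point being hit twice, not
about base-pair overlap. Base-pair-overlap semantics are deliberately
out of scope.

**Peak-set matching** (`match_peak_sets`, default threshold 150 bp) is
one-to-one: candidate same-chromosome pairs within the threshold are
sorted by distance and taken greedily, which is equivalent to iterating
mutual-nearest-neighbour matching. Ties break on the symmetric key
(min center, max center, min start, max start), so output is
deterministic and invariant under swapping the two sets. Consequences
worth knowing: counts always reconcile (`matched + uniqueA = |A|`,
`matched + uniqueB = |B|`), and an unmatched peak may still lie within
the threshold of an *already matched* peak of the other set — but never
of another unmatched one.

**Merging** (`merge_peaks`, same threshold) chains greedily left to
right over centers sorted within each chromosome: when the next center
lies within the threshold of the current merged center, the merged
center moves to the midpoint of the two (floor on odd sums). A chain's
final centers are pairwise more than a threshold apart, which makes the
operation idempotent. Multi-peak chains are resolved by this running
midpoint — the natural one-pass reading of "combine two nearby peaks at
their midpoint" — and the spanned interval is the union of the
contributors.

## Fold enrichment and filters

Fold enrichment is a density ratio:

    FE = (count / window_len) / (total_tags / genome_size)

with `window_len = 2*halfwidth + 1` (both boundary positions of a
±250 bp window count). FE = 1 is the genome-background expectation,
which is what makes "fold enrichment" interpretable; the formula is
linear in the count and invariant under joint scaling of count and
library size. Tag positions are taken as given (read 5′ ends); no
fragment-shift model is applied — position shifting is the peak
caller's job upstream.

All filters use **strict** inequalities — q < 1e-4, FE > 10 (ChIP
reproducibility, every replicate), FE > 20 (strong subset), FE > 3
(ATAC, all three replicates), TPM > 5, fold change > 3, p < 0.05 —
so a value exactly at a threshold is excluded. The ChIP and ATAC
filters share one code path ("all replicates supplied"); the replicate
count is validated for ATAC.

## Switch classification and motifs

`classify_sites` is a thin, auditable composition: match the filtered
low-condition peak set against the filtered high-condition set; uniques
on the low side are *lost* (set 1), pairs are *switch* (set 2), uniques
on the high side are *de novo* (set 3). By default classification runs
on the strong (FE > 20) subset; this is a config toggle
(`strong_only`).

Motif calls use a standard log-odds PWM scan: score(window) =
Σ log2(p_i(base)/bg(base)), both strands, windows containing N skipped;
a peak is motif-positive when any window inside its span reaches the
caller's score threshold. The PWM is user-supplied (e.g. a JASPAR
TCF/LEF matrix); none is bundled, since no single matrix is ground
truth. Overlap significance is a hypergeometric upper tail over a
caller-supplied site universe, returned as log10 p to survive
genome-scale extremes; the universe size is a modelling choice the
caller must own, so this statistic is a generic enrichment measure, not
a reproduction of any published p-value.

## The negative-binomial test

`nb_wald_test` is a deliberately simple, fully documented NB pipeline:

1. **Size factors**: median-of-ratios over features with nonzero counts
   in every sample (no renormalization).
2. **Dispersion**: per feature, the method-of-moments estimate
   α = (s² − m)/m² on normalized counts, averaged over the two groups —
   then **floored at the across-feature median dispersion** (and at
   1e-8). The raw per-feature estimate at 2–3 samples per group is
   noisy enough to inflate Wald type-I error roughly 2.5-fold; the
   common-dispersion floor (in the spirit of edgeR's common dispersion)
   restores near-nominal calibration while leaving genuinely
   overdispersed features their larger α. This moderation is the one
   place the implementation departs from the naive textbook estimator,
   and it is driven by the calibration property below.
3. **Effect and test**: LFC = log2((μ_B+0.5)/(μ_A+0.5)); the Wald
   statistic divides the LFC by its delta-method standard error using
   the NB variance μ + αμ² of each group mean; two-sided normal
   p-values; Benjamini–Hochberg adjustment over all tested features.

This is **not** DESeq2: there is no dispersion trend or MAP shrinkage,
no Cook's-distance outlier handling, no independent filtering, no LFC
shrinkage. Its contract is behavioural, enforced by the test suite:
under an NB null (3+3 samples, dispersion 0.1, 2000 features) the
fraction of raw p < 0.05 lies in [0.03, 0.07]; planted 8-fold effects
at mean 100, dispersion 0.05 are recovered with BH power > 0.8; LFC
signs flip exactly under group swap. A separate test cross-checks
directionality and effect-size correlation against pyDESeq2 on planted
effects — as an independent oracle, never as the implementation.

DE calling applies TPM > 5 to the larger group-mean TPM, fold change
(ratio of group-mean TPMs with a 0.5 pseudocount, taken in the
direction exceeding 1) > 3, and raw NB p < 0.05. DAR calling applies
BH-adjusted p < 0.05 (configurable — the appropriate cutoff is a
per-study choice) over ±500 bp windows around merged ATAC peak centers,
labeling each DAR with the more accessible condition. TPM is
`rate/Σrate·1e6` with rate = count/(length/1000); every column sums to
1e6 by construction.

## Loop connectivity

Two loops are the same interaction when both **ordered** anchor-center
distances (anchor1↔anchor1, anchor2↔anchor2; anchors are stored
lexicographically sorted, so no swap is considered) are ≤ 10 kb.
Replicate reconciliation keeps first-replicate loops with any partner
in the second replicate (annotated with the nearest one); condition
comparison uses the same rule but one-to-one greedy matching (same
scheme as peak matching, on the max of the two anchor distances) so the
shared/specific partition reconciles with input sizes. The 10 kb rule
is reused for condition comparison because the two questions — "same
loop seen twice?" across replicates or across conditions — are the
same measurement problem.

The chain: a peak is *in an anchor* when its center is within 5 kb of
either anchor center (a peak may hit several loops); it is
*TSS-connected* when some TSS lies within 15 kb of the **opposite**
anchor's center on that chromosome. The TSS search is strand-agnostic —
it is a pure distance rule — and TSS positions come from BED6 (start
for +, end−1 for −). A connected peak is attributed to *conserved*
looping when at least one of its connecting loops is shared between
conditions, else to *specific*; conserved wins ties so the two tallies
partition the connected peaks. Report percentages are
nearest-integer-rounded ratios (half away from zero); raw counts are
always retained alongside.

## Synthetic data

The generators exist so every stage is testable against planted truth
without any external download. Design principles:

- **Grid placement.** Sites sit on a grid whose spacing (5 kb for
  peaks, 250 kb slots for loops with anchors at fixed in-slot offsets)
  is far above every matching tolerance. Planted structure is therefore
  unambiguous: any recovery error is caused by the injected jitter, not
  by accidental collisions. A capacity check rejects configurations
  that would overfill the genome.
- **Noise model.** Center/anchor jitter is truncated Gaussian — a
  single interpretable spread parameter. Default jitter is 20% of the
  tolerance it stresses (30 bp vs 150 bp; 2 kb vs 10 kb), the regime
  where matching is genuinely exercised yet near-lossless (the
  between-copy difference is ~3.5 SD below the tolerance). Setting the
  SDs to 0 gives exact, zero-error round trips.
- **Unambiguous filter truth.** Passing peaks draw q uniformly in
  (0, 1e-5) and FE from a normal truncated above the strong threshold;
  planted failures draw q in (1e-3, 1) or one replicate FE in (1, 9).
  No planted peak is borderline, so filter behaviour is exactly
  predictable.
- **Exact planted fractions.** Motif flags are assigned to exact
  rounded counts per class, so configured fractions (e.g. 73% of
  motif-positive low-condition sites shared, 29% of motif-negative)
  reproduce identically, not just in expectation.
- **Connectivity bookkeeping.** Planted peaks are placed within 2 kb of
  an *emitted* high-condition anchor (and connected TSSs within 8 kb of
  the partner anchor), inside the 5/15 kb tolerances by a wide margin,
  so the intended chain counts are recovered exactly whenever replicate
  reconciliation and condition matching succeed. The genome-scale
  scenario (19 chromosomes × 100 Mb) plants the chain
  5530 → 1573 → 647 → 371, whose ratios are 28%, 41% and 57%.
- **Determinism.** All randomness flows from one seed through one
  `numpy` generator; identical configs give byte-identical outputs.

What passing these tests does **not** show about real data: the
generators use well-separated sites, symmetric unimodal jitter, clean
NB counts with group-constant dispersion, and loops with exactly two
tidy replicate copies. Real peak landscapes have clustered and
overlapping sites, irregular summit error, batch structure and
mean-dependent dispersion trends; real loop calls have resolution
-dependent anchor widths and many-to-many replicate correspondence.
The suite certifies the *rules* are implemented exactly as stated, and
the statistics are calibrated under their stated model — not that the
model captures every property of experimental data.

## Numerical details and degenerate inputs

- Different-chromosome center distance is `inf`, so it fails every
  finite threshold without special-casing.
- Matching/merging tie-breaks are documented above; all are
  deterministic.
- Zero-count features: FE 0 is valid; size factors require at least one
  feature nonzero in all samples (error otherwise, advising deeper
  counts or a pseudo-reference); all-zero features get LFC 0, p 1.
- Empty inputs are empty outputs (with a logged warning for empty
  files), never errors; malformed lines are hard errors with file and
  line number.
- PWM rows are pseudocount-smoothed and renormalized; zero
  probabilities score −inf, which simply can never reach a finite
  score threshold.
- Problem sizes in the routine test run are desk-scale by design — a
  few hundred to a few thousand sites/loops/features, 2000-feature
  count matrices, and one genome-scale (5530-peak) connectivity
  scenario — chosen so brute-force all-pairs oracles can arbitrate
  every matcher exactly.

## Known limitations

- The NB test trades DESeq2's estimator sophistication for
  auditability; for publication-grade DE/DAR inference on real data,
  export the count matrices and run DESeq2/edgeR, then feed the results
  back through the calling rules here.
- `reconcile_replicate_loops` handles two replicates (the design it
  models); more replicates require pairwise composition.
- Peak-to-gene assignment by regulatory-domain rules, loop calling,
  peak calling and motif discovery are out of scope; this package
  starts from called peaks, called loops and count tables.
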