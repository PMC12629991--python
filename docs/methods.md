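# Methods

This note documents the models and procedures implemented in `germ`, the
numerical choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## The multivalency score

A multivalent RNA region is a stretch densely populated by similar k-mers,
able to scaffold repeated binding of the same protein. The GeRM score of the
k-mer starting at position `p` is

    g(p) = Σ_{i ∈ B} exp(−λ·d(A₀, A_i)) · weight(i),
    B = {−w, …, −k, k, …, w},  w = (n + 1) / 2

where `d` is the Hamming distance between the central k-mer `A₀` and the
neighbour starting `i` nucleotides away, and the weight decays linearly from
1 at the centre to 0 at `|i| = w`. Offsets `|i| < k` (overlapping k-mers) are
excluded; neighbours beyond the transcript ends contribute 0, as do k-mers
containing `N`. Defaults: `k = 5`, `n = 123` (so `w = 62`), `λ = 1`,
smoothing window 123 nt.

Two weight conventions exist: the symmetric `(w − |i|)/w` used by default,
and a literal `|w − i|/w`, which is asymmetric in `i` (it exceeds 1 for
negative offsets). The symmetric form matches the verbal definition of the
score ("decays linearly from 1 to 0 with distance"); the literal form is
retained behind `literal_weight=True` for comparison. A consequence of the
symmetric weight worth knowing: because complementation preserves Hamming
distances and reversal maps `i → −i`, the score profile of a reverse
complement is the exact mirror of the forward profile. Scores at a given
coordinate still depend on strand, and the literal weight breaks even the
mirror identity.

Two scorers are provided and cross-checked: a vectorized offset-sweep
(`score_transcript`, O(L·n) with running sums) and a direct term-by-term
evaluation of the sum at each position (`score_transcript_reference`). They
agree to < 1e−9 on random sequences by test.

**Normalization** is affine: raw scores pooled over a declared transcript
set are mapped so the pooled minimum is 0 and the median 1. The coefficients
are stored with a provenance string; applying them to new transcripts can
produce values < 0 or ≫ 1, which is intended (no clipping). **Smoothing** is
a centred moving mean of width 123; at transcript edges the window is
truncated to in-bounds values rather than zero-padded, so edge scores are
not artificially suppressed beyond the score's own edge rule. Per-nucleotide
views assign each nucleotide the value of the k-mer starting at it, with the
trailing k − 1 positions carrying the last defined value.

## Region calling

Primary transcripts are chosen per gene as the longest CDS, ties broken by
total transcript length, restricted to spliced transcripts. The region
threshold is the 98th percentile (linear interpolation) of smoothed scores
pooled over all CDS positions of the supplied set — pooled, not
per-transcript, since a per-transcript percentile would force calls on every
transcript. Super-threshold runs are extended by half the smoothing window
(61 nt) on each side so a region contains every k-mer inside the smoothing
window of a super-threshold position; regions overlapping by ≥ 41 nt are
merged (to a fixed point, so merging is idempotent and order-independent);
regions with ≥ 1/3 of their extended span in a UTR are removed. Each
region's per-k-mer contribution fractions are the raw-score mass of each
distinct 5-mer inside the region divided by the region total.

## Codon-level statistics

**Shuffle nulls.** Synonymous codon shuffling preserves each amino acid's
codon multiset and permutes order — within each transcript, or pooled across
the transcriptome and dealt back. The encoded protein is unchanged by
construction; internal stop codons are a hard error and a trailing stop is
held fixed. Per-position null tracks are the element-wise mean over 10
shuffles (5 is the region-level convention); both counts are exposed.

**Codon ratios.** A mutable position is any CDS nucleotide admitting ≥ 1
synonymous single-base substitution under the standard genetic code —
third positions of degenerate codons plus first positions of CTA/CTG↔TTA/TTG
(Leu) and CGA/CGG↔AGA/AGG (Arg). For each, the maximum raw score over the
≤ k 5-mers overlapping the position is compared between the native sequence
and each synonymous variant; the ratio is native over the mean of variant
maxima, so ratio > 1 means the native base supports local multivalency.
Raw (unsmoothed, unnormalized) scores are used: the comparison is local and
normalization is affine, so raw is the minimal consistent choice. Variant
scoring uses only the window that can influence the overlapping 5-mers
(w + k − 1 nt each side); this is exactly equal to rescoring the full
mutated transcript (asserted, to 0.0, in tests). If a degenerate context
leaves no scoreable 5-mer for either allele the ratio is defined as 1.

**Conservation.** Per-base conservation (PhyloP-like, log-scale, so
normalization is by subtraction) at mutable positions is centred by the
median over all instances of the same (codon, offset) type; the same codon
instance's middle-position conservation — never synonymously mutable — is
then subtracted, itself centred by its per-type median. Centring the middle
position as well makes a constant track normalize to exactly 0 and differs
from subtracting the raw middle value only by a per-type constant, which
cancels from every between-bin contrast. Records are binned by codon ratio
into 10 equal-count bins within each codon type and pooled, so each bin
holds an equal proportion of every codon; effect size is read off as the
top-bin minus bottom-bin mean.

**Recoding.** `recode_cds` minimizes (or maximizes) the count of 5-mers
composed only of A/G, under three hard constraints: identical protein, GC
content within 0.02 of the input, protected spans byte-identical. The
optimizer is greedy coordinate descent over codons in a seeded random order
with restarts; when single-codon moves stall on short inputs it also tries
GC-compensating pairs of codon moves, which lets small instances reach the
exhaustive optimum (asserted on ≤ 10-codon toys) even when every single
move violates the GC tolerance.

## Proteins: entropy, LCDs, arginine codon classes

Shannon entropy (log base 2; the base only rescales the pooled threshold's
input monotonically, so calls are base-invariant) is computed over 41-aa
sliding windows. LCDs are windows with entropy in the bottom 2% of the
pooled distribution, expanded to their full window span and merged when
overlapping; an explicit threshold override supports reusing one proteome's
cutoff on another. R-LCDs have ≥ 20% arginine; R-MCDs additionally have
net positive charge (K + R − D − E > 0) and > 40% charged residues, with
charged = {D, E, K, R} (histidine excluded by the usual mixed-charge-domain
convention). Boundary cases sit exactly on the documented side (≥, >, >).

Arginine codon usage within R-LCDs is a 6-proportion vector over
AGA/AGG/CGA/CGG/CGC/CGT; pairwise Spearman correlations are taken across
LCDs and PCA over the vectors defines the GA-rich vs CG-rich split: PC1's
sign is fixed so AGA loads positive, and the top/bottom thirds of PC1 are
labelled GA_rich/CG_rich.

## Multivalency classes

Regions are embedded by UMAP (4 components, 50 neighbours, min_dist 0.001,
seeded) on their 4⁵-dimensional k-mer fraction vectors and clustered by
density with OPTICS (min_samples = 1% of regions, floor 5), followed by a
flat DBSCAN-style cut of the reachability profile; noise is −1 and excluded
downstream. The cluster count is an outcome, never a parameter. Two
threshold rules are provided for the cut. The knee rule scans thresholds
from the 99th percentile of reachability to 0 and takes the first point
where the derivative of the proportion-below curve reaches 40% of its
maximum. It behaves well when a substantial fraction of points lies between
clusters, but when fewer than 1% do, its scan starts inside the
within-cluster bulk and fragments genuine clusters; the default is therefore
a scale-separation cut at the widest log-gap in the upper half of the sorted
reachability values, which targets the same transition directly. Both are
exposed (`eps_rule="gap" | "knee"`).

Representative k-mers per cluster are the minimal descending-sorted prefix
of k-mer contribution proportions (pooled as fraction × region total raw
score) reaching 50% coverage, ties broken lexicographically; an optional
deduplication keeps a k-mer only in the cluster where its proportion is
highest (feature-table mode). Transcript class scores z-scale each 5-mer's
raw scores against all instances of that same 5-mer in the fitting set
(zero-variance 5-mers contribute 0) and sum z-scores over CDS occurrences of
a class's representative 5-mers; "in the CDS" means the 5-mer starts in the
CDS, which makes the score exactly additive over disjoint CDS segments. The
retention feature table carries CDS length, mean exon length (an inverse
proxy for exon-junction-complex density) and per-class length-normalized,
standard-scaled multivalency sums, with an optional merge map to fold
correlated GC-like classes into one; classifier training itself is out of
scope.

## RBP binding and CLIP statistics

Binding potential converts a table of per-5-mer in vitro enrichments
(RBNS R scores) to z-scores using the table's own mean/sd, keeps motifs with
one-sided upper-tail normal P < 0.05 (boundary excluded), and sums
count × z over a rolling 5-nt window.

The multivalency-preference statistic: every CDS 5-mer instance receives the
percentile of its raw score within the distribution of that same 5-mer
transcriptome-wide (single-instance 5-mers get percentile 50, the
uninformative value for a degenerate distribution). Each crosslinked
nucleotide maps to the ≤ 5 covering 5-mer instances (configurable to the
single 5-mer starting at the crosslink); crosslink-weighted mean percentiles
are aggregated per 5-mer, and the mean over the 50 most crosslinked 5-mers
(ties lexicographic) is divided by the mean over all others. Samples with
ratio ≥ 1.1 are multivalency-preferring. Sample QC drops the bottom third
by CDS-crosslink proportion, then the bottom third of the remainder by raw
CDS crosslink count.

Region-level enrichment is the crosslink density inside a region over the
density in the rest of that CDS (transcripts restricted to the top half by
CDS crosslink density; an optional 0.5-crosslink pseudocount floors empty
denominators), averaged per sample and cluster. Metaprofiles sum crosslinks
by position relative to region midpoints, normalized by region count and
millions of crosslinks in the sample.

## The simulator and what the tests show

`simulate_transcriptome` emits multi-exon spliced transcripts (3–12 exons,
log-normal length weights; half the genes on the minus strand so the GTF
round trip exercises strand logic) whose CDSs (350–650 codons) are drawn
codon-by-codon from a bundled human-like codon usage table — hence no stop
codons can arise internally and none are appended. A planted fraction
(default 10%) carries one 250–400 nt region drawn from a class recipe: GA
(R/K/E/G/D/S-rich amino acids, AGA/AGG arginine bias — an R-MCD by
construction), CAG (poly-glutamine), GC (R/A/P/G with CGG/CGC bias) and C
(P/S/T/H-rich). The codon-bias strength (default 0.9) is the probability a
degenerate codon follows the class-consistent choice rather than the usage
table. Conservation tracks are baseline + Gaussian noise (sd 0.3) plus a
bonus δ at mutable positions whose codon ratio exceeds 1; crosslink tracks
are multinomial over CDS positions, uniform or region-enriched by a factor.
Everything is deterministic under the config seed, including emitted files.

Two honest caveats. First, at bias 0 the planted amino-acid pools alone
still elevate multivalency somewhat — that is the structure of the genetic
code, not a bug — so the bias gradient is monotone rather than on/off.
Second, random-sequence "noise" regions have mutually similar k-mer fraction
vectors and can form their own embedding cluster rather than scattering;
recovery tests therefore score the planted regimes and do not require noise
to be labelled −1.

The simulator reproduces the statistical skeleton the methods target —
planted repeats, codon bias, conservation bonuses, enriched crosslinking —
but not real-data features such as isoform structure beyond one transcript
per gene, composition gradients along CDSs, mappability artefacts, or
antibody-specific CLIP backgrounds. Passing tests demonstrate correctness
and calibration of the statistics under known truth, not biological
conclusions about any particular transcriptome.

## Problem sizes

The test and acceptance runs use: 100 random sequences (200–2000 nt) for
scorer/oracle agreement; a 200-transcript simulation (20 planted) for region
recovery; 100 single-transcript fixtures × 10 shuffles × 2 scopes for the
shuffle null; 20 transcripts (~4000 mutable positions) for the codon-ratio
oracle; 5000 conservation records; 900 regions + 10% noise for clustering;
300 R-LCDs for the arginine regimes; 200 null CLIP samples at 10⁴
crosslinks plus one enriched sample at 10⁵; and ten ≤ 10-codon recoding
toys checked against exhaustive search.
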