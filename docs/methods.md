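# Methods

This note documents the models and procedures implemented in `soymir`, the
defaults they ship with, and what the synthetic data does and does not
emulate.

## Study design

The analysis is organized around a 16-library crossing: two genotypes (a
low-nitrogen tolerant line "116" and a sensitive line "84"), two tissues
(root, shoot), two stress terms (short, long — each a pool of several
sampling time points) and stress vs. control treatment. Differential
expression always compares a stress library against the control matched on
genotype, tissue and term, giving eight comparisons. Pooling of time points
is modeled as a single library per term, since sequencing only ever saw the
pools.

## Read processing

The 3' adapter is located by the longest prefix of the adapter sequence
(>= 8 nt) occurring in the read, with a 3'-anchored partial overlap of >= 6
nt as fallback. A read is kept iff its trimmed length lies in [18, 30] nt
(the lower bound reads the "longer than 18 nt" convention inclusively, as is
standard for small RNA work; both bounds are parameters), its mean Phred
quality is >= 20, it contains no N, and it is not >= 80% A after trimming
(the poly-A rule makes the otherwise unspecified contaminant classes
concrete). Identical clean reads collapse into unique tags with one count
column per library; mapping is exact-match on both genome strands through a
k-mer seed index with verification, so the contract is "all exact
occurrences". Multi-mapping tags are counted once per library, not
fractionally, because abundance is tallied per tag, not per locus.
Percentages in the stats table are reported to two decimals.

## Known-miRNA variant unification

Tags are aligned to precursors by exact substring search. The hairpin
midpoint (sequence midpoint by default; a structure-derived midpoint can be
supplied) splits each precursor into a 5' and a 3' arm; tags spanning the
midpoint are excluded. Per library and arm, the most abundant tag wins,
ties broken by smaller offset then lexicographic sequence.

Across libraries, let T be the tag that wins in the most supporting
libraries (ties toward the higher total count). T is the *unified most
abundant variant* iff it wins in more than `majority_frac` (default 0.5, a
strict majority) of the supporting libraries, and in every library won by
another tag U, count(T)/count(U) >= 1/`closeness_ratio` (default 2.0, i.e.
"close" means within two-fold). Both parameters are exposed because the
qualitative rule they implement ("most libraries", "close in frequency")
has no canonical numeric reading. Non-unifiable arms are reported as such;
when the per-library winners partition cleanly by genotype the arm is
additionally flagged variety-specific.

The arm with the larger total window count is the miRNA; the opposite-arm
variant is the miRNA* even when sequenced once in a single library.
Precursors whose winning arm differs between libraries are flagged
arm-switching. Counts aggregate over tags on the same arm whose start
offset is within `window` (default 2) nt of the variant's start — the
window constrains the start only, since a single positional distance is
being modeled; aggregation is monotone in the window size by construction.
A long precursor can host a second duplex: a non-overlapping same-arm
variant with total count >= `min_secondary` (default 100) and a
duplex-positioned opposite-arm partner is emitted with a `-2` name suffix.

Variants are classified against annotated matures as identical /
shifted-same-arm (overlapping footprint, different boundaries) /
opposite-arm / novel-arm.

## Secondary-structure backend

The internal folder minimizes a deliberately simple energy:

* pairs: Watson-Crick and G:U, minimum hairpin loop 3 nt;
* +3 kcal/mol per hairpin loop (a pair whose interior is completely
  unpaired);
* -2 kcal/mol for each Watson-Crick pair stacked directly on another pair,
  -1 for a stacked G:U.

Interior loops, bulges and multiloops are free. The optimum is computed by
dynamic programming over three tables (unconstrained, >= 1 pair, and
closed-by-a-pair) and is exact for this model; tie-breaking is
deterministic (the traceback pairs the 5'-most base first and prefers
stacked continuations), and the reported energy is re-derived from the
returned structure as a self-check. A perfect n-bp stem scores
3 - 2(n - 1), so a 30-bp stem reaches -55 kcal/mol. Because multiloops are
free, long random windows also reach very negative energies — exactly as
with thermodynamic folders on 200+ nt windows — so the MFE cutoff screens
only degenerate candidates and the discriminative power lies in the arm,
duplex and miRNA* criteria. An RNAfold-based backend can be swapped in via
`fold(seq, backend="rnafold")`; all bundled analyses and tests use the
internal backend for determinism.

## Novel miRNA discovery

Mapped tags overlapping known precursor loci or ncRNA annotation on either
strand, or exons on the sense strand, are removed; intronic and
antisense-exon tags remain, which is what allows intron-hosted miRNAs to be
found. Seed tags need a 16-library total of at least `min_candidate_count`
(default 20) — the Mireap-style minimum locus depth; without it every
stray degradation read would nucleate a candidate window. Hits within
`merge_dist` (default 200 nt) merge into one locus, +/-`flank` (default
100) nt windows are extracted (minus-strand windows reverse-complemented so
the tag reads 5'->3'), and each window is folded.

A candidate passes the hairpin screen iff: MFE <= -20 kcal/mol (reading the
reported "less than 20 kcal/mol" with the physically required sign; the
cutoff is configurable); the mature tag is 18-25 nt and lies entirely on
one arm (all paired partners on one side, no pairing within its own
footprint); the mature/star duplex has <= 4 mismatches under an ungapped
antiparallel alignment with +/-2 nt shift tolerance; and the enclosing
hairpin spans 80-376 nt (the observed size range of plant pre-miRNAs, used
as a configurable acceptance window since the text leaves criterion vs.
observation ambiguous). Calling then requires a sequenced miRNA* — a
mapped tag within 2 nt of the predicted star segment — in at least one
library, and a total mature window count strictly over `min_total`
(default 100). Overlapping loci deduplicate to the higher-count candidate,
strand-agnostically: with a perfect stem, every stem tag also maps
antisense at its mirror position, so one physical locus can surface on
both strands.

Called miRNAs are numbered in descending count order (`novel-soy0001`...);
single-linkage clustering of matures (<= 2 mismatches, end shifts <= 2 nt)
defines families, whose members take letters a, b, ... by descending count.
Host-gene annotation labels each locus intergenic or `intr<k>`/`exon<k>` of
its host gene, numbering exons along the gene's strand and flagging
antisense placement.

## Differential expression

Counts are normalized as TPM = count x 1e6 / library size, the library
size being genome-mapped clean reads (configurable to total clean reads).
Fold change is log2(stress/control) after replacing zero TPM with 0.01;
miRNAs below 1 TPM in both compared libraries are excluded. Significance
uses the Audic-Claverie conditional-Poisson model: given count x in a
library of size N1, the probability of y in a library of size N2 is the
negative-binomial mass nbinom(y; x+1, N1/(N1+N2)). Tails are evaluated via
the regularized incomplete beta function (exact in log space for large
counts; verified against direct summation of the mass function to < 1e-10
for all counts <= 200). The reported p-value doubles the smaller tail,
capped at 1; a single-tail mode is available because tail conventions vary
across digital-tag pipelines. The normalized form of the mass function
(denominator exponent x+y+1) is used; variants quoted without the +1 do
not sum to one over y.
The test is exactly symmetric in its mass function for N1 = N2 but only
approximately symmetric in its tail p-values, since it conditions on the
first count.

A miRNA is considered only if its raw count strictly exceeds `min_reads`
(default 100) in at least one compared library. Calls: up if log2FC >= 1
and p <= 0.05, down if log2FC <= -1 and p <= 0.05. No multiple-testing
correction is applied in the classification (matching the single-library
design's convention); Benjamini-Hochberg q-values are reported alongside
for reference. Set logic over comparisons returns intersections and
per-comparison exclusive sets at variant or family granularity, a family
being the name stripped of arm suffix, variant number and paralog letter.

## Target prediction

The miRNA is aligned antiparallel and ungapped to every transcript window
of its own length: Watson-Crick = 0, G:U = 0.5, otherwise 1 mismatch unit.
Sites with score <= 2.0 and no mismatch at miRNA positions 10-11 are
reported. By default a G:U at positions 10-11 also rejects the site (the
stricter reading; `allow_wobble_central=True` relaxes it). DNA transcripts
are handled by U/T equivalence. Bulges and the psRNATarget expectation
machinery are out of scope.

## qPCR normalization

Ct values convert to quantities via q = E^(Ct_min - Ct) with amplification
efficiency E = 2.0 by default (perfect doubling; configurable), triplicates
summarized by mean Ct first. geNorm M for gene j is the mean over other
genes k of the SD across samples of log2(q_j/q_k); iterative exclusion of
the highest-M gene yields the ranking, with the final indistinguishable
pair reported jointly. V_{n/n+1} is the SD across samples of
log2(NF_n/NF_{n+1}) with NF_n the geometric mean of the n most stable
genes; the smallest n with V < 0.15 is recommended. Target expression is
the target quantity divided by the geometric mean of the chosen
references; stress/control ratios are reported in log2. These statistics
are invariant to per-sample global scaling by construction. A utility
validates the stem-loop RT primer convention (44-nt self-looped backbone
plus a 6-nt tail reverse-complementary to the miRNA 3' end).

## Synthetic data: what it emulates, and what it does not

Planted pre-miRNAs are perfect stems (stem + loop + reverse complement), so
any folding backend recovers the hairpin and the star is the exact
2-nt-overhang duplex partner. Expression means are expected read counts
per library at a reference depth of 1e5 and scale linearly with depth, so
composition and planted fold changes are depth-invariant. Defaults for the
bundled study: 30 known precursors (three paralog families among them, with
one-substitution matures), 5 novel hairpins (one inside a gene intron), 2
no-star decoys, 2 low-count decoys (mean 4 reads/library, total ~64), 2
expressed non-hairpin loci, 10 planted effects of |log2FC| = 2 at mean 800
reads/library, 3 low-expression precursors (mean 8, to trip the over-100
count filter) and 2 rare precursors (mean 0.15, to trip the both-below-1-TPM
exclusion); mature:star ratio 10:1; 10% of mature reads become +/-1-2 nt
isoforms; background fills the remaining depth with genome-derived reads
(length distribution peaked at 24 nt with a 21 nt mode, so total reads peak
at 21 nt and unique tags at 24 nt), plus 2% unmappable reads and 5%
injected contaminants. Counts are multinomial draws at fixed depth,
deterministic per seed; per-library generators derive from the study seed.

Background reads are drawn only from unplanted genome regions: planted loci
emit hairpin-derived reads exclusively. Without this, antisense degradation
fragments landing on a planted hairpin satisfy the "miRNA* detected"
criterion and the no-star decoy class stops testing anything.

Not emulated: sequencing errors, genotype-level sequence divergence,
imperfect stems (real pre-miRNA bulges), expression correlation between
tissues, and ratio compression from highly multi-mapping tags. Passing
tests on this data therefore demonstrate the correctness of the
algorithms' logic and their statistical calibration, not robustness to
alignment ambiguity or base-call noise.

Truth recovery is measured over precursors that received at least one
aligned read; a rare precursor sampled zero times is unrecoverable by any
method, mirroring real precursors that are not well-supported in some
libraries.

## Numerical and degenerate-input choices

Ties in per-library winners break toward smaller offset then lexicographic
sequence; unification ties toward the higher total count. The folding
traceback order (5'-most pair, stacked continuation preferred) is fixed and
asserted against the reported energy. Empty arms, empty tag tables and
zero library sizes raise errors rather than returning silent defaults.
Window extraction clips at chromosome ends. The acceptance script's only
randomness is the seeded construction of the example duplex.

## Problem sizes

The bundled simulation runs 16 libraries of 1e5 reads on a 2 x 200 kb
genome (about one million unique tags); the full suite, including two such
studies and the brute-force p-value oracle up to counts of 200, completes
in a few minutes on one CPU. Unit tests use a 2e4-read study of identical
structure.
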