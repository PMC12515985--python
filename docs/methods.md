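# Methods

This note defines every statistic the package computes, the defaults and
why, the numerical conventions, and what the synthetic generators do and
do not emulate.

## Coordinates, strands and the gene vocabulary

Internally all intervals are 0-based half-open; GenBank's 1-based
inclusive convention exists only at the file boundary (Biopython converts
on read and write). The deposited strand is called H (heavy); features
annotated on the complement are strand L and are reverse-complemented on
extraction. Compound (`join`) locations are kept as ordered interval
lists in transcription order and arise only for origin-spanning features
on circular genomes.

Gene labels are normalised onto a canonical 37-gene vocabulary
(ATP6/8, COX1–3, CYTB, NAD1–6 + NAD4L, trnA…trnY with split
trnL1/trnL2 and trnS1/trnS2, rrnS/rrnL) through a synonym table
(COI→COX1, ND2→NAD2, 16S→rrnL, trnL(CUN)→trnL1, …) because deposited
records from different submitters name the same genes differently.
Unknown labels become `other` with a warning, not an error.

Ambiguity codes other than N are rejected at parse; N is allowed but
excluded from the numerator *and* denominator of every statistic, since
all quantities here are defined over A/C/G/T.

## Composition and skews

For a sequence with base counts A, C, G, T:

    AT content = (A+T)/(A+C+G+T)
    AT skew    = (A−T)/(A+T)
    GC skew    = (G−C)/(G+C)

A skew whose denominator is zero is *undefined* (reported as null), never
coerced to 0. Whole-genome statistics are computed on the deposited (H)
strand as-is — the convention under which these mitogenomes show negative
AT skew. Dataset rows (whole / PCGs / tRNAs / rRNAs) concatenate
strand-corrected gene sequences in genome order; overlapping genes are
each counted in full, so dataset lengths can exceed the unique genomic
span (noted here because databases differ on this choice).

Positional (codon-site) composition is computed over the stop-free,
in-frame part of each coding sequence. GC1/GC2/GC3 are GC fractions at
codon positions 1/2/3 over **all** sense codons (no restriction to
synonymous or four-fold families — the A3/T3/C3/G3 counts feeding the PR2
plot use whole-gene third positions), and GC12 = (GC1+GC2)/2. GC12 is
always per-gene, over that gene's own codons; genes are never pooled
codon-weighted.

## Coding-sequence extraction

A PCG's stop is classified from its final 3/2/1 nt: TAA/TAG → complete;
a trailing TA or T → an incomplete stop completed post-transcriptionally
by polyadenylation. The trimmed sequence excludes the stop or incomplete
tail, is validated to be a whole number of codons with no internal stop
under the gene's code (default table 5), and is the universe for all
codon counting. Start codons (ATN, also TTG/GTG) are counted at face
value as their literal triplet — they occupy a codon slot.

## RSCU and bias classes

Within a synonymous family of size k with total count N,
RSCU(c) = count(c)·k/N; 1.0 is unbiased, and the family's RSCU values sum
to k. Stop codons are excluded from the universe (62 sense codons under
table 5; family-size multiset 12×2, 6×4, 1×6, 1×8). Thresholds: strictly
RSCU > 1.6 → overrepresented, strictly RSCU < 0.6 → underrepresented,
values in [0.6, 1.6] unbiased; a family with zero observations is
*undefined*, not 0. Multi-species pooling offers two labelled modes:
the default averages per-species RSCU vectors codon-wise; the alternative
computes RSCU of the summed count table. They differ whenever species
contribute unequal codon totals, so neither is silently substituted for
the other.

## PR2 and neutrality analyses

PR2 coordinates are x = G3/(G3+C3), y = A3/(A3+T3); either is undefined
(error naming the axis) when its denominator is zero. Quadrants follow
the standard Cartesian convention about (0.5, 0.5) — I: x>0.5,y>0.5;
II: x<0.5,y>0.5; III: both <0.5; IV: x>0.5,y<0.5 — with boundary points
assigned to none, and the convention is recorded in output metadata.

The neutrality fit is ordinary least squares of GC12 on GC3 with
Pearson r and its exact two-sided t-transform p-value at n−2 df (no
permutation test: at the n ≈ 12 typical of these cohorts the t-transform
is standard). Degenerate inputs are errors (n < 3; zero GC3 variance); a
constant GC12 returns slope 0, r 0, p 1 rather than 0/0. The decision
rule, applied mechanically at alpha = 0.05 and slope cut 0.5:

* p ≥ alpha → `selection_dominant` (GC3 uninformative about GC12);
* p < alpha and slope ≥ 0.5 → `mutation_dominant`;
* p < alpha and slope < 0.5 → `co_dominant`.

Significance is additionally reported at the 0.05 and 0.01 tiers in
summaries. No multiple-testing correction is applied across genes — the
per-gene classification is descriptive, matching field practice for
13-gene panels. Boundary semantics: slope exactly at the cut counts as
mutation-dominant, p exactly at alpha as non-significant.

## Nucleotide diversity

π is the mean over all unordered row pairs of (pairwise differences /
pairwise compared sites). Default missing-data handling is **pairwise
deletion** — a column is compared for a pair only when both rows have
A/C/G/T there, so each pair has its own denominator; a pair with no
comparable site is dropped from the average. **Complete deletion**
(only columns valid in every row) is available behind a flag: the choice
matters for gappy alignments and popular desktop tools differ, so both
are offered and labelled. Sliding windows are anchored at column 0 of
the concatenated alignment in the partition table's gene order, advance
by `step`, and drop trailing partial windows; the reported coordinate is
the window start. Defaults are 200 bp windows at 20 bp steps, with
100/20 one flag away — both settings circulate in the comparative
literature and the package takes no position on which is canonical.
π is reported to 3 decimals in summaries and at full precision in
machine output.

## Synthetic generators

The genome generator emulates a stylommatophoran land-snail mitogenome:
circular, default 14.5 kb, 37 genes with Camaenidae-like sizes
(13 PCGs summing ≈ 10.9 kb, 22 × 60 nt tRNAs, rRNAs of 800/900 nt),
split 9 PCGs + rrnL + 13 tRNAs on H vs. 4 PCGs + rrnS + 9 tRNAs on L,
and targets AT = 0.70 with AT skew −0.10 and GC skew +0.10 on each
gene's coding strand — mid-range values for this family. PCGs are a
start codon drawn from {ATG 0.70, ATA 0.15, ATT 0.10, TTG 0.05}, codons
sampled i.i.d. from a 62-entry frequency vector (by default derived from
the base targets, so PCG composition tracks the genome-wide targets),
and a stop drawn from {TAA 0.70, TAG 0.15, T- 0.10, TA- 0.05} —
proportions chosen to mirror the usual census shape (ATN starts and TAA
stops dominant, incomplete stops present). tRNA/rRNA/intergenic tracts
are i.i.d. bases at the target composition. L-strand genes are stored
reverse-complemented, which dilutes the *whole-genome* skew relative to
the per-gene target (as in real two-strand genomes); the AT *content*
target is unaffected and is realised within sampling error (±0.02 at
14 kb). The truth record stores realised per-dataset base counts,
per-gene codon counts and the start/stop census, all recomputable from
the emitted files — generator/pipeline agreement is the module's core
cross-check.

Alignments use a **star phylogeny**: an ancestral row i.i.d. uniform over
A/C/G/T, each taxon independently substituting each site with probability
p (uniformly to one of the other three bases; single hit, no within-
partition rate variation). This is deliberately not a coalescent: the
point is the closed-form expectation

    E[π] = 2p(1−p) + (2/3)p²

(one lineage mutates → always a difference; both mutate → differ with
probability 2/3), which makes π testable to Monte-Carlo precision.
Per-partition rates provide rate heterogeneity across genes. No indels
are simulated; gap handling is exercised with hand-written fixtures.

What passing tests therefore show: the arithmetic of every statistic is
right, strand/coordinate bookkeeping is exact, and the estimators recover
known parameters at realistic sizes. What they do not show: robustness
to real annotation noise (wrong boundaries, missing genes), alignment
error, indel-rich regions, or phylogenetic correlation between taxa —
real cohorts violate the star assumption, so π comparisons there are
descriptive, not model-based.

## Problem sizes and determinism

Stochastic checks run at 20 taxa × 10 kb alignments (three substitution
rates 0.02/0.1/0.3), 10⁴ codons for RSCU recovery, and 12-point
neutrality sets — sizes matching the cohorts this kind of study uses,
where all expectations are comfortably resolvable. All randomness flows
through `numpy.random.default_rng` seeds; identical spec + seed yields
byte-identical output.
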