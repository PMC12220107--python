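# Methods

This note documents the models, conventions, and numerical choices behind
`tescope`, and what the synthetic data generator does and does not
emulate.

## Coordinates and formats

All internal coordinates are 0-based, half-open. RepeatMasker `.out`
records (1-based inclusive) and VCF `POS` (1-based) are converted exactly
once, at the parsing boundary, and converted back on write; BED and the
package's own TSV dialects are already half-open. Malformed annotation
lines are skipped, counted and reported rather than aborting a parse;
structurally fatal problems (duplicate FASTA names, inconsistent sample
rosters across VCF records) raise immediately.

Repeat families map to major TE classes (DNA, LINE, SINE, LTR, RC,
Unknown, non-TE) through an editable TSV resource
(`tescope/data/te_classes.tsv`). Resolution order: an explicit
RepeatMasker `class/family` column wins, then an exact name match, then
the longest matching name prefix (so `hAT-Tip100_Hv3` inherits from
`hAT-Tip100`); anything unresolved is `Unknown`, which still counts as TE
in coverage unions — unclassified interspersed repeats are predominantly
decayed TEs, and erring the other way would deflate TE fractions.

## Divergence model

The copy-age statistic is the Kimura two-parameter distance
`K = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]` over ungapped aligned columns; gap
columns never count as sites or substitutions. `P` and `Q` outside the
domain (`1-2P-Q <= 0` or `1-2Q <= 0`) raise a saturation error carrying
the offending proportions; saturated copies fall into the landscape's
overflow bin rather than being dropped. CpG-aware counting
(`cpg_mode="exclude"`) removes both columns of any consensus CpG
dinucleotide (paired across gaps) before counting, for users whose
consensus libraries are CpG-rich; the default is to include them.

The simulator's `mutate_copy` evolves a consensus under the same model.
Rates are normalized so branch length equals expected substitutions per
site (`alpha + 2*beta = 1`, `alpha/(2*beta)` = the transition/transversion
ratio, default 2.0), and each site draws its fate from the exact K2P
transition probabilities at distance `K`. The returned truth record holds
the realized transition/transversion counts, so estimator tests compare
against realized — not merely expected — substitution histories. Requests
beyond the saturation bound (expected `1-2P-Q < 1e-3`) are rejected: the
distance is analytically unrecoverable there.

## Coverage accounting

Per-family coverage is the length of the union of that family's hit
intervals (overlap-merged); overlapping hits of *different* families each
receive full credit in their family's tally but count once in the TE
union, so per-family numbers match RepeatMasker-style accounting while
the genome TE fraction stays ≤ 1. Landscapes assign each hit's full
merged length to the 1-percentage-point bin containing its `K × 100`
(half-open bins over [0, 55) plus overflow), so landscape row sums equal
the family coverage of divergence-bearing hits exactly. Hits with neither
a linked alignment block nor a `divergence_pct` are excluded and counted.

## Differential coverage and A-TE calling

The active-family criterion is purely the bp-coverage delta: strictly
greater than the threshold (2.5 Mb at full scale, supplied rescaled for
smaller genomes — the packaged synthetic genomes are 1/100 scale, hence
25 kb). The log2 fold change is computed and reported (with ±inf/NaN
sentinels for empty sides) but not used for calling. The attribution
statistic sums only family deltas whose sign agrees with the
assembly-size difference; a family that shrank in the larger assembly
does not offset the expansion being attributed. This choice is flagged in
the output because the alternative (signed net sum) is equally defensible;
the positive-direction sum answers "how much of the growth is TE growth".

## Insertion typing

The two filters follow different boundary conventions on purpose,
matching their phrasing: the length filter is strict ("larger than 1 kb"
excludes exactly 1000 bp), the annotation span is inclusive ("500 bp or
more" admits exactly 500 aligned columns). Genotype classification over
a lineage-labelled roster: `specific:<L>` iff the carriers are exactly
lineage L's samples, `shared` iff every sample carries the call, and any
other non-empty pattern is preserved losslessly as
`shared-subset:<lineages>` rather than forced into either bin.

TE annotation runs an exact Smith–Waterman (Biopython PairwiseAligner,
local mode; +2/−3 match/mismatch, −5/−2 affine gaps) against every
library consensus on both strands; the span is the local alignment's
column count, gaps included; ties break by score, then family name. An
edit-distance prescreen (edlib, infix mode) can rank the (family, strand)
candidates first so the quadratic alignment only runs on the top few —
the pipeline default evaluates the top 2 candidates, which reproduces the
exhaustive result on every synthetic cohort tested while cutting runtime
roughly six-fold. Exhaustive mode remains available and is what the
boundary and tie-break tests exercise.

Target-site duplications: the detector looks for the longest suffix of
the left flank equal (up to a configurable mismatch budget, default 0) to
a prefix of the right flank, length 4–25 bp. The pipeline convention —
left flank = tail of the inserted sequence, right flank = reference bases
immediately 3′ of the anchor position — reflects how a TSD appears in
reference-based insertion calls: the inserted allele ends with a copy of
the target site whose other copy begins right after the anchor. The
simulator plants TSDs the same way (the motif is copied from the
reference target site) and rejection-samples non-TSD insertions so no
accidental junction duplication of detectable length exists, keeping
truth labels exact.

## Enrichment statistics

`fisher_exact` computes the two-sided p as the sum of hypergeometric
probabilities not exceeding the observed table's probability (1e−7
relative slack against floating-point ties; zero-margin tables give
p = 1). It is backed by `scipy.stats.hypergeom` and tested against an
exact-rational enumeration oracle over every 2×2 table with N ≤ 40.
`wilcoxon_rank_sum` uses the exact permutation null when n+m ≤ 20 with no
ties and the tie-corrected normal approximation with continuity
correction otherwise (via `scipy.stats.mannwhitneyu`); the exact path is
verified against a subset-sum enumeration oracle over every achievable
rank sum. The doubled-tail convention is used for two-sided exact p. If
all values across both samples coincide, p = 1.

Open-chromatin enrichment counts any-bp intersection of insertion anchors
with the OCR set, per category, and tests each category against a
reference category (default: shared insertions) — the contingency
construction is explicit and configurable because the comparison group is
an analysis choice. GO overrepresentation is the classic one-sided
hypergeometric per term (no GO-graph propagation), with
Benjamini–Hochberg q-values alongside raw p. "Standardized expression
variance" is CV² (population variance over squared mean across cells),
computed for genes with positive mean; this operationalization is an
assumption and is isolated in one function so an alternative can be
swapped in.

Nearest-gene distances are signed: negative when the insertion lies
upstream of the gene's 5′ end on the gene's strand (the regulatory
reading); equidistant genes resolve to the leftmost by start coordinate.

## Retention clustering

The species × family matrix holds each family's share of the species'
total TE coverage (non-TE families excluded; rows sum to 1). Families are
clustered by average-linkage hierarchical clustering on Euclidean
distances between their raw share vectors. Standardizing each family row
first was evaluated and rejected as the default: it erases the share
*level*, so any ubiquitous low-share family becomes indistinguishable
from the core block (planted-core recovery fell from 20/20 seeds to 0/20
with standardization). `scale_rows=True` remains available for users who
want pattern-only clustering. The flat cut defaults to √(number of
families) clusters; the core set is the highest-mean-share cluster,
filtered to members holding at least a 1% share in at least 90% of
species. The cluster count, linkage, metric and both core thresholds are
parameters.

## Contact ranges

Contacts are symmetrized on load (indices canonicalized, duplicates
summed; total intensity conserved). The distance-decay background at
separation d is the mean intensity over *all* possible cis bin pairs at
that separation, absent records counting as zero. A bin's interaction
range is the farthest separation at which its observed intensity (mean of
its left/right partners) meets θ × background and is nonzero; the
nonzero guard keeps empty separations with an all-zero background from
qualifying. θ defaults to 1.5: at θ = 1 any stray single contact at a
sparse long-range separation exceeds the tiny background mean, so every
bin's range collapses to the window edge and the statistic carries no
signal; 1.5 restores a margin while keeping the no-association null
calibrated (7.5% of 40 null replicates below p = 0.05 in the packaged
check). The comparison splits bins at the top/bottom a_te_fraction
quartiles (configurable) and uses the rank-sum test.

## TE-transcript rules

A long read is TE-derived when its best single-consensus local alignment
spans strictly more than 1 kb ("over 1 kb"), using the same alignment
engine and span definition as insertion annotation. The spliced-leader
detector requires the configured SL motif within the first 30 bases with
at most one mismatch; the motif has no default because it is
organism-specific (the synthetic generator uses its own 18-mer). The
top-expression membership rule takes families at or above the (1−q)
empirical quantile, ties included.

## What the synthetic data emulates — and what it does not

The generator reproduces the statistical *structure* the analysis relies
on, at 1/100 genome scale (two ~10 Mb haplotypes, 20 families, ~40% TE
content): a haplotype pair whose size difference is entirely planted TE
expansion (8 families above the scaled A-TE cutoff, 4 below, 8
unchanged); copies diverged under K2P with per-copy realized-count truth;
a 3-lineage cohort of shared plus lineage-private insertions with
configurable missing-genotype and sub-1-kb fractions, diverged library
copies as TE insertions, planted TSDs, and lineage-dependent
open-chromatin overlap via rejection sampling (OCRs cover 8% of the
synthetic genome; the i-cell lineage defaults to a 0.5× multiplier); a
Poisson contact map with power-law decay (exponent 1.0, base intensity
100) whose per-bin intensity is lifted by `1 + multiplier × coverage`;
a 12-species retention panel with a planted 12-family core block
(70% combined share, noise sd 0.005, bystander presence 0.8); and
transcript reads with planted SL rates (0.30 TE / 0.48 non-TE).

It does **not** emulate read-level noise (no FASTQ or error model —
the pipeline starts at annotation/call level), annotation artifacts
(overlapping or mis-assigned RepeatMasker hits beyond what coverage
merging handles), nested insertions, population structure beyond the
lineage labels, Hi-C normalization biases, or GO-term correlation
structure. Passing tests therefore demonstrate correctness of the
computations and detectability of the planted effects under clean
conditions, not robustness to upstream calling errors in real data.

Determinism: a `SimulationConfig` with a fixed seed yields byte-identical
fixture files; every emitted record appears in exactly one truth-table
row. Each sub-generator derives its own child seed from the config seed,
so cohorts, haplotypes, features and reads can be regenerated
independently.

## Problem sizes

The packaged checks run at the scale the synthetic study design
prescribes: 10 Mb haplotypes for coverage/differential work; 500-insertion
cohorts for typing (exact truth agreement, including boundary cases);
700-vs-3000 category sizes for open-chromatin depletion power and
2500-per-category cohorts with a denser (20%) OCR track for the
null-calibration check, where the exact-test p lattice is fine enough for
a Kolmogorov–Smirnov uniformity test; 800 contact bins (200 per quartile
group) for range-association power. The full simulate-plus-run pipeline
completes in under a minute on one CPU, and the whole test suite in a few
minutes.
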