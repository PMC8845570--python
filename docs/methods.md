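# Methods

This note records the models, parameter choices and numerical conventions
behind each stage of the pipeline, and what the synthetic generators do and
do not emulate.

## Growth-curve quantification

A well's trace is A600 absorbance sampled every 10–20 min (simulated at
15 min) for 4 days. The automated caller operates on a median-smoothed copy
of the trace (window 5 points), which removes isolated single-reading
artifacts such as bubbles or transient precipitation without displacing a
genuine sigmoid. Growth onset ("min") is the first point where the forward
slope exceeds `slope_epsilon` (default 1e-4 AU/min) for two consecutive
sampling intervals *and* the curve later rises at least `rise_delta`
(default 0.02 AU) above that point; the endpoint ("max") is the global
maximum of the smoothed trace at or after onset. Curves with no qualifying
onset return a degenerate zero-width window; if their raw span nevertheless
exceeds the no-growth threshold they are flagged for manual review rather
than silently called — the flag replaces interactive curation, keeping the
pipeline deterministic. The three caller parameters are the package's own:
the onset rule was chosen so that a quadratic brute-force search over all
(min, max) point pairs under the same rise constraint reproduces its total
growth on essentially all noiseless sigmoids (the test suite requires
≥ 99% agreement over 500 random curves).

Total growth is G = A600(max) − A600(min) with the strain's mean
negative-control growth subtracted and the result clamped at 0 (growth is
defined as an increase, and sub-threshold values are zeroed anyway). Rate
is G/(t_max − t_min), 0 for degenerate windows. Thresholding follows the
two-replicate rule: each replicate with G ≤ 0.1 is individually no-growth,
and if either replicate fails, both are zeroed. Replicates are then
averaged (a symmetric choice; the alternative of taking the maximum would
bias recovered growth upward under noise). Normalization is two-stage and
independent for growth and rate: rows (strains) are scaled so the best
substrate is 1.0, then columns (substrates) so the best strain is 1.0.
All-zero strain rows — which occur in practice for poorly growing taxa —
are left at zero and reported in a warning list instead of raising.
Medium formulation is carried as strain metadata only; the two-stage
normalization is the entire between-medium correction.

## Clustering and species coherence

Strains are clustered by complete-linkage agglomeration on Euclidean
distances between profile rows; with `features="both"` the normalized
growth and rate blocks are concatenated unweighted, both already being on
[0, 1]. The species clustering index divides a species' strain count by
the leaf count of the smallest clade containing all of its strains, so a
pure clade scores exactly 1 regardless of species size; single-strain
species score 1 by definition and are marked uninformative. "Branches" is
read as terminal leaves of that minimal clade — the alternative reading
(number of maximal pure clades) agrees on pure clades, which is the only
regime the tests assert exactly. Substrate co-occurrence is the pairwise
Pearson correlation across strains of normalized growth; zero-variance
columns produce missing entries rather than spurious values, and |r| ≥ 0.40
is the default reporting flag.

## Gene families and PULs

Pairwise protein identity is defined reproducibly as matches divided by
alignment columns (gaps included) of a global alignment under
match = 1 / mismatch = 0 / gap = −1; among co-optimal alignments the
aligner's deterministic first traceback is used. Families are connected
components of the between-genome reciprocal-best-hit graph at ≥ 90%
identity (the cutoff is inclusive), with within-genome duplicates merged
into their family at the same cutoff — so a family counts distinct genes,
not alignment columns. An exact edit-distance prefilter skips pairs that
provably cannot reach the cutoff (identity ≥ c implies edit distance
≤ (1 − c)(|p| + |q|)), which keeps all-vs-all construction tractable
without changing any result.

PUL calling makes the canonical definition operational: every adjacent
susC–susD tandem (either order; strand affects nothing but gene order)
seeds a span extended in both directions over susC/susD/GH/PL/CE/
sulfatase/regulator genes, tolerating at most `max_gap = 2` consecutive
unrelated genes; spans without a degradative CAZyme are discarded and
overlapping spans merged. This is a deterministic stand-in for
informatics-plus-manual annotation, and adjacent PULs that a curator might
split are reported merged. Cross-genome PUL homology uses a ≥ 50%
shared-family rule. Gene activation is strict (> 10-fold), so a gene at
exactly threshold is not activated; a PUL is activated by any member gene.
ORF-length QC flags families whose shortest member is under half the
longest (strictly), a frameshift/mis-assembly signal for manual review.

## LGT screen

Single-copy core families (copy number exactly 1 in every genome of both
species) are aligned with a deterministic star-progressive aligner: the
center sequence minimizes total k-mer distance to the rest, every other
sequence is globally aligned to it, and pairwise alignments are merged
under once-a-gap-always-a-gap; pre-aligned input bypasses this. Gene trees
are neighbor joining on Jukes–Cantor-corrected distances (gap columns
excluded pairwise; saturated pairs with p ≥ 0.75 raise an error naming the
pair; negative NJ branch lengths are clamped to 0 before patristic
computation). NJ replaces approximate-ML deliberately: it is exact on
additive matrices, dependency-free and fast at 10–33 taxa, and for the
clock-like data simulated here median patristic and median corrected
distances converge — `distances="raw"` exposes the tree-free variant.

For each genome and family the median patristic distance is taken to the
other alleles within its own species (self excluded) and within the
opposite species. The transfer call is median_same > 0.1 AND
median_opposite < 0.1, both strict, so an allele exactly at threshold is
not called; the strict reading follows the procedural description of the
rule over a figure caption's "≤". The call is monotone in the threshold
only above the opposite-species median — the call window is the open
interval between the two medians.

Co-transfer loci: each genome is partitioned into inter-node intervals
bounded by consecutive single-copy core genes (contig ends truncate).
"Adjacent" means within either flanking interval. An accessory family
qualifies for a locus when *every* pangenome-wide occurrence lies in an
interval bounded by a transfer-flagged core family; flagging is at the
family level (flagged in at least one genome), because the donor genome's
own copy necessarily sits next to its unflagged allele of the same node —
a strictly per-genome reading would exclude every true event. Flagged core
families adjacent in node order merge into one locus; a locus is reported
only with at least one qualifying accessory family. The recipient species
is the one whose member carries the discordant allele.

## Synthetic data

The plate generator produces logistic curves
A(t) = baseline + gain / (1 + e^{−rate (t − lag)}) plus Gaussian noise and
optional isolated +0.3–0.6 spikes (the bubble artifact model); negative
controls have zero gain. The phenotype panel draws species archetypes
(a substrate is utilized with probability 0.55, at a level uniform on
[0.2, 1.0]) and derives strains by Bernoulli trait dropout plus noise —
it emulates block structure and strain-level trait loss, not diauxie,
precipitation drift, or medium effects, so passing tests demonstrate
correct bookkeeping and recovery, not robustness to every real-plate
pathology.

The pangenome generator evolves each core family's DNA down a two-species
clock tree under Jukes–Cantor with leaf-to-leaf expectations d_w = 0.03
within and d_b = 0.25 between species (ancestor branches (d_b − d_w)/2,
leaf branches d_w/2), 900 nt per gene, and no indels in core genes —
alignment becomes trivial, isolating the distance logic under test.
Protein sequences evolve on the same tree with branch lengths scaled by
0.2, a purifying-selection proxy that keeps cross-species orthologs near
95% amino acid identity (above the 90% family cutoff) while their DNA
distances straddle the 0.1 threshold — the situation that makes the screen
meaningful for real *B. ovatus*/*B. xylanisolvens* genomes. Accessory
segments are species-specific, inserted per inter-node interval with
probability 0.3; about 20% are PUL cassettes (susC, susD, ≥ 1 CAZyme,
extras), exercising the PUL caller. Transfer events copy a donor genome's
run of `span = 2` consecutive node alleles and the intervening accessory
content verbatim into an opposite-species recipient (homologous
recombination replaces rather than mutates); sites are drawn uniformly
among runs whose interior interval carries donor accessory content, kept
non-adjacent so loci stay distinct. Defaults — 5 + 5 genomes, 200 core
families, 10 transfers — are the scale at which the whole screen runs in
seconds on one CPU while leaving each median over ≥ 4 alleles.

## Known limitations

Diauxic (two-phase) curves are called as a single window spanning both
phases. The PUL caller reports merged adjacent PULs as one locus. The
family builder is quadratic per genome pair and intended for desk-scale
pangenomes (tens of genomes, thousands of genes). The simulator omits
rearrangement beyond segment replacement, indels in core genes, and codon
structure; divergence calibration is therefore exact only in expectation.
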