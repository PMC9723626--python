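# Methods

This note documents the models, conventions and numerical choices behind
`rrnscape`, and what the synthetic panels do and do not establish about
real genomes.

## Coordinates and domain objects

All coordinates are 0-based half-open internally; GFF3 written to disk uses
the standard 1-based inclusive convention. A genome is a position-sorted
list of gene records (CDS, tRNA, 16S/23S/5S rRNA) on a single linear
chromosome with exactly one *dnaA* gene; the midpoint of *dnaA* serves as
the oriC proxy throughout (in these genomes the origin lies in the
*dnaA*–*dnaN* intergenic region, so *dnaA* both locates and orients it).
Circular chromosomes, plasmids and duplicate terminal inverted repeats are
out of scope; input is expected to carry a single TIR.

**rrn locus assembly.** Annotations give individual rRNA genes, not operons.
Same-strand rRNA genes whose spans lie ≤ 2 kb apart are merged by single
linkage into one locus; a locus with at least one each of 16S, 23S and 5S is
*complete*, anything else *unlinked* (including lone-5S loci). The 2 kb gap
is a proxy choice — internal transcribed spacers are a few hundred bp while
distinct operons are tens of kb apart, so the clustering is insensitive to
the exact value over roughly 1–10 kb. It is a keyword argument
(`max_gap`) wherever it matters.

## Orthology

Hits are BLAST tabular rows with a sequence-length sidecar for coverage
(coverage = alignment length / shorter sequence × 100; hits without lengths
are taken at face value). Thresholds (identity ≥ 40, coverage ≥ 70,
E ≤ 1e-10) are applied **before** best-hit selection, so a sub-threshold hit
can never shadow a passing one. Best = maximal bitscore, ties broken by
minimal E-value then maximal identity; a residual tie between distinct
subjects voids the best hit (and hence the BBH) — a conservative rule,
since the downstream core definition requires single-copy genes anyway.
Orthogroups are connected components of the panel-wide BBH graph; core
groups are single-copy in every genome with every cross-genome pair a BBH
(a clique). The persistence index of a group is the fraction of panel
genomes carrying at least one member.

## Consensus core order and nomenclature

Each genome ranks its core genes 1..N by start coordinate (starts are
distinct by construction in the generator and in any non-overlapping
annotation). The consensus assigns each group its modal rank over a chosen
genome subset (canonical-configuration genomes, in practice); groups
colliding on a modal rank are ordered by majority pairwise precedence
(Condorcet), falling back to mean rank then group id when no majority
winner exists — a deterministic replacement for manual inspection of
ambiguous regions.

An rrn locus's **environment** is the unordered triplet {previous, nearest,
next} of core genes, where nearest minimizes span-to-span distance
(overlap = 0; exact ties go to the lower consensus rank) and previous/next
are its chromosomal neighbors. Orientation is *sense* if the triplet's
consensus ranks strictly increase along the chromosome, *antisense*
(asterisk) if they strictly decrease, and *broken* otherwise (a breakpoint
inside the triplet). Broken environments are rendered with a `~` suffix —
our own extension, needed so that reverse-complementing a genome maps
tokens one-to-one (sense ↔ antisense, broken ↔ broken) and the
configuration equivalence stays exact.

Dictionary construction ranks environments by panel frequency (ties by the
consensus rank of the nearest core gene, then lexicographically); the top
six become `A`–`F` in consensus-rank order of their nearest cores. Other
environments are labeled in genome-id-sorted discovery order: sharing a
triplet gene with exactly one canonical environment gives that letter in
lower case numbered from 2 (the canonical environment itself being the
implicit first variant); sharing with two gives a hybrid label like
`[d/e]`; sharing with none gives fresh letters `g`, `h`, … numbered per
letter, with later novel environments that share a gene joining the same
letter.

A configuration lists labels in chromosomal order with the genome's own
*dnaA* strand as its sign. `canonicalize` computes the reverse-complement
form (labels reversed, asterisks toggled, sign flipped) and returns the
lexicographically smaller token sequence, so database orientation is
irrelevant: `rrn F*E*D*C*B*A* dnaA-` normalizes to `rrn ABCDEF dnaA+`.

## Compartments

The central compartment is the span-inclusive interval from the start of
the leftmost rrn locus to the end of the rightmost. By default every locus
counts as a potential delimiter (unlinked and lone-5S included);
`complete_only=True` restricts to complete operons, and both modes are worth
reporting when a distal locus is unlinked. Core-region and tDNA-region
intervals come from the outermost core genes and tRNAs. CCC/TCC classes use
a 0.95 membership threshold ("almost always" made operational);
it is a keyword argument.

## Rearrangement detection

Positions are gene starts (consistent with rank construction). The query
genome is auto-flipped when its Spearman synteny orientation against the
reference is negative. Δ = position in genome − position in reference over
core genes inside both central compartments, iterated in reference order;
ΔΔ is its successive difference. |ΔΔ| > 200 kb marks a breakpoint between
two reference-consecutive core genes. Consecutive breakpoints are paired
greedily into events: a segment whose genome positions strictly decrease is
an inversion, anything else a displacement; an odd trailing breakpoint
yields an open-ended event. This deterministic segmentation replaces manual
curation; an exported event table supports human review. Resolution is
bounded by local core-gene spacing — a breakpoint can only be localized
between two consecutive core genes, so recovered ends sit within one
spacing of the truth. Events with identical boundary groups and type merge
across genomes forming a connected clade (all carriers, without a tree),
averaging sizes and rrn distances.

## ANIb

Query genomes are cut into consecutive 1000-nt fragments, keeping the
trailing remainder (droppable via `drop_below`). Boundary semantics follow
the stated rule literally: alignment **strictly greater** than 70% of the
fragment length, identity **at least** 30%. The built-in aligner indexes
reference k-mers (k = 14), votes exact matches onto diagonal offsets, takes
the winning offset and scores column identity over the overlap — adequate
for the generator's substitution-only sequences, where the best local
alignment is an ungapped diagonal; highly diverged fragments find no seeds
and correctly report no hit. For real data a blastn adapter implements the
same per-fragment contract. Aligned fraction is measured against fragment
length (not alignment columns). One-way scores average identity over
positive fragments; the final score averages the two directions and is
exactly symmetric.

## Expression statistics

Size factors are DESeq2-style median-of-ratios: the reference is the
gene-wise geometric mean across samples (genes with any zero excluded) and
each sample's factor is the median count/reference ratio. A global scaling
of the count matrix therefore cancels (the reference absorbs it), while a
per-sample depth change moves that sample's factor proportionally.
Normalized expression is log₂(count / factor / gene-length-in-kb +
pseudocount) with pseudocount 1 (configurable). Correlations are Spearman,
stratified by compartment × core status (CCC/CCNC/TCC/TCNC) and pooled,
against persistence and against |distance to oriC| (absolute distance pools
both arms; a per-arm analysis is possible by filtering on position).
Differential-expression testing is out of scope — downstream use here is
correlation, not DE calls.

## Stepwise model of core-region size

Ordinary least squares with AIC = n·ln(RSS/n) + 2(p+1) up to an additive
constant (irrelevant to comparisons); categorical predictors enter and
leave as dummy blocks. Forward and backward passes both run; both are
reported and the lower-AIC result is the selection. Exactly collinear
candidates are dropped with a warning before selection — note that
compartment geometry makes one such identity unavoidable (central +
terminal-left + terminal-right = chromosome). A known property of
AIC selection worth keeping in mind when reading recovery studies: a pure
noise predictor is admitted whenever its χ²(1) improvement exceeds 2, which
happens with asymptotic probability ≈ 0.157, so per-decoy false-inclusion
rates in the 15–25% range are the statistic's own behavior, not an
implementation artifact; a BIC-like penalty (ln n) would push them below
5%, but AIC is the criterion used here.

## The synthetic generator

The generator's defaults encode the study conditions the analysis assumes:
a 8 Mb chromosome, 1017 core genes, six complete rrn operons placed at
signed fractions (−1, −0.7, −0.45, −0.2, +0.5, +1) of the central-
compartment half-spans around an origin at 0.55 L — four loci on one side,
two on the other (the ~2:1 asymmetry) — all co-oriented with continuous
replication away from oriC; 88.5% of core genes inside the central
compartment (the distal operons pin its edges at 20% and 80% of the
chromosome); non-core genes denser in the arms; a tDNA region slightly
wider than the core region. Evolution applies, per branch and Poisson in
the branch length: pericentric inversions (ends drawn from a 70:30 mixture
of an exponential kernel of decay 100 kb around a random rrn locus and a
uniform background, constrained to straddle oriC and to the configured size
range), rrn duplications (70% adjacent, otherwise ectopic in the central
compartment), losses of non-distal loci, relocation of a 5S away from its
operon, and arm-biased (3:1) gain/loss of non-core genes. Breakpoints and
insertion points snap to intergenic gaps, so genes are never split. Every
applied event is logged with concrete coordinates; replaying the log on the
ancestor reproduces each leaf exactly, which is what the recovery tests
score against.

Similarity tables give true ortholog pairs reciprocal hits passing the
40/70/1e-10 thresholds; decoys are either sub-threshold or one-directional,
so zero-noise panels are exactly recoverable and noisy ones cannot create
false BBHs (false *negatives* via tie-voiding remain possible in principle).
Sequences evolve by i.i.d. substitutions on a uniform-GC background — no
indels, codon structure, GC skew or horizontal transfer — so ANIb
calibration checks the estimator, not sequence-evolution realism.
Expression counts are negative binomial (dispersion α; α = 0 gives Poisson)
around a mean = baseline × length(kb) × central multiplier ×
exp(−λ·|distance to oriC|) applied to arm genes only × optional persistence
coupling × a per-sample depth factor.

**What passing tests show — and don't.** Recovery on these panels
demonstrates that each algorithm measures what it claims under its own
generative assumptions (clean orthology, substitution-only divergence,
planted rearrangements with known ends). It does not validate annotation
quality, alignment-tool behavior on real sequence, or the biological claims
about real panels, whose headline numbers depend on the particular genomes
analyzed.

## Problem sizes

Test and acceptance runs use the full-size ancestor (1017 core genes, 8 Mb)
for nomenclature, compartments, rearrangements and expression; a scaled
ancestor (80 core genes, 0.6 Mb) for orthology round-trips where panels of
similarity tables are quadratic in panel size; 2 Mb sequence pairs for ANIb
calibration; and 100 feature panels of 60 genomes for the model-selection
study. These sizes are the package's own defaults for a desk-scale
demonstration and are all configurable.
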