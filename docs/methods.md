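# Methods

This note documents the models, parameter choices and numerical policies
behind `grasfam`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinates and the curated table

All genomic coordinates are 1-based, fully closed intervals — the convention
shared by curated locus tables and GFF3 — and no half-open conversion happens
anywhere. A `Locus` stores exon segments in ascending genomic order
regardless of strand. The bundled grapevine GRAS table carries 52 gene
models; its accessions encode the chromosome (`Vitvi08g00007` → chr 8) and
the parser enforces that consistency. Span cells accept en-dash or hyphen;
the table's original typographic curation marks are not machine-recoverable
and are dropped (an optional free-text `notes` column is preserved instead).

Two published length claims about this family (a 2349-nt longest-gene figure
and a "41 genes > 1400 bp" count) are not derivable from the table's
coordinates, which give 1419 nt spliced / 1804 nt span for the gene in
question; they were evidently computed on a different sequence set. The
package reports both spliced length (Σ exon lengths) and genomic span
(end − start + 1) per locus and makes no claim about those two numbers.
Likewise the table lists three segments for one gene (GRASV2b) where the
family literature describes two exons; the table is kept verbatim.

## Local alignment and expectation values

`align_local` is exact Smith–Waterman (Biopython's `PairwiseAligner` in
local mode) under BLOSUM62 with affine gaps costing `open + k·extend`
(defaults 11/1). Exact alignment stands in for heuristic database search
deliberately: it can only find equal-or-better local alignments, so
downstream identity/E-value gates err on the permissive side, never by
missing a hit. Identity is matches over aligned columns, with gap columns
in the denominator; the alternative denominator (shorter sequence length)
is a documented switch away in the code but not a config option, because
within-family comparisons align nearly end to end and the choice barely
moves the gate.

Expectation values use the Karlin–Altschul form E = κ·m·n·e^(−λS) with the
standard gapped-BLOSUM62 constants λ = 0.267, κ = 0.041. These are scoring
constants, not fitted parameters; both are configurable.

The progressive multiple aligner builds a UPGMA guide tree on
(1 − pairwise local identity) and merges groups by semi-global profile DP
(end gaps free, expected column scores from residue frequencies). It has no
iterative refinement; it is used for within-family and within-subfamily
alignments at low divergence, where progressive alignment is adequate, and
the degapping invariant (every row reproduces its input) is enforced.

## Orthology

Both retention gates are strict inequalities (E strictly below 10⁻²⁰,
identity strictly above 0.40), reading the thresholds as exclusive bounds.
Best match is by raw score with E-value and then lexicographic target id as
tie-breaks, making calls deterministic; reciprocity is evaluated on the
mirrored hit set, which is exact because Smith–Waterman score, identity and
the E-value are all symmetric in the two sequences. Classification is
strictly cross-genome; self-comparisons within a genome are never made.

## Phylogeny

Column masking removes alignment columns whose non-gap fraction is strictly
below 0.95 ("less than" reads as strict, so a 20-row column with exactly one
gap survives). Ambiguity characters count as residues, not as missing data.

Distances are p-distances over mutually ungapped columns, optionally
corrected by d = −ln(1 − p − 0.2p²) — Kimura's empirical protein correction,
the standard closed-form approximation to the JTT expected-substitution
curve. The correction saturates at p ≈ 0.85; such pairs are clamped to
d = 10 substitutions/site rather than raising, so a single saturated pair
cannot abort a bootstrap replicate.

Trees come from Saitou–Nei neighbor joining rather than a likelihood
search: NJ on corrected distances is deterministic, runs in milliseconds at
family scale, and recovers clade membership — the only thing subfamily
assignment consumes — exactly at the divergences involved (the test suite
verifies exact recovery from additive matrices over hundreds of random
trees). Negative NJ branch lengths are clamped to zero with the deficit
moved to the sibling edge, preserving the joined pair's path length. Q-matrix
ties break on the lexicographically smallest label pair, so topologies do
not depend on input row order.

Bootstrap consensus resamples columns with replacement (seeded NumPy
generator), builds one NJ tree per replicate, and keeps splits supported by
at least the retention floor (default 30 %, inclusive — the collapse rule
applies to "less than" the floor), added greedily in descending support
under pairwise compatibility. Degenerate replicates (a pair with no
comparable columns) are skipped with a warning and the support denominator
shrinks accordingly. Supports are percentages of usable replicates.

Subfamily assignment treats the consensus as an unrooted tree: candidate
groups are the sides of retained splits, so a subfamily containing the
rooting leaf is handled identically to any other. For each unlabeled leaf,
the smallest side containing it that holds any anchor decides — one anchor
label assigns, mixed labels leave the leaf unassigned, and a fully
collapsed star assigns nothing.

## Motifs

Catalog patterns are consensus strings: literal residues, `X`/`+`
single-position wildcards (`+` appears in the published accessory-motif
consensi and is read as a wildcard, since no narrower definition is given),
and per-position alternative sets like `[LIVF]`. A window's score is the
matched fraction of non-wildcard positions; scanning keeps all windows at or
above the floor (default 0.7), greedily best-first and non-overlapping per
pattern. The shipped catalog encodes the five-unit GRAS domain architecture;
the units whose consensus strings are not printed in the family literature
are synthetic placeholders, labeled as such in the catalog file and
trivially editable.

Conserved-window discovery evaluates identity per column (modal residue over
all rows, gaps counting against) and reports maximal runs of at least 10
columns at ≥ 50 % — both bounds inclusive, per "at least". Per-column
evaluation is the stricter of the two readings of the rule (the alternative,
window-average identity, would admit windows with weak interior columns);
it also makes windows well-defined and order-independent.

## Duplications

"Tandem" is not quantitatively defined in the family literature; the chain
rule with a 250 kb default gap reproduces the observed LISCL clusters
(members within ~25 kb) while excluding same-chromosome loci megabases
apart, and the gap is a parameter. Arrays are maximal and disjoint by
construction. Segmental calls require both loci of a same-subfamily pair to
fall fully inside the two intervals of one map pair and to lie on different
chromosomes; containment is strict, with an optional symmetric tolerance for
the near-segment cases the literature mentions. The paralogous-segment map
is an input, not an inference — the package does no synteny detection.

## Expression

Replicates are averaged arithmetically in log2 space. The PO gate is
inclusive (≥ 8.0 in log2, so a raw intensity of exactly 256 = 2⁸ is
attributed); a strict-gate switch exists. Attribution is per tissue: any
condition of a tissue at/above the gate attributes that tissue's PO term.

Co-expression distance is 1 − Pearson correlation over condition averages.
Distances are rounded to 12 decimals before comparison so that a pair at
nominal distance 0.2 compares equal to the 0.2 cutoff (1 − 0.8 lands one
ulp short of 0.2 in binary floating point) and the strict "lower than" test
excludes it. Clustering cuts an average-linkage tree at the cutoff and then
enforces the complete-pair reading of "distance between each other lower
than 0.2": any cluster containing a pair at or above the cutoff is re-split
by complete linkage just below it (complete-linkage merge heights bound the
within-cluster maximum, so the re-cut provably satisfies the bound). The
final pairwise bound is asserted. Constant-profile genes (undefined
correlation) are excluded with a warning; singletons are unclustered.
Cross-platform probeset merging is out of scope: the pipeline operates on
one matrix whose rows are already gene-resolved.

## Synthetic data

The generator is the package's ground-truth instrument. Defaults mirror the
grapevine family shape: 13 subfamilies × 4 members (52 genes), protein
lengths 400–700 aa, within-subfamily divergence 0.20 and between-subfamily
0.60 expected substitutions/site, orthologs at 0.10, two subfamilies lost
from the second genome, two lineage-specific duplicates at 0.02 from their
source, 2 tandem arrays (10 kb spacing), 3 segmental pairs with a matching
segment map, and an expression design of 50 conditions × 3–4 replicates
with a 10-gene module at target pairwise correlation 0.9 and five
tissue-boosted genes.

Sequence evolution is residue-frequency-weighted random replacement along
star-like trees (family root → subfamily ancestors → members, each branch
substituting sites at half the target pairwise divergence). This is
deliberately simpler than an empirical-matrix simulation: every downstream
stage consumes identities, distances or exact matches, none of which
distinguish the substitution process at these divergences. Motif instances
are written over the sequence after mutation, one concrete instantiation
per (motif, subfamily), so planted motifs are exactly conserved within a
subfamily and recoverable at exact boundaries. Star-like subfamily trees
keep clade recovery unambiguous; they do not exercise deep nested topology,
so passing tests certify subfamily-level classification, not fine intra-
subfamily resolution.

What the generator does **not** emulate: indels (alignments of simulated
families are effectively gap-free before the N-terminal length trim),
compositional bias, rate heterogeneity across sites, correlated losses, and
cross-platform probe effects in expression. Recovery rates on synthetic
data are therefore upper bounds on real-data performance, and the
quantities that depend on real external datasets (the full
grapevine+Arabidopsis tree, the Arabidopsis orthology split, observed
co-expression partner lists, atlas intensity patterns) are documented as
out of desk-reproducible scope rather than asserted.

## Problem sizes and determinism

Default analysis sizes — one 52-protein family, a 46-protein partner
genome, 100 bootstrap replicates, 50 expression conditions — complete in
about a minute on one CPU; the test suite uses a 5-subfamily × 3-member
family for most integration checks. Every stochastic step (simulation,
bootstrap resampling) takes a single integer seed; the pipeline stamps its
report with package version, seed and a hash of the effective
configuration, and identical config + seed reproduce byte-identical
outputs.
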