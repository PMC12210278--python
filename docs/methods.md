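# Methods

This note documents the models, statistics and numerical conventions behind
`taxodelim`, and what the synthetic-data tests do and do not demonstrate
about real genome collections.

## Problem setting

Bacterial orders are increasingly revised from whole-genome evidence rather
than 16S rRNA phylogenies, whose nodes are often too weakly supported to fix
family- and genus-level boundaries. The workflow this package implements
mirrors such revisions: build several phylogenomic trees (different marker
sets, different inference methods), confirm they agree topologically, then
partition the tree into ranks using overall genome relatedness indices —
average amino-acid identity (AAI) between proteomes and evolutionary
distances (ED) between tips — constrained by monophyly and branch support.
Species-level questions (possible heterotypic synonyms) are screened with
average nucleotide identity (ANI) and digital DNA–DNA hybridization (dDDH).

## AAI from reciprocal best hits

For proteomes *A* and *B*, every protein pair is aligned (Smith–Waterman,
BLOSUM62, affine gaps: a gap of length *k* costs 11 + *k*); a pair (a, b)
is a reciprocal best hit (RBH) when each is the other's best-scoring match.
AAI(A, B) is the unweighted arithmetic mean of RBH percent identities,
computed over core alignment columns (terminal-gap overhangs excluded).
Pairs below 30% identity or covering less than 70% of the shorter protein
are discarded *after* RBH selection; both filters are conventional
orthology heuristics, configurable, not measurements. Score ties in best-hit
selection are broken by higher identity, then lexicographic partner id; the
traceback prefers diagonal over up over left. These conventions make AAI
deterministic and exactly symmetric. Self-comparisons are defined as 1.0.

The aligner is an in-package Gotoh dynamic program (numba-compiled). Tests
verify it against a brute-force alignment-path enumeration, an independent
memoized three-state DP, and Biopython's `PairwiseAligner`.

## Consensus degree and tree statistics

The consensus degree (CD) between two trees on one leaf set is the
percentage of identical internal nodes: shared non-trivial bipartitions
divided by L−3, the bipartition count of a fully resolved unrooted tree.
The L−3 denominator is a deliberate convention (applied to unresolved
inputs too): it makes CD = 100 equivalent to complete topological
agreement and yields the closed relation `cd = 100·(1 − rf/(2(L−3)))`
against the Robinson–Foulds distance on fully resolved pairs, which the
tests exploit as an oracle identity (RF cross-checked against dendropy on
all 945 unrooted 7-leaf topologies).

ED is either read from an IQ-TREE `mldist` file (PHYLIP square dialect) or
computed as patristic path lengths on a tree; both sources are labeled in
outputs. Majority-rule consensus trees retain exactly the bipartitions in
more than the threshold fraction of inputs (no greedy completion), each
annotated with its recovery count. Monophyly is assessed on the rooted tree
as supplied; rooting by a named outgroup or by midpoint is available.
Support values are plain internal-node labels; values on [0, 1] are read as
posterior probabilities and rescaled to [0, 100]. Whether mixed
bootstrap/posterior inputs should be rescaled before CD comparison is a
genuinely open convention; this package always rescales and says so here.

## Rank delineation

`delineate_rank` walks the rooted tree in preorder and emits a clade as a
group as soon as (i) every intra-clade pair satisfies every threshold rule
— minimum pairwise AAI at or above the cutoff, maximum pairwise ED at or
below it, applied jointly — and (ii) the clade root's support is at least
`support_min` (default 70, the usual robustness cutoff; the tree root is
exempt). Leaves reached without emission become singletons. This greedy
maximal-clade rule yields the coarsest partition consistent with the
thresholds and monophyly; where thresholds and topology conflict the walk
descends, so missing (NaN) matrix entries fail safe toward finer
partitions. Family defaults are AAI 0.6 / ED 0.5; genus defaults 0.7 / 0.4.
Genus delineation runs independently inside each family subtree and genus
rules must be at least as tight as family rules, so the genus partition
refines the family partition by construction. Thresholds are treated as
non-strict for intra-group values (intra AAI ≥ cutoff, intra ED ≤ cutoff);
whether the boundary values themselves belong to the intra or inter side is
not observable from practice, so the convention is fixed here.

Separation statistics: intra- and inter-group samples are all unordered
same-group and cross-group pairs (singletons contribute no intra pairs);
group summaries report n/mean/median/min/max; the Welch unequal-variance
t-test (Satterthwaite degrees of freedom, two-sided) quantifies separation,
with p-values below 2.2e-16 reported as "< 2.2e-16" in the conventional
way. `derive_threshold` picks, among midpoints of adjacent pooled order
statistics, the cutoff minimizing total misclassification (ties: maximal
margin, then the smaller cutoff); for separable samples this is the gap
midpoint.

## Synonymy screen

Pairs with ANI strictly above 96 (the upper end of the 95–96 species band)
and dDDH strictly above 70 are flagged as putative heterotypic synonyms.
The screen only flags: deciding nomenclatural priority, or overriding a
genomic flag with phenotype evidence, is not algorithmic.

## The synthetic-data generator

`simulate_tree` plants a three-tier rooted tree: species tips inside
genera, genera inside families, families off the root. It is ultrametric
within families; per-family stem offsets vary tip depths so between-family
distances spread across their band. Distance tiers are drawn uniformly from
corridors inside the published band envelopes (intra-family 0.16–0.57,
inter-family 0.50–1.22):

* within-genus distances from (0.17, 0.30),
* cross-genus (same family) from (0.42, 0.44),
* between-family from (0.57, 1.20).

The envelopes themselves overlap (0.50–0.57), because the published bands
are ranges of per-family averages; raw pairwise draws across the full
envelopes would straddle the family ED boundary of 0.5 and no threshold
rule could recover the planted ranks. The corridors instead keep the three
tiers separated by the genus (ED 0.4) and family (ED 0.5) boundaries with
margins, while every realized distance still falls inside its envelope. A
few draws are anchored at corridor edges — the two first families at the
between-family floor, the first family (always given the maximum genus
count, its first genus the maximum species count) at the cross-genus
ceiling — so every tier and the band edges are exercised in each replicate.
Infeasible band/corridor combinations raise instead of clipping.

`evolve_proteomes` evolves a root proteome (default 10 proteins of 280–320
residues) down the tree with substitutions only — no indels and no gene
gain or loss, a deliberate trade of realism for closed-form expectations
while the RBH machinery (mutual-best selection, identity and coverage
filters) is still fully exercised. On a branch of length *d* each site
mutates with probability p(d) = (19/20)(1 − e^(−k·d)) to a uniformly chosen
different residue — exactly the 20-state Jukes–Cantor transition — so two
tips at patristic distance D have expected identity
I(D) = 1/20 + (19/20)·e^(−k·D). The rate k is calibrated once from this
closed form so that I maps the distance-corridor gap midpoint (ED 0.505)
onto the AAI band-gap midpoint minus a 0.005 terminal-trim allowance
(local alignments clip low-scoring ends, measuring ≈ I·t/L above per-site
identity for t ≈ 1–2 trimmed columns at length ≈ 300); k ≈ 1.064 at the
defaults. Under this calibration intra-family AAI lands in ≈ 0.62–0.85 and
inter-family AAI in ≈ 0.32–0.60, overlapping the published bands, with the
realized gap centred near the family AAI boundary of 0.6.

All randomness flows from the single `seed` (tree and proteome streams are
spawned from it), so equal seeds give byte-identical outputs.

### What the synthetic tests show — and what they do not

Passing recovery tests show that the delineation machinery is correct and
deterministic: when relatedness bands are separated the way the study
reports them *between* ranks, greedy monophyly-constrained thresholding
returns exactly the planted families and genera (ARI = 1), the data-derived
AAI cutoff brackets 0.6, and intra/inter separation is significant beyond
the 2.2e-16 reporting floor. They do not show that real proteomes behave
this way: real data have indels, gene gain/loss, unequal proteome sizes,
rate heterogeneity, horizontally transferred genes and incompletely
separated bands, and real trees have weakly supported nodes that force
singleton spill-over. The generator is a test substrate, not a genome
model.

## Problem sizes and study conditions

The recovery study runs 20 replicates at the default conditions: 13
families, 1–2 genera per family, 1–2 species per genus, 10 proteins of
280–320 residues per taxon (a deliberately reduced proteome — thousands of
proteins would measure the same means with smaller variance), supports
constant at 100. The acceptance script runs 12 replicates of the same
study plus a consensus-degree study (a 30-leaf resolved tree and three
replicates one nearest-neighbor interchange away; any two such trees differ
by at most two NNIs, so CD ≥ 100·(1 − 4/(2·27)) ≈ 92.6, matching the
"concordant trees" regime) and a synonymy screen over 40 synthetic genomes
with three planted same-species pairs.

The published revision itself rests on 429 type-strain genome assemblies,
their four phylogenomic trees and web-server AAI/ANI/dDDH values. Those
inputs are external data; reproducing the headline numbers (all pairwise
CD above 90%, 75.0% of 16S nodes under 70% support, thirteen families,
the 0.62–0.84 vs 0.51–0.60 AAI bands) requires downloading the genome set
and is documented here as a cluster-scale exercise: point the pipeline's
TOML config at the proteome directory, the four newick trees, the bac120
`mldist` file and the taxonomy mapping, with the default thresholds and the
outgroup *Rhodospirillum rubrum* ATCC 11170. Nothing in the desk-scale
tests stands in for that run.

## Numerical conventions and degenerate inputs

* Matrices must be symmetric within 1e-9 (readers tolerate 1e-6 and
  average); similarity diagonals are fixed at the scale maximum, distance
  diagonals at zero. NaN marks a recorded-missing pair and fails every
  threshold.
* Alignment scores with integer scoring tables are exact in floating
  point, so traceback equality tests are exact, not tolerance-based.
* Welch's test with two zero-variance samples returns t = 0, p = 1 when the
  means agree and the reporting floor when they differ.
* Empty local alignments (no positive-scoring segment) are returned with
  zero columns; percent identity on them is an error, and RBH treats such
  hits as "no conserved comparison".
* Trees are normalized on reading: unary nodes suppressed (lengths summed),
  supports on [0, 1] rescaled to [0, 100], negative branch lengths
  rejected.
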