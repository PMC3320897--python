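# Methods

This note documents the models, conventions, and numerical choices behind
`radphylo`, and what the synthetic experiments do and do not demonstrate.

## Coordinates, symbols, formats

All coordinates are 0-based, half-open, on the forward strand of the stored
sequence.  `?` means a locus is absent in a taxon; `-` is an alignment gap
within a locus; both (plus `N`) are treated as missing by site counting and
distances, but the two are distinguished in files and in the reported
statistics (`missing_fraction` counts all three, `absent_fraction` counts
`?` alone) because they have different biological readings.  Supermatrices
are written as relaxed PHYLIP or FASTA plus a RAxML-style partition file
(`DNA, locus = start-end`, 1-based inclusive), so external maximum-likelihood
tools can be pointed at the same files; trees are Newick with bootstrap
percentages as internal node labels.

## In-silico digest

Sites are exact string matches of the recognition motif (overlapping
occurrences included; `N` never matches).  For a site at position `p` with
motif length `m`, the reads are `seq[p-L, p)` and `seq[p+m, p+m+L)`; a flank
that would cross a contig boundary is dropped, so an interior site yields
exactly two reads.  Reads containing `N` are kept by default (they behave as
mismatches downstream); `drop_ambiguous` removes them.  Both flanks are
reported in forward-strand orientation — the enzymes used are palindromic
and simulated assemblies are consistently oriented, so no reverse-complement
handling is applied (a flag on clustering would be the extension point).

When harvesting from a reference whole-genome alignment, sites are found on
each taxon's ungapped row and each read is labelled with the alignment
column of the motif start, giving cross-taxon truth labels for orthology
scoring.

### Known-orthology benchmark matrices

Benchmark loci group reads by exact (site column, side).  The subalignment
of a locus is the span of reference columns that accumulates `L` ungapped
characters of the locus's *first present taxon* in alignment order, walking
outward from the site.  Anchoring the column span on one taxon is a design
choice: gap patterns can differ between rows, some taxon's span must define
the window, and the first-present rule is deterministic and order-stable.
Absent taxa are `?`-filled, loci with fewer than `min_taxa` present taxa are
dropped, and survivors are concatenated in site-column order (upstream flank
before downstream).

## Pairwise identity and greedy clustering

Identity is defined constructively so it can be oracle-checked: globally
align the two reads with match +1, mismatch −1, gap −2 (no free end gaps);
on score ties prefer a match/mismatch column, then a gap in the first
sequence, then a gap in the second; identity = identical-residue columns /
total alignment columns, with `N` matching nothing.  The tie preference
makes rare score-tied pairs order-sensitive; clustering always passes the
incoming read first and the seed second ("identity of each sequence to the
seed").  Seed-based clusterers used in practice leave their internal
identity definition unspecified; this one is concrete and reproducible,
which matters more here than bit-compatibility with any particular tool.

Clustering is greedy and first-match: reads in input order, seeds in
creation order, a read joins the first seed with identity ≥ T, otherwise
becomes a seed.  This deliberately mirrors the heuristic order-dependence
of seed-based clustering; the pipeline quantifies it with seeded input-order
permutations (replicates) and the proportional difference 1 − n/m of
cluster counts.

Two *exact* accelerations make the quadratic comparison load tractable
(both are verified against a naive full-DP reference in the test suite):

* **Ungapped accept.** For equal-length reads with `M0` positional matches,
  the ungapped alignment scores `2*M0 − L`.  A gapped alignment with `g`
  gap columns has `L − g/2` residue columns, so its score is
  `2*Mg − L − 3g/2`; beating the ungapped score forces
  `Mg ≥ M0 + 3g/4`, and then its identity `Mg/(L + g/2)` is at least
  `M0/L` (cross-multiplying needs `M0 ≤ 3L/2`, always true).  Hence the
  DP identity is never below the Hamming identity, and `M0/L ≥ T` accepts
  without running the DP.
* **Provable bands.** Any path drifting `d` cells off the main diagonal
  carries ≥ 2d gap columns and scores ≤ `L − 5d`.  (i) Paths scoring below
  the ungapped score are never optimal, giving the exact band
  `d ≤ 2(L − M0)/5 + 1`.  (ii) An alignment with identity ≥ T must score
  at least `L(6T−4)/(1+T)` (maximise `Mg/(L+g/2)` subject to the score),
  so paths outside `d_T = (L − L(6T−4)/(1+T))/5` either are not optimal or
  decide "reject" anyway; the band is clipped to `min` of the two.  The DP
  fills a score-only matrix in diagonal-offset storage and recovers the
  tie-broken path's match/column counts by an O(L) traceback.

Identical reads are deduplicated before clustering: a duplicate scans the
same seeds in the same order as its first occurrence and ties at identity
1.0 on that occurrence's seed, so it provably makes the same decision.

## Assembly

The per-cluster aligner is a seed-anchored star alignment: each member is
pairwise-aligned to the seed with the same DP, and the pairwise alignments
are merged on the seed coordinate frame (insertion slots take the maximum
length over members).  For substitution-only data this reduces to the
identity alignment.  It replaces a general-purpose progressive aligner by
design: reads are short, equal-length, and seed-centred, so star alignment
is adequate and keeps the package self-contained; disagreements with a
reference alignment are themselves a measured quantity (alignment-agreement
fraction over fully orthologous clusters, compared string-wise after
removing all-gap columns on both sides).

Concatenation orders loci by descending taxon count, then locus id — an
arbitrary but fixed order that makes replicate artifacts diffable.  A
matrix where some taxon is `?` everywhere is flagged incomplete and no tree
is inferred from it.

Parsimony-informative sites are columns with ≥ 2 states (A/C/G/T) each held
by ≥ 2 taxa; variable sites have ≥ 2 states.  The invariant-cluster
fraction counts clusters whose member reads are byte-identical.

## Inference

Distances use pairwise deletion: a column contributes to a pair iff both
taxa hold A/C/G/T there.  A pair with no comparable column is an error
(zero overlap), surfaced rather than imputed.  The Jukes–Cantor correction
−(3/4)ln(1 − 4p/3) is capped at 5.0 substitutions/site for p ≥ 0.749 to
keep neighbor joining finite on saturated pairs; capped pairs are logged.
Neighbor joining is the canonical Saitou–Nei algorithm; Q-matrix ties break
to the lowest taxon-index pair (the search scans the upper triangle
row-major, so `argmin` does this for free) and negative branch lengths are
clamped to zero.  Distance+NJ stands in for external maximum-likelihood
inference as the built-in engine; the matrix and partition files written by
the assembler are exactly what an external RAxML-style run would take, so
swapping in such a tool is a file-level integration, not an API change.

The bootstrap resamples matrix columns with replacement (width preserved),
implemented as a multinomial draw over the matrix's unique column patterns
— distributionally identical to per-column resampling but far cheaper.
Support of an internal edge of the point-estimate tree is the percentage of
replicate trees containing the same bipartition; replicates that hit a
zero-overlap pair are skipped and counted.  A matrix with no variable sites
yields all-zero supports with a warning.

## Evaluation

A node is correct iff its bipartition occurs in the reference tree; for
binary trees this equals (n−3) − RF/2.  "Supported" means bootstrap
strictly greater than 70%.  Topologies are classified as
reference/alternative/other by exact unrooted bipartition-set equality
against the reference first, then listed alternatives — the mechanism for
recognising topologies supported by known gene-tree incongruence.
Mann–Whitney U uses midranks; when `n_x·n_y ≤ 400` the p-value is exact,
computed by a subset-sum dynamic program over the doubled midranks (this
enumerates the full permutation distribution, ties included, without
generating the subsets); otherwise a tie-corrected normal approximation
with continuity correction is used.  Two-sided p is `2·min(lower, upper)`
tails, capped at 1.  Pooled support comparisons aggregate nodes across
trees that are not independent; reports flag them as descriptive, which is
also why the exact/deterministic machinery matters more than asymptotics
here.

## Synthetic data

The generator plants `S` motif copies at evenly spaced positions in a
random root genome of length `G` and evolves it along a given tree under
Jukes–Cantor: a branch of length `t` (expected substitutions/site) mutates
each site with probability `p_sub = 3/4·(1 − e^(−4t/3))`, drawing uniformly
among the other three bases.  Indels are modelled as deletions only
(Poisson events at `indel_rate` per site per unit branch length, geometric
lengths with mean 2).  Deletion-only evolution keeps every lineage in the
root coordinate frame, so the true multiple alignment is exact by
construction; insertions would add column-merge bookkeeping without adding
coverage of anything the pipeline measures, and real RAD flanks are short
enough that this simplification is acceptable for testing.  With motif
protection on, planted motif columns are immune to substitution and
deletion, so every taxon retains every locus — the regime for isolating
clustering/inference behaviour.  With protection off, sites are lost along
branches (losses only, matching the expectation that site loss dominates
gain), so isolated long-branch taxa retain fewer loci.  The truth table
records every motif occurrence in the final genomes — planted or arisen by
substitution — with per-taxon flank sequences, which keeps it in exact
correspondence with what a digest of those genomes finds.

Named fixtures: `tiny` (4 taxa, 5 kb, 10 sites, L=50) for fast unit tests;
`dros12` (12 taxa, 200 kb, 300 sites, L=100) with two short-branch species
pairs and several long isolated branches, maximum root-to-tip depth 0.15
substitutions/site — a moderate-divergence clade of the shape where RAD
phylogenetics is expected to work; `saturated` (8 taxa, two clades, far
clade on long individual branches) engineered so the assembled matrix
contains taxon pairs with no shared loci, exercising the zero-overlap error
path.

Problem sizes in the heavy tests (200 kb genomes, 300 sites, identity grid
{0.55, 0.70, 0.85}, 5 replicates, 100 bootstrap replicates) were chosen as
the smallest configuration that leaves the qualitative effects — orthology
fraction rising with identity, matrix width falling with identity and
min-taxa, long-branch underrepresentation, support separating correct from
incorrect nodes — comfortably outside noise.

## What the synthetic experiments show, and what they do not

Passing tests demonstrate internal correctness (oracle equivalence, NJ
consistency on additive inputs, byte-exact benchmark assembly) and that the
workflow recovers a known 12-taxon topology under Jukes–Cantor evolution at
moderate divergence.  Real data differ in ways the generator does not
emulate: sequencing error and within-species polymorphism (reads are
assumed to be error-free consensus sequences), base-composition and rate
heterogeneity (no Γ, no GTR), insertions, repetitive DNA beyond what the
paralog filter sees, and incomplete lineage sorting (gene-tree incongruence
is evaluated via alternative topologies, not simulated).  Accuracy numbers
from the fixtures are therefore upper bounds on, not estimates of,
real-data performance.

## Known limitations

* Identity is defined on one fixed scoring scheme; no k-mer prescreen
  heuristics means clustering is exact but quadratic in cluster count.
* The star aligner does not iteratively refine; pathological indel
  placements relative to a reference aligner are expected and measured,
  not corrected.
* Distance+NJ underuses signal compared to likelihood methods on saturated
  or rate-heterogeneous data; the cap at 5 substitutions/site is a blunt
  instrument for saturated pairs.
* Min-taxa counts distinct taxa only; it does not weight by informativeness.
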