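# Methods

This note records the models, rules and numerical choices behind
`phagekit`, and what the synthetic fixtures do and do not establish.

## Coordinate and interval conventions

All coordinates are 0-based half-open internally.  GFF3 and BLAST
outfmt-6 are 1-based inclusive and are converted exactly once, at the
I/O boundary (`phagekit.io`); a reverse-ordered subject range in a
tabular hit is swapped and tagged `strand='-'`.  Whether upstream
aligners strand-normalized coordinates before coverage merging is not
observable from hit tables alone; `phagekit` always normalizes.

Adjacent half-open intervals are merged: coverage is a position count,
and `[0,100) + [100,200)` covers exactly the positions of `[0,200)`.
Interval merging is idempotent and order-invariant, and
`covered_fraction` clips to the sequence bounds; both are tested
exhaustively against a brute-force position-set oracle.

## Screening thresholds

Every published rule is applied with the strictness of its wording:
"at least 10 kb" is inclusive (`>= 10000`), VirFinder's "score > 0.9,
p < 0.01" strict, the human-coverage rule "> 60%" strict (exactly 60%
keeps the contig), VC edges "> 75%" strict, presence "> 75%" strict,
the depth floor "below 50 million" removes strictly smaller counts,
taxonomy's "minimum of 20% / 60%" inclusive.  The two predictors are
combined by OR: either tool's acceptance admits a contig.  Boundary
cases are unit-tested individually.

## The phage-vs-ICE classifier

Architecture is fixed: 1026 inputs → dense 10 (ReLU) → dense 5 (ReLU) →
1 sigmoid; loss is binary cross-entropy, optimizer Adam, mini-batches of
32.  Features are z-scored before the network; without standardization
the mixed scales (density ≈ 1, 5-mer frequencies ≈ 1e-3) stall
optimization.  5-mers are counted on the given strand only — canonical
collapsing would halve the 1024-column block — with N-containing windows
skipped and the remaining counts renormalized.

Model selection is a 5-fold stratified cross-validation over a small
grid (learning rate {1e-3, 1e-2} × epoch budget {50, 150}) scored by
mean AUC, followed by a refit on the full training set; everything is
deterministic given the seed.  The fitted weights are exported to a
portable JSON form and scoring is an explicit numpy forward pass,
verified to reproduce the fitting library's probabilities to 1e-10.

The operating point treats ICE as the positive class and a true phage
flagged as ICE as the false positive, since the costly error when
curating a phage catalog is discarding a real phage.  The threshold is
the lowest score cut-point whose empirical FPR on validation data stays
≤ 0.25% (maximizing ICE recall subject to the budget); an unattainable
budget falls back to the most conservative cut with a warning.

## Dereplication

Greedy longest-first clustering in the CD-HIT style: sequences are
visited by decreasing length (ties lexicographic by id) and join the
first representative they match, else found a new cluster.  Identity is
a pluggable backend; the built-in one uses edit-distance alignment
(edlib), end-to-end for the 99% global level and shorter-as-infix for
the species level, where identity is computed over the shorter sequence
(aligned in full, satisfying the ≥ 75% aligned-fraction requirement by
construction for the indel-free fixtures).  Representatives are pairwise
non-matching at the level's threshold; the cluster set partitions the
input.

## Viral clusters and MCL

Pair coverage merges, per unordered pair, hits with E ≤ 0.001 and
identity ≥ 90% projected onto the shorter sequence; an unweighted edge
is created when the merged coverage exceeds 75%.  Coverage is
symmetrized by pooling hits from both alignment directions, since
tabular all-vs-all output is asymmetric per direction.

The Markov Clustering engine alternates expansion (matrix squaring) and
inflation (entrywise power 6.0 with column renormalization) on the
column-stochastic adjacency with unit self-loops, converging when the
flow matrix changes by < 1e-6 (max 100 iterations, error with the
residual otherwise).  Clusters are attractor rows and their supports,
with overlapping attractor systems merged; the output always partitions
the node set and never joins distinct connected components.  Pruning of
small entries is available but defaults to a near-exact 1e-9 cutoff and
never removes a column's largest entry: on the small dense graphs this
package targets, an aggressive blunt cutoff measurably changes
clusterings relative to the exact flow (the large-scale programs that
prune aggressively pair the cutoff with mass-recovery machinery), and a
starved column would break the partition invariant.  At inflation 6.0
the tested random graphs converge in a few dozen iterations.

Protein clustering reuses the same engine on a similarity graph and
drops single-member clusters.  The similarity metric is pluggable; the
built-in one is the pair's best bitscore normalized by the larger
self-hit bitscore, capped at 1 — a deliberate stand-in for more
elaborate hybrid metrics, exposed as a function argument.

Clade structure within a phage group uses shared-protein-cluster
fractions with the symmetric union denominator, |A∩B| / |A∪B|.  Genomes
sharing > 40% are called one genus; pairs in the open (20%, 40%) band
are same-subfamily/different-genus.  The accompanying dendrogram is
average-linkage, Euclidean metric, over rows of the shared-fraction
matrix.

## Taxonomy consensus

One vote per gene — its best hit by full-sequence E-value, ties by
bitscore then taxon name.  Eligibility: hits on ≥ 20% of genes, or ≥ 2
genes for contigs with fewer than 10.  Consensus walks ranks from most
specific to broadest (an optional lineage map lets specific votes count
toward ancestors) and returns the first taxon reaching ≥ 60% of hit
genes; an exact tie between two taxa at the winning rank returns
"unassigned" rather than an arbitrary choice.  Lowering the consensus
threshold can only assign more contigs, never fewer (tested).

## Host assignment

CRISPR spacer matching is exact two-strand substring search: the
published criterion (100% identity across the whole spacer, short-word
alignment parameters) reduces bit-for-bit to "the spacer or its reverse
complement occurs verbatim", so no external aligner is involved.
Genomes are treated as linear; a spacer spanning a circular junction
would be missed.  Spacers from arrays below evidence level 3 are
excluded, as are spacers with ambiguous bases (with a warning).
Prophages are assigned to their source assemblies; assignments
deduplicate per (phage, host) pair while keeping distinct hosts from
different methods.  Host range is the most specific GTDB rank at which
all host lineages agree, with hosts spanning two phyla reported as
"cross-phylum"; inconsistent lineages (one taxon under two parents) are
rejected.

## Phageome profiling

Presence, depth and global-VC rules are threshold comparisons listed
above.  Jaccard distances are computed on per-sample VC sets (a VC is
present iff any member genome is); two empty phageomes get distance 0 —
identical, if vacuously so.  Collapsing genomes to VCs can only shrink
distances (tested).  The 5-continent rule counts a continent once a
single sample shows the VC; a stricter per-continent sample floor is a
parameter.  The PCA embedding of the distance matrix is a visualization
convenience; group significance testing is left to general statistics
packages.

## Synthetic fixtures

Generators are pure functions of seed and parameters and always emit
their planted truth.

* **Phage/ICE genomes**: sequences from class-specific first-order
  Markov chains (transition matrices drawn per class from a seeded
  Dirichlet blend, simulated vectorized across the batch), lengths
  uniform in 8–16 kb — the typical scale of gut Caudovirales prediction
  fragments.  Genes are tiled non-overlapping to per-genome targets
  drawn around class means: phage 1.4 genes/kb and 45% hypothetical,
  ICE 0.9 genes/kb and 75% hypothetical (sd 0.15 and 0.08).  The
  directions of these gaps mirror real phage/ICE corpora; their sizes
  are deliberately wider, so classifier checks (held-out AUC ≥ 0.95
  across seeds, shuffled-label control at chance) validate the
  machinery, not the biological difficulty of the real corpora.
* **Sequence families**: point substitutions at rate d, no indels by
  default, so expected pairwise identity is exactly (1−d)² + d²/3 and
  co-clustering truth at each threshold follows analytically
  (d = 0 → one cluster everywhere; d = 0.02 ≈ 96% identity → one
  species-level cluster and VC but distinct at 99%; d = 0.20 ≈ 65% →
  distinct everywhere).
* **CRISPR fixtures**: 25–45 bp spacers cut verbatim from chosen
  genomes (half stored reverse-complemented), rejecting fragments that
  coincidentally occur elsewhere; decoys are random sequences verified
  absent from every genome on both strands.
* **Coverage tables**: two continent groups (rural: Africa, South
  America, Oceania; urban: Asia, Europe, North America) with disjoint
  VC repertoires; present entries draw covered fraction from
  Beta(25, 3) (mass above 0.75), absent from Beta(2, 30); a noiseless
  mode emits exact 1/0 for truth-equality checks.

What passing on fixtures does **not** show: performance on real
metagenome predictions (real class gaps are narrower, real families
have indels and rearrangements, real coverage noise is not Beta), or
any of the published catalog-scale counts, which depend on tens of
thousands of external metagenomes.

## Problem sizes

Defaults keep every stage within interactive runtimes on one CPU: the
classifier study condition is 400+400 genomes of 8–16 kb; oracle sweeps
use 1,000 random interval sets, 50 random graphs of ≤ 40 nodes, and 500
spacer fixtures; clustering truth uses three 3-member families of 10 kb;
profiling uses 48 samples × 40 genomes.  All are parameters.
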