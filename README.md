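# phagekit

A desk-scale toolkit for building and analyzing a catalog of human gut
bacteriophage genomes from metagenomic predictions.  Large gut-virome
mining pipelines wrap a handful of bespoke computational rules around
standard external tools (assemblers, aligners, HMM searches); `phagekit`
implements those bespoke stages as a tested Python library, driven
either by real upstream tool outputs (tabular predictor scores, BLAST
outfmt-6 hit tables, covered-fraction tables) or by its own synthetic
fixtures with planted ground truth.

It is aimed at microbiome bioinformaticians who want the decision rules
of virome catalog construction — thresholds, consensus logic, clustering
semantics — as importable, auditable functions rather than shell
pipelines.

## The stages

1. **Screening** (`phagekit.screening`) — a contig is a candidate phage
   when it is ≥ 10 kb and either VirSorter put it in category 1, 2, 4 or
   5, or VirFinder gave score > 0.9 with p < 0.01 (categories 4/5 carry a
   prophage tag used later for host linkage).  Contigs whose merged
   human-genome hits cover > 60% of their length are discarded.
2. **Phage-vs-ICE classifier** (`phagekit.classifier`,
   `phagekit.features`) — integrative and conjugative elements (ICEs)
   contaminate phage prediction sets.  Each genome is summarized by 1026
   features: gene density (genes/kb), fraction of hypothetical proteins,
   and the relative frequencies of all 4⁵ = 1024 DNA 5-mers.  A
   feedforward network (1026→10→5→1, ReLU hidden layers, sigmoid output)
   is trained with Adam on binary cross-entropy, hyperparameters chosen
   by 5-fold cross-validation, and its operating threshold set so that
   the false-positive rate — a true phage flagged as ICE — stays ≤ 0.25%.
   Contigs assigned to non-phage taxa (*Mimiviridae*, *Poxviridae*,
   *Marseilleviridae*) are also purged.
3. **Dereplication and viral clusters** (`phagekit.clustering`,
   `phagekit.mcl`) — greedy longest-first dereplication at 99% global
   identity, then at 95% identity over a local alignment covering ≥ 75%
   of the shorter sequence (the "species" level).  Viral clusters (VCs,
   roughly sub-genus) come from a graph whose edges join pairs where
   ≥ 90%-identity hits (E ≤ 0.001) cover > 75% of the shorter genome,
   partitioned by a Markov Clustering implementation at inflation 6.0.
   The same engine clusters proteomes (singleton clusters dropped), and
   shared-protein-cluster fractions resolve genus (> 40% shared) vs
   subfamily (20–40%) structure within a clade.
4. **Taxonomy and hosts** (`phagekit.taxonomy`, `phagekit.hosts`) —
   per-gene HMM-style hits vote for a contig's taxon: eligible contigs
   (hits on ≥ 20% of genes, or ≥ 2 genes when under 10 genes) take the
   most specific taxon with ≥ 60% agreement among hit genes.  Hosts are
   assigned by exact full-length CRISPR-spacer matches (either strand,
   spacers from evidence-level 3/4 arrays) and by linking prophages to
   their source assemblies; a VC's host range is the most specific GTDB
   rank shared by all its hosts.
5. **Phageome profiling** (`phagekit.phageome`) — a genome is present in
   a sample when reads cover > 75% of its length; samples under 50
   million reads are dropped; samples are compared by Jaccard distance
   on their VC sets, embedded by PCA, and summarized as per-continent
   prevalence and globally distributed VCs (≥ 5 continents).
6. **Fixtures** (`phagekit.simulate`) — seeded generators for every
   input above, each emitting machine-readable planted truth.

## Worked example

```bash
python examples/03_viral_clusters.py
```

prints

```
identical: divergence 0.0, expected pairwise identity 1.000
species: divergence 0.02, expected pairwise identity 0.961
diverged: divergence 0.2, expected pairwise identity 0.653
global 99%: 9 genomes -> 7 clusters
species 95%/75%: 9 genomes -> 5 clusters
VC graph: 6 edges -> 2 non-singleton VCs of 5 total
  VC_1: ['iden_000', 'iden_001', 'iden_002']
  VC_2: ['spec_000', 'spec_001', 'spec_002']
```

Three planted families behave exactly as their divergence dictates: the
identical copies collapse at every level; the ~96%-identity family stays
apart at 99% global identity but forms one species-level cluster and one
VC; the ~65%-identity family falls below the 90%-identity VC floor and
remains as singletons.  The other `examples/*.py` scripts walk through
screening, classification, taxonomy/host assignment and phageome
profiling the same way.

A thin CLI mirrors the library for shell use:

```bash
phagekit simulate mge --seed 17 --n-phage 50 --n-ice 50 --prefix scratch/mge
phagekit mge train --pos-fasta ... --neg-fasta ... --model model.json
phagekit derep --fasta genomes.fna --identity 0.99 --mode global --out clusters.tsv
phagekit vc --hits blast6.tsv --lengths lengths.tsv --out vcs.tsv
```

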