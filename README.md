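# radphylo

Phylogenetics from restriction-site associated DNA (RAD) sequences.

RAD sequencing samples the short genomic regions flanking the recognition
sites of a restriction enzyme (e.g. SbfI, 5′-CCTGCAGG-3′).  Because
restriction sites are scattered across the genome and moderately conserved
between related species, the harvested flanks form a large set of putatively
orthologous loci — without requiring a reference genome.  `radphylo` is a
toolkit for studying how well such data resolve *interspecific* phylogenies.
It is aimed at systematists evaluating RAD-style reduced-representation data
for tree inference, and at methodologists who want a controlled, fully
synthetic test bed for the clustering/filtering choices involved.

## The workflow

Given per-taxon genome assemblies (or a reference whole-genome alignment for
truth-tracked benchmarking), the pipeline is:

1. **Digest** — find every exact motif occurrence and harvest the `L` bases
   immediately upstream and downstream (the motif itself is excluded; flanks
   running past a contig end are dropped).
2. **Cluster** — estimate orthology by greedy seed-based identity
   clustering: reads are processed in input order and join the first seed
   whose pairwise identity ≥ T, else found a new cluster.  Identity is
   defined on the score-optimal global alignment (match +1, mismatch −1,
   gap −2); the result depends on input order, so the pipeline runs seeded
   input-order replicates and reports the spread.
3. **Filter** — discard clusters with more than one read from a single
   taxon (a paralogy signal), then clusters with fewer than *k* = "min.
   taxa" distinct taxa (k ≥ 4 for an informative unrooted tree).
4. **Assemble** — align each surviving cluster with a seed-anchored star
   aligner and concatenate into a total-evidence supermatrix, writing `?`
   where a taxon lacks a locus.
5. **Infer** — Jukes–Cantor pairwise-deletion distances
   (d = −(3/4)·ln(1 − 4p/3), capped at 5 substitutions/site) →
   Saitou–Nei neighbor joining → nonparametric bootstrap over matrix
   columns for node support.  Matrices in which a taxon has no data at all
   are flagged incomplete and excluded from inference.
6. **Evaluate** — bipartition-based accuracy against a reference topology
   (a node is correct iff its taxon bipartition occurs in the reference),
   counts of correct/incorrect nodes with bootstrap support > 70%,
   orthologous-cluster fraction against truth labels, Mann–Whitney U
   comparison of support on correct vs incorrect nodes, and consistency of
   topologies across input-order replicates.

A synthetic-data module (`radphylo.synth`) generates genomes with planted
restriction sites evolved along a known tree under Jukes–Cantor, so every
stage is testable against ground truth without downloading anything.

## Worked example

```python
from radphylo import synth, digest, pipeline

data = synth.make_fixture("dros12", seed=11)   # 12 taxa, 300 planted SbfI sites
reads = digest.harvest_from_alignment(data.alignment, data.params.enzyme, 100)
cfg = pipeline.RunConfig(identity_grid=(0.55, 0.70, 0.85), min_taxa_grid=(4,),
                         replicates=5, master_seed=11, bootstrap=100)
res = pipeline.run_pipeline(reads, data.alignment.taxa, cfg, reference_tree=data.tree)
print(res.summary[["identity", "correct_nodes_mean", "matrix_length_mean",
                   "orthologous_fraction_mean"]].to_string(index=False))
```

prints

```
 identity  correct_nodes_mean  matrix_length_mean  orthologous_fraction_mean
     0.55                 6.6              6454.4                   0.340227
     0.70                 9.0             60979.0                   1.000000
     0.85                 9.0             65737.2                   0.999698
```

Read it as: at clustering identity 0.55 the greedy clusters absorb
non-orthologous reads (34% of clusters are purely orthologous), the paralog
filter then discards most loci, and the trees average 6.6 of 9 correct
internal nodes; at 0.70 and 0.85 essentially every cluster is one true locus
and all five input-order replicates recover the true 12-taxon topology at
every node.  The same `radphylo` CLI (`radphylo simulate | digest | cluster
| assemble | infer | evaluate | run`) exposes each stage on files, writing
relaxed-PHYLIP matrices with RAxML-style partition files, Newick trees with
support labels, and TSV cluster/report tables.

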