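# panisles

Discovery of genomic islands and **homeocassettes** in collections of
closely related prokaryotic genomes, via the pan-genome graph.

Genomic islands are horizontally acquired loci with a limited distribution
among the strains of a species. When many near-clonal genomes are
available, islands can be found without compositional heuristics: build
the pan-genome graph (gene families as nodes, observed gene adjacencies as
edges), overlay each family's *representation* (how many genomes carry
it), and look for the signature pattern

```
core gene — (rare gene(s)) — core gene
```

i.e. a run of low-representation families flanked on both sides by
near-universal core families. When two *different* islands invade the same
pair of core genes in different, mutually exclusive sets of genomes, they
form a *conflicting pair*; if at least 50% of each island's gene content
consists of divergent homologs of the opposing island's genes
("homeoalleles"), the pair is a **homeocassette** — two swappable,
iso-functional cassettes maintained at one locus within a species.

The package implements that discovery pipeline end to end, plus the
supporting analyses used to characterize such islands:

- **pangraph** — gene families (greedy 98% nucleotide-identity
  clustering, or imported Panaroo outputs), core/shell/cloud divisions
  (core = present in ≥ 44 of 47 genomes, ~94%; cloud = exactly one
  genome), and the adjacency graph with per-edge genome support.
- **islands** — the core-flanked run query with locus-level merging
  (identical / reversed / subset occurrences), discard of over-multifurcated
  loci, ±5-gene mobilome neighborhood scan (transposase / integrase /
  tRNA), island G+C, and cross-carrier sequence-identity flags.
- **homeocassette** — conflicting pairs at shared loci,
  local-alignment homology with shuffle-permutation significance (the PRSS
  idea), greedy one-to-one homeoallele matching, unbalanced duplications,
  iORFans, and the ≥ 50% classification rule.
- **tani** — fragment-based ANI and alignment fraction (AF), the
  tANI genome distance `d = −ln(ANI × AF)` (species boundary `d < 0.315`,
  i.e. ANI > 73% at AF = 1), neighbor-joining trees, and a
  fragment-resampling bootstrap.
- **popgen** — Tajima's D per core-gene alignment (families with
  |D| < 0.2 treated as effectively neutral), a SNP matrix from concatenated
  neutral genes, and nested population assignment by silhouette-guided
  hierarchical clustering.
- **dtl** — NJ proto-phylogenies, rooting by minimum
  duplication-transfer-loss (DTL) reconciliation cost, an exact undated
  parsimony DTL dynamic program with uniform sampling of optimal
  reconciliations (cost schemes (2,3,1), (3,3,1), (2,4,1)), event rates
  normalized by internal nodes × total branch length, and a Welch t-test
  comparing island vs core-gene rates.
- **synthetic** — a generator of pan-genomes with planted ground
  truth (islands, homeocassette pairs, mobilome flanks, nested clades of
  core SNPs) so every stage is testable without downloads.

## Worked example

Run the synthetic demo pipeline (12 genomes, 150 core families, four
planted islands including one conflicting pair):

```
panisles all --outdir demo_out --seed 7
```

The manifest (`demo_out/manifest.json`) reports 228 gene families
(150 core / 58 shell / 20 cloud), and `planted_recovered: "4/4"` — every
planted island is rediscovered with its exact flanks and carrier set.
`pair_summary.tsv` contains the one planted conflicting pair:

```
pair_id              invaded_core_genes  orfs_encoded  n_homeoalleles  avg_gc  classification
island003+island004  core0080,core0081   4 vs 4        3               0.501   homeocassette
```

Three of four genes on each island are homeoalleles (75% ≥ 50%), so the
pair is classified a homeocassette; the two islands' carriers are
disjoint (no exclusivity violations). `dtl_comparison.tsv` gives the
island-vs-core Welch test on normalized event rates:

```
event_class   p_value
duplication   0.326
loss          0.0147
transfer      8.6e-05
```

— island trees are inferred as transferred (and lost) significantly more
often than core genes, the expected signature of mobile loci.

Each stage is also runnable on its own (`panisles islands`, `panisles
tani`, ...) and on real inputs: per-genome FASTA + GFF3
(`--mode fasta+gff`) or Panaroo outputs (`--mode panaroo`).

## Layout

```
src/panisles/     library modules (pangraph, islands, homeocassette,
                  tani, popgen, dtl, synthetic, pipeline, cli)
tests/            pytest suite incl. end-to-end acceptance checks
docs/methods.md   model and algorithm notes, parameter defaults
scripts/          acceptance script
```
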