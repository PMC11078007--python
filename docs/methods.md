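# Methods

## The pan-genome data model

Gene calls are ordered records `(genome, contig, index, strand, family)`.
A *pan-gene family* groups homologous genes across genomes; when family
labels are not supplied (e.g. by Panaroo), they are assigned by greedy
single-linkage clustering at ≥ 98% global nucleotide identity
(edit-distance based; identity ≥ t forces a length ratio ≥ t, which is
used to prune hopeless pairs). This is a deliberate simplification of
Panaroo's multi-stage graph correction: the bespoke part of this package
begins at the graph *query*, and a GML importer accepts real Panaroo
graphs for users who want the full clustering.

The pan-genome graph has one node per family and an undirected edge for
every adjacency observed in gene order on a single contig; the edge's
*support* is the set of genomes exhibiting the adjacency (a genome counts
once per edge regardless of copy number). Edges never cross contig
boundaries. Divisions follow representation (number of distinct genomes
per family): **core** ≥ core threshold, **cloud** = exactly 1, **shell**
otherwise. The core threshold defaults to ceil(0.94 · n) and is pinned to
44 when n = 47, the scale of the data set the method was designed around.

## Island discovery

An island occurrence is a maximal run of non-core families bounded by a
core family on each side, found by a linear scan of each contig's gene
order. This per-genome scan is equivalent to traversing the graph's ±20
neighborhood paths wherever a locus is linearizable, and admits a direct
correctness argument (the test suite checks it against a brute-force run
scanner on random pan-genomes). Runs touching a contig end lack a flank
and are skipped (counted in the report); runs longer than `max_len`
(default 40, comfortably above the largest curated island of 22 ORFs) are
reported as overlong.

Occurrences are grouped by unordered flank pair ("locus") and merged:
identical member tuples, reversed tuples (orientation-normalized), and
proper subsets (recorded as *partial carriers*) join an existing island;
otherwise an occurrence joins the island with the highest member-set
Jaccard ≥ 0.5, or founds a new island. Loci that still hold more than
`max_variants_per_locus` islands (default 3) are discarded as
unresolvable multifurcations — a numeric stand-in for the curators' "few
multifurcations" judgement, chosen because the most complex retained
locus in the motivating data had three paths. Islands of one gene are
kept only when another island invades the same locus.

Post-processing: G+C over pooled carrier sequences (N excluded from both
numerator and denominator); a per-carrier scan of the ±`radius` (default
5) genes beyond each flank for transposase / integrase / tRNA annotation
labels, where a tRNA whose family is itself an island member is not
counted; and an `identical_flag` that is true when all carriers'
concatenated member sequences are byte-identical after orientation
normalization (reverse-complemented occurrences are normalized first).

## Conflicting pairs and homeocassettes

All island pairs sharing a flank pair become conflicting pairs; carrier
intersections are reported as mutual-exclusivity violations rather than
errors (real data contains such strains). Every cross-island gene pair is
scored by local amino-acid alignment (BLOSUM62, affine gap open 11 /
extend 1; nucleotide scoring +2/−3 with gaps 5/2 where sequences exist).
Significance is a shuffle-permutation test: the observed score is
compared against `n_shuffles` (default 200) alignments to independently
shuffled partners, with the pseudocount estimator
`perm_p = (1 + #null ≥ obs) / (1 + n_shuffles)`. The shuffled side and
the RNG stream depend only on the unordered gene names, making the search
symmetric in the two islands and deterministic given the seed.

A pair of genes is homologous iff `perm_p ≤ alpha` and the alignment
covers ≥ 50% of the shorter protein. The default `alpha = 0.01` was
chosen jointly with `n_shuffles = 200`: the estimator's floor is
1/201 ≈ 0.005, so a perfect score is significant, while a random score
(uniform rank) passes with probability ≈ 2/201 ≈ 1%. Significant hits are
resolved greedily by descending score into one-to-one *homeoalleles*
(best-reciprocal-hit style; ties broken lexicographically); a leftover
gene whose only significant partners are already matched becomes an
*unbalanced duplication*; genes with no significant partner are
*iORFans*. Classification: a pair is a **homeocassette** iff on *both*
islands at least 50% (inclusive) of members participate in homeoallele or
duplication matches. Applying the rule to both islands is a design
choice; the threshold's provenance does not specify which island's gene
content anchors the fraction.

## tANI distances and trees

Each query genome is cut into consecutive windows of `fragment_len`
(default 1020 nt, the convention of the fragment-ANI lineage of methods);
a trailing window is kept when it reaches `min_coverage` (default 0.7) of
the nominal length, so a genome against itself yields AF = 1 exactly.
Fragments are mapped by infix alignment (edlib, band-limited by the
identity cutoff); hits with identity ≥ `min_identity` (default 0.7) are
retained. ANI is the mean retained identity, AF the retained fraction of
the query, both symmetrized by averaging the two directions. The distance
is `−ln(ANI × AF)`, capped (default 10) when no hits survive. The product
form is used because only it reproduces the printed species boundary:
−ln 0.73 = 0.3147 ≈ 0.315 at AF = 1.

Trees are neighbor joining (scikit-bio) with negative branch lengths
clamped to zero. Bootstrap: each query's fragment set is resampled with
replacement, the matrix and tree recomputed, and bipartition frequencies
(×100) attached to internal edges. Resampling reuses the stored
per-fragment identities, so replicates cost no new alignments.

## Neutral-core population structure

Tajima's D is computed per core-family alignment from the canonical 1989
coefficients (a1, a2, b1, b2, c1, c2, e1, e2), with π the mean pairwise
difference count per alignment. Columns containing gaps or ambiguous
bases are removed first (conventional; the source procedure does not
specify). D is undefined at S = 0 (flagged, non-neutral) and requires
n ≥ 4. The neutrality filter is strict: |D| < 0.2, so D = ±0.2 is
non-neutral. Neutral alignments are concatenated; polymorphic columns
(≥ 2 distinct non-N states) form the SNP matrix, with N filling families
a genome lacks; N-aware Hamming distances exclude uncalled sites from
the denominator.

Population assignment approximates a nested Bayesian clustering with a
deterministic stand-in: average-linkage hierarchical clustering cut at
the k ∈ [2, 10] maximizing mean silhouette, then the same procedure
within each level-1 cluster for level 2 (default 2 levels; the original
analysis does not state its level count). Labels at level k+1 refine
level k by construction. Note that a flat silhouette criterion applied to
strongly nested data can legitimately prefer the finer partition at
level 1; the planted-structure tests therefore use (and real data
typically shows) dominant top-level divergence.

## DTL reconciliation

Gene "proto-phylogenies" are NJ trees on Jukes–Cantor distances
(pairwise-deletion of gap/N sites; saturated pairs capped), built only
when there are ≥ 3 taxa and non-identical sequences. Unrooted trees are
rooted at the edge minimizing DTL cost, evaluating every edge with ties
broken by traversal order.

Reconciliation uses the undated parsimony DTL model (RANGER's default
regime): a dynamic program over (gene node, species node) cells with
speciation, duplication, and transfer cases; losses cost one per species
edge skipped while descending; transfer recipients may be any species
edge incomparable to the donor, and no time-consistency constraint is
imposed. The DP also counts optimal solutions per cell, enabling exact
uniform sampling of optimal reconciliations by weighted backtrace. The
published protocol's "300 independent runs" is realized as 300 uniform
samples whose event counts are averaged; every sample satisfies
d·D + t·T + l·L = min cost. Cost schemes (2,3,1), (3,3,1), (2,4,1) for
(duplication, transfer, loss) are all computed; (2,3,1) is the headline
scheme in summaries. The DP is verified against exhaustive enumeration
over all gene-to-species mappings for trees up to 6 leaves, and against
an LCA-mapping duplication-loss oracle when transfers are priced out.

Event counts are normalized to rates by (number of internal gene-tree
nodes) × (total branch length); gene trees with zero total length are
excluded and flagged. Island trees use the concatenated island sequence
per full carrier. Island and core rates are compared per event class by
Welch's two-sided t-test.

## The synthetic generator

The generator emulates the structure of the motivating data set — 47
genomes of one species at ≥ 98.5% ANI, a core backbone in conserved
order, shell/cloud accessory genes, and islands of 2–22 genes planted
between specific core pairs — with full ground truth. Defaults: 47
genomes, 2,000 core families, 400 shell and 300 cloud singletons, gene
lengths 300–900 nt, core G+C 0.68 (the core-genome average of the
motivating species), island G+C 0.45 (inside the reported 40–55% island
band), core SNP rate 0.01/site (≈ 99% pairwise core identity).

Sequences are i.i.d. per position at the target G+C, then ORF-ized
(start/stop added, internal stops resampled) — composition is the only
sequence property downstream stages consume, so no codon or rate model is
attempted. Core SNPs are planted on a two-level clade structure (40%
clade-informative, 20% subclade-informative, 40% frequency ~1/k random
subsets), giving population clustering a recoverable nested signal and
Tajima's D a mix of balanced and rare variants. Homeoalleles are produced
by substituting amino acids to a target identity (exact to rounding,
since no indels are introduced) and back-translating with G+C-weighted
codons. Flanking transposase/integrase/tRNA elements are planted as
accessory genes at configured gene offsets beyond the flanks. Shell and
cloud singletons occupy one inter-core slot each, so control runs without
planted islands contain no multi-gene accessory runs — by design, an
islands-free control has zero discoverable islands.

What the generator does **not** emulate: recombination, indels and length
variation within families, annotation noise, assembly errors beyond
optional contig fragmentation at random core-core junctions, and
realistic phylogenetic sequence evolution. Passing tests therefore
demonstrate the correctness of the graph query, the classification logic,
and the statistics on clean inputs — not robustness to clustering errors
in real draft genomes, which is the role of the Panaroo import path.

## Problem sizes and numerical choices

Tests run at desk scale by choice: planted-recovery checks use the full
47-genome / 2,000-core configuration (sequence-free, 20 seeds), while
sequence-bearing end-to-end runs use 8–12 genomes with 60–150 core
families; the demo pipeline config mirrors the study structure at that
reduced scale. Determinism is end-to-end: all randomness flows from one
top-level seed via per-stage derived seeds, outputs are written in sorted
order, and stage timings go to stderr only, so a rerun with the same
config is byte-identical.

Degenerate inputs: empty or all-N sequences raise on G+C; pairs with no
retained ANI fragments are flagged and capped in the distance matrix;
S = 0 alignments yield undefined D; identical sequences or < 3 taxa are
rejected for tree building; < 3 genomes yield a single population
cluster. Tie-breaks are lexicographic (clustering, homeoallele matching)
or traversal-order (rooting) throughout.
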