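# pqclan

Forest- and network-based analysis of microbial gene evolution: tools for
studying genomic fluidity — lateral gene transfer (LGT), recombination, and
gene/genome partnerships — without forcing the data onto a single species
tree.

The package targets pangenome-scale datasets of the kind produced for
bacterial strain collections (tens of strains, thousands of gene trees,
all-vs-all protein similarity searches, mobile genetic elements): it is for
microbial evolutionary biologists who want fast heuristic answers to
questions a single reference tree cannot address — which families were
recently exchanged with plasmids and phages, which trees are structured by
lifestyle rather than taxonomy, which strain pairs recombine preferentially.

## What it computes

**Gene families** (`pqclan.families`) — single-linkage clusters over
homology hits: either every hit pair passing e-value/identity filters
("false BBH") or only reciprocal best hits ("true BBH"). Families are
connected components of the resulting sequence graph.

**Genome networks** (`pqclan.genome_network`) — nodes are genomes, an edge
joins two genomes sharing ≥ 1 family whose best cross-genome identity falls
in a chosen band; edge weight is 1/(shared family count). The [100, 100]
band surfaces candidate *recent* transfers between cellular chromosomes and
mobile elements; per-COG-category summaries mirror the standard
sequences/families-by-function table.

**Gene networks** (`pqclan.gene_network`) — nodes are sequences, edges
filtered hits. Per connected component: density, average clustering,
diameter, betweenness, articulation points, greedy-modularity communities,
and a coarse topology class (`clique_like` / `intermediate` / `bridged`)
for bulk triage of thousands of families.

**Clanistics** (`pqclan.clanistics`) — for a two-category leaf colouring
(natives vs intruders) of each unrooted gene tree: classification as
*pure*, *perfect clan* (one cut isolates exactly the natives), *perfect
slice* (two cuts), or *mélange*; the **p-score** (two-state parsimony =
minimum cuts separating the categories); and **E\***, a Shannon
equitability over the sizes `c_i` of the maximal all-native subtrees,

```
E* = [ - Σ (c_i/N) ln(c_i/N) ] / ln(N),   N = Σ c_i,
```

0 when the natives form a single clan, → 1 when fully interleaved.
`find_mobile_modules` groups trees that carry mobile-element leaves, occur
only in pathogenic hosts, and share identical strain presence/absence
vectors — candidate mobile modules of pathogenicity.

**Polychromatic quartets** (`pqclan.quartets`) — per gene tree, random
quartets of four distinct strains are drawn; the induced bipartition (kept
only when the separating path carries a bootstrap-supported edge, default
≥ 50%) contributes its two "clans" (cherries) to per-strain-pair tallies.
Pooled over the forest, `f(i,j) = same-clan count / co-occurrence count`,
and `d(i,j) = 1 − f(i,j)` is a distance exported as Nexus for
split-network (Neighbor-Net) visualization. A one-tailed Mantel
permutation test on `d` against a group design (e.g. PATH vs NON-PATH)
asks whether between-group distances exceed within-group ones — the
signature of preferential within-group exchange. Forests are partitioned
into core (all strains), shell, and single-copy subsets.

**Synthetic forests** (`pqclan.simulate`) — a Yule species tree over
strains plus an out-group clade; each gene tree is a (core or shell)
restriction perturbed by Poisson-distributed transfer events (recipient
leaf regrafted next to its donor, optionally biased towards
same-lifestyle pairs, optionally depositing a mobile-element leaf), with
bootstrap supports high on concordant edges and mixed on transfer-created
edges. Every event is logged in a truth table, so all of the above is
testable at desk scale.

## Worked example

```
$ pqclan simulate --n-strains 8 --n-trees 15 --seed 5 --out sim/
15 trees -> sim

$ pqclan pq --forest sim/forest.nwk --annotations sim/annotations.tsv \
    --n-quartets 100 --seed 7 --mantel-groups pathogenicity --out pq/
trees_used	15
mantel_r	-0.2596
mantel_p	0.9164
```

The simulated forest has 15 trees over 8 strains (5 pathogenic, 3 not) at
the default transfer rate with *no* group bias, so the Mantel test is
correctly insignificant (r < 0, p = 0.92): within-group PQ distances are
no shorter than between-group ones. `pq/pq_distances.nex` holds the
8 × 8 one-complement frequency matrix for SplitsTree/Neighbor-Net, and
`pq/pq_counts.tsv` the raw per-pair tallies.

```
$ pqclan clanistics --forest sim/forest.nwk --annotations sim/annotations.tsv \
    --natives ecoli --support-cutoff 50 --out clan/
counts: pure=0, perfect_clan=14, perfect_slice=1, melange=0, absent=0
```

With strains as natives and out-group bacteria as intruders, 14/15 trees
keep all strains in a perfect clan and one needs two cuts — transfer at
the default rate rarely drags a strain into the out-group clade.
`clan/clan_reports.tsv` lists per-tree classification, E*, p-score and
leaf counts.

Every run writes a `manifest.json` (inputs, digests, parameters, seed) so
results are replayable.

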