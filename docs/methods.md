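# Methods

This note records the models and procedures behind `pqclan`, the choices
made where the design was genuinely open, and what the synthetic forests do
and do not establish about real data.

## Gene families

Families are single-linkage clusters of an all-vs-all similarity search.
Two linkage modes are provided: *false BBH* links any sequence pair with a
hit passing the filters; *true BBH* links only reciprocal best hits (b is
a's best-scoring subject within b's genome and vice versa) passing the same
filters. The filters are an e-value ceiling (default 1e-20 for clustering;
hit tables are assumed pre-thresholded at the customary 1e-5 retention
cutoff, both exposed as parameters) and an identity floor (default 70% for
forest construction, 30% for gene networks). When the two BLAST directions
disagree, a pair passes if its *better* direction passes: asymmetric BLAST
statistics are common and single linkage is permissive by design. Best-hit
ties resolve by higher bit score, then lower e-value, then lexicographic
subject id, which is order-independent and unique. Sequences that appear in
the annotation table but in no hit become singleton families, keeping the
family partition total. Because true-BBH edges are a subset of false-BBH
edges at equal thresholds, true-BBH families always refine false-BBH ones,
and raising the identity floor (or lowering the e-value ceiling) can only
split families, never merge them.

## Genome networks

For an identity band [lo, hi], a family is *shared* by a genome pair when
the maximum identity over its cross-genome member pairs lies in the band.
Maximum (rather than mean or any) is used because it is the only choice
that makes "families 100% identical between two genomes" well defined; it
also makes bands disjoint per family and genome pair. Edge display weight
is the inverse of the shared-family count (retained alongside the raw
count so either convention can be exported). Per-category summaries count
shared sequences (those attaining an in-band cross-genome identity) and
shared families; each family receives a single category — the modal COG
letter of its shared sequences with ties resolved L-first then
alphabetically, X absorbing unknowns — and percentage columns always use
the computed column totals, never externally supplied ones. Candidate
recent transfers are the per-family records of cellular↔mobile-element
edges in the [100, 100] band; MGE–MGE and cellular–cellular edges are
excluded by definition.

## Gene networks

Components of the filtered sequence graph are annotated with: density
(possible-connection ratio) and average local clustering (both reported —
prose definitions of "clustering coefficient" in this literature match
density, common usage matches transitivity), diameter in edge counts,
unnormalized betweenness, articulation points (global, plus *local* ones
computed within each greedy-modularity community), and communities.
Topology classes: `clique_like` needs density ≥ 0.8 and no articulation
point; `bridged` needs density ≤ 0.3, or an articulation point that either
exceeds the component's mean betweenness by 2 SD or is an *obligate
bridge* (every component left by its removal has ≥ 2 nodes — the barbell
join pattern; the z-rule alone is underpowered on components of ~10
nodes); everything else is `intermediate`. The 0.8/0.3/2-SD values are
configuration defaults documented as heuristics, not biological constants.
Single-node components report diameter 0 and clustering 1.0 by convention
and carry a `degenerate` flag.

## Clanistics

Given a two-colouring of the leaves, let T_N be the minimal (Steiner)
subtree spanning the natives and c the number of edges with exactly one
endpoint in T_N. Since phylogenetic trees have no degree-2 vertices, c is
the minimum number of cuts isolating a single all-native component that
contains every native; hence c = 1 ⇔ perfect clan and c = 2 ⇔ perfect
slice, which is how classification is computed (and verified in the tests
against explicit one-cut/two-cut enumeration). Trees whose natives cannot
be isolated by two cuts are mélange; trees without intruders are pure;
trees without natives (common under the mobile-element rule) are tallied
separately as "absent". The *trivial* flag marks ≤ 1 native.

The **p-score** is the parsimony score of the native/intruder character on
the unrooted, possibly multifurcating tree, computed by unit-cost Sankoff
dynamic programming (exact on polytomies). It equals the minimum number of
edge cuts separating the two categories, is symmetric under exchanging the
category labels, and can only grow when poorly supported edges are
collapsed (contraction restricts the feasible assignments).

**E\*** is a reconstruction: the index is cited in the clanistics
literature without a printed formula, so the package adopts Shannon
equitability over the sizes c_i of the maximal all-native subtrees,
normalized by ln N (N natives). This reproduces every stated qualitative
property — 0 at perfect grouping, 1 at full interleaving (all c_i = 1),
0.5 for two equal groups of a four-native tree, bounded in [0, 1],
invariant to relabelling among intruders. E* is undefined (reported
missing) when no native is present. The forest-level mean E* averages over
mélange trees only; averaging over all non-pure trees is available as an
option.

Support collapsing contracts internal edges with recorded support below
the cutoff (default 50%); edges without support are kept. Newick
internal-node labels are read as supports; strictly fractional values
(0 < v < 1) are taken as proportions and scaled ×100, while integer 0 and
1 are kept as percents — a file writing proportions with an exact "1.0"
remains ambiguous and is documented as such.

Mobile-module detection returns groups (≥ 2) of trees that contain at
least one mobile-element leaf, whose every cellular leaf of known
lifestyle is pathogenic (equivalently p-score 0 with pathogens native),
and that share an identical strain presence/absence vector; groups are
keyed by that vector. Category rules are pluggable (taxon-based,
pathogenicity, disease, mobile elements, or any callable), so reanalyses
that remap taxa — e.g. folding a sister genus into the native side — need
no code changes.

## Polychromatic quartets

Per tree, `n_quartets` (default 1000) draws sample four distinct strains
uniformly *with replacement across draws* (duplicate quartets allowed; the
original description samples "at random" with no exclusion). A strain with
several leaf copies contributes one copy drawn uniformly per quartet; the
single-copy forest subset exists precisely so this choice can be avoided
entirely. The induced bipartition of the four leaves is accepted only when
the internal path separating the two cherries contains at least one edge
with support ≥ the cutoff (default 50%; edges without recorded support
count as supported). A resolved quartet increments the co-occurrence count
of all six strain pairs and the same-clan count of the two cherry pairs;
an unresolved quartet increments nothing — the bootstrap rule is an
inclusion criterion, so unresolved draws must not enter denominators.
Trees with fewer than four distinct strains are skipped.

Pooling across trees sums counts (weighting trees by information content)
rather than averaging per-tree frequencies; the per-pair frequency
f = same/co-occurrence is conditional on co-sampling, the only
normalization invariant to unequal strain representation across trees.
The distance is d = 1 − f with zero diagonal; pairs never co-sampled are
mean-imputed (flagged) or left missing on request. On a transfer-free
forest generated from one fully supported species tree, d is additive on
that tree up to sampling error (four-point condition; measured maximal
violation ~0.005 at 30 × 400 quartets on 5 strains), so the exported
split network is a tree — incompatibility in the splits graph therefore
measures genuine conflict among gene trees, not an artifact of the
distance construction.

The **Mantel test** correlates the off-diagonal distances with a binary
design (0 within group, 1 between) and permutes strain labels; the p-value
is one-tailed in the direction "between-group distances larger", i.e.
preferential within-group exchange, with p ≥ 1/(permutations + 1)
(default 9999 permutations). A Welch two-sample t-test compares mean
pairwise distances between forest subsets (core vs shell), with the
documented caveat that pair distances are not independent observations.

## Synthetic forests

The generator is scaffolding for validation, not a model of sequence
evolution. A Yule-style species tree is drawn over the strains with an
out-group clade spliced on one branch. Each gene tree restricts the
species tree to all strains (core, probability `core_fraction`, default
0.4 ≈ published core/eligible ratios) or a uniform random subset of ≥ 4
(shell), then suffers Poisson(`lgt_rate`) transfer events: a donor/
recipient strain pair is drawn with same-pathogenicity pairs up-weighted
by `within_group_bias`, and the recipient's leaf is pruned and regrafted
next to the donor's — the topological signature of a gene replacement via
transfer. A fraction of events (default 0.1) deposits a mobile-element
leaf beside the recipient; Poisson(0.1) duplications attach second copies
so the single-copy partition is exercised. Supports are drawn uniformly
from 90–100 on unperturbed edges and 20–100 on edges created by transfer
or duplication, so the bootstrap-cutoff logic is genuinely exercised.
Two thirds of strains are pathogenic (the published 20:10 split), each
pathogenic strain carries one fixed disease label. Identical configuration
and seed give byte-identical output, and every event is logged in the
truth table.

Default `lgt_rate` is 2.0 events/tree, a heavy-mixing regime (≈ 86% of
trees carry ≥ 1 event). The Mantel *power* experiment in the acceptance
suite instead specifies 8.0 events/tree as its transfer regime: with only
66 strain pairs at 12 strains, the group effect of a 3× bias must
dominate the species-tree baseline variance of the PQ distances to be
detectable, which requires transfer to be the primary topological signal;
at that rate the unbiased null remains clean (measured type-I error ≈ 5%).
This is a property of statistical power at small strain counts, not of
the test: real 30-strain datasets offer 435 pairs and correspondingly
more sensitivity.

The hit-table generator emits complete within-family hit pairs (both
directions) with identities drawn from configured bands and e-values below
threshold, plus optional spurious cross-family hits above threshold; it
does not model alignment lengths or score distributions realistically.

**What passing tests show** — that the algorithms implement their
definitions exactly (oracle equivalence), that the statistics are
calibrated (type-I error, power) under a known generative process, and
that the pipeline is deterministic and reproducible. **What they do not
show** — robustness to alignment error, model misspecification in tree
inference, annotation noise, or biased taxon sampling, none of which the
generator emulates.

## Numerical choices and conventions

- Problem sizes in tests and the acceptance script are desk-scale (≤ 30
  strains, ≤ 200 trees, ≤ 1500 quartets/tree) so the full suite runs in
  minutes on one CPU.
- Nexus distance export writes full-triangle matrices with 6-decimal
  precision; round trips are exact to 1e-6.
- E* is clamped to [0, 1] against floating-point spill.
- Trees with < 4 leaves are accepted by the readers but flagged unusable
  by quartet sampling and skipped; identifiers are case-sensitive
  throughout.
- All stochastic entry points take a seed or `numpy.random.Generator`;
  CLI runs record their seed in the manifest.
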