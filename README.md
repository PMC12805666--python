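# treejack

Diagnose and mitigate **ineffective taxon overlap** in multilocus
phylogenetics.

Multilocus and phylogenomic studies rarely sample every taxon for every
locus.  When the sharing of taxa among loci is *ineffective* — when the
coverage pattern is not *decisive* for the underlying tree — many equally
optimal supertrees exist (a *terrace*), consensus trees collapse, and
individual taxa behave as rogues.  `treejack` is a toolkit for systematists
assembling supermatrix or supertree datasets who want to know, **before**
spending money on sequencing: which taxa are unstable because of poor
overlap, which loci hold the analysis together, and which taxon/locus pairs
are the cheapest targets for new data.

## What it computes

Given a set of rooted gene trees in Newick format (one file per locus):

1. **Matrix representation (MR).**  Each gene tree is Baum–Ragan coded —
   one binary character per non-trivial clade, taxa absent from the tree
   scored `?` — and the per-locus matrices are concatenated (exportable to
   NEXUS with a PAUP* search block for full-scale MRP).

2. **Concatabomination network.**  For every pair of leaves, a *chimera*
   merging their non-conflicting characters is substituted for the pair;
   if this adds no new pairwise character incompatibility (four-gamete
   test), there is *no cost* to forcing the leaves together and the pair
   are potential taxonomic equivalents.  The resulting network links
   sister taxa into harmless dyads — and rogues into clusters of D-type
   (disjoint-data) edges.  Exports: SIF/GraphML for Cytoscape, TSV, JSON.

3. **Gene-tree jackknife.**  The network is rebuilt with each locus left
   out.  A locus whose removal *increases* the edge count is
   **stabilizing**: its data suppress instability, and taxa missing from
   it are candidates for targeted sequencing.  `evaluate_graft` measures
   the payoff of the intervention by grafting a taxon onto a candidate
   locus tree (as sister to its nearest sampled relative in a reference
   topology) and recounting edges.

4. **Gene-sampling sufficiency.**  From the coverage pattern alone:
   the taxon coverage density *d* = (Σ n_l/n)/k, the approximate
   minimum number of loci for decisiveness at confidence *p*,

       k_min ≈ log(n³/6p) / −log(1 − d⁴),

   and the sufficiency ζ = ln(k/k_min), with ζ ≥ 0 meaning enough loci
   have been sampled for probable decisiveness.

5. **Terraces.**  Exact counting (and capped enumeration) of the plenary
   rooted binary supertrees displaying a set of induced subtrees, the
   strict consensus of the terrace, and the decisiveness test; plus tree
   statistics: resolution ρ (normalised consensus fork) and cladistic
   information content, CIC = log₂B(n) − log₂R(T) bits, with exact
   big-integer double factorials.

6. **Desk-scale MRP.**  Exact Fitch/Hartigan scoring and exhaustive or
   branch-and-bound search for *all* most-parsimonious supertrees of
   small matrices (≤ 11 taxa), with strict consensus.

A seeded synthetic-data generator (`treejack simulate` /
`treejack.fixtures`) produces multilocus tree sets with known structure —
partial coverage, injected conflict, single-locus rogues inside
polytomies — so the whole pipeline is testable end-to-end.

## Worked example

Simulate 20 taxa and 6 loci at 60 % coverage, with one rogue taxon
(`rogue1`) sampled only for locus L1, where it sits in a polytomy:

```sh
treejack --quiet simulate --n-taxa 20 --k-loci 6 --coverage 0.6 \
    --rogue rogue1:L1:polytomy --seed 3 --out-dir demo
treejack --quiet network demo/loci --out-dir demo/net
treejack --quiet jackknife demo/loci
```

prints

```
{"clusters": 2, "dyads": 5, "edge_count": 12, "singletons": 3}
baseline edges: 12
  -L6: edges 16 (delta +4) *stabilizing*
  -L2: edges 13 (delta +1) *stabilizing*
  -L4: edges 12 (delta +0)
  -L5: edges 12 (delta +0)
  -L3: edges 11 (delta -1)
  -L1: edges 9 (delta -3)
```

Reading this: the network has 12 no-cost edges; the 5 dyads are cherries
(true equivalents, unproblematic) but the clusters flag instability.
Removing L6 raises the count to 16 — L6 is the best *stabilizing* locus,
so taxa missing from L6 (the rogue among them) are the prime sequencing
targets.  Removing the rogue's only locus L1 instead drops it from the
matrix entirely (9 edges): deletion also "fixes" the problem, but at the
price of an incomplete phylogeny.  Acting on the diagnosis:

```python
>>> from treejack.fixtures import FixtureConfig, RogueSpec, simulate
>>> from treejack.jackknife import evaluate_graft
>>> data = simulate(FixtureConfig(n_taxa=20, k_loci=6, coverage=0.6,
...     rogues=(RogueSpec("rogue1", "L1", "polytomy"),), seed=3))
>>> g = evaluate_graft(data.gene_trees, "L6", "rogue1", data.true_tree)
>>> g.sister, g.edges_before, g.edges_after
('t01', 12, 9)
```

Adding a single pseudo-sequence for the rogue to the top candidate locus
cuts the instability from 12 edges to 9.  The sufficiency statistics for
the same data (`treejack sufficiency demo/loci`) report d = 0.60,
k_min = 77, ζ = −2.55: the amount-of-overlap theory asks for an
unrealistic 77 loci, while the jackknife found a one-sequence fix — the
contrast the toolkit is designed to expose.

`treejack diagnose demo/loci --out-dir demo/reports` runs all of the
above in one step and writes every export plus a checksum manifest.

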