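# Methods

This note records the models and conventions the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not show about real data sets.

## Tree model and conventions

Trees are rooted, leaf-labelled, possibly polytomous, and are stored as a
leaf set plus the set of proper non-trivial clusters (one per non-root
internal vertex).  Consequences of this representation:

* degree-2 vertices cannot exist (suppressed on construction);
* child order is never meaningful; equality is cluster-set equality;
* branch lengths are parsed and discarded — no computation here uses
  them, and zero-length edges are *not* collapsed;
* Newick output is deterministic (children sorted by smallest label), so
  repeated runs are byte-identical.

Two resolution conventions coexist deliberately:

* **ρ (resolution / normalised consensus fork)** uses the *rooted*
  convention: internal vertices (root included) divided by n − 1.  A
  binary rooted tree scores 1; the star tree 1/(n−1).
* **CIC (cladistic information content)** uses the *unrooted* form:
  CIC = log₂ B(n) − log₂ R(T), with B(n) = (2n−5)!! and
  R(T) = Π_v (2·deg(v) − 5)!! over internal vertices of the unrooted
  tree.  Double factorials are exact big integers; `math.log2` of a
  Python integer is exact-argument, so no floating overflow occurs even
  for hundreds of leaves.  A fully binary tree on 105/106 leaves scores
  643.61/651.30 bits; the star tree 0.

When a tree's root has exactly two children, unrooting suppresses the
root and joins its children; their degrees are unchanged.

`nearest_sampled_relative` restricts the reference tree to the sampled
set plus the target and returns the target's sister group's
alphabetically first leaf — a deterministic tie-break for multi-leaf
sister groups; no biological meaning is claimed for the tie-break.

## Matrix representation

Standard Baum–Ragan coding of rooted trees: one column per non-trivial
cluster, cluster members 1, other leaves of the source tree 0, taxa
outside the tree `?`.  Input gene trees are treated as rooted as written;
users with unrooted semantics should root on an outgroup before
encoding (MRP parsimony scores are polarity-invariant, so the choice
does not affect search results).  No all-zero pseudo-outgroup row is
added by default — the universe-row semantics already distinguish 0 from
`?` — but `write_nexus(..., mrp_outgroup_row=True)` adds one for
compatibility with conventional MRP pipelines.

Taxa with all-missing rows are retained (and flagged) by concatenation;
they are removed only when a locus is dropped (`drop_locus`, and each
jackknife replicate), mirroring how the taxon complement of an analysis
shrinks when its only locus is removed.

## Compatibility and the no-cost test

Characters are strictly binary, so pairwise compatibility is the
four-gamete rule on taxa scored in both columns.  Internally the
all-pairs test is three integer matrix products (ones/zeros indicator
matrices against their transposes); because every combination-count
matrix is a sum of per-taxon outer products, replacing two rows by a
chimera row is a rank-two update — three outer products per count matrix
— rather than a recomputation.  Behaviour, not representation, is
normative: a naive O(n²m²) recount is kept in the test suite as the
oracle.

The **no-cost criterion is set inclusion**: a merge is free iff every
incompatible column pair of the modified matrix was already incompatible
in the original.  A count comparison (`count_after <= count_before`) was
rejected because replacing two rows by one can reduce counts for reasons
unrelated to the merge, silently masking new conflict.  The chimera
*replaces* both member rows, so the test asks "what if these two leaves
were one taxon".  Pairs conflicting on any shared column are non-edges
with no category (logged at debug level).

Edge categories are assigned from the scored-column-set relation, in this
order: A (both complete), C (identical, incomplete), B (proper subset),
D (disjoint), E (partial overlap with unique columns on both sides).
A, C, D and E are symmetric relations, B is not.  Categories affect
reporting (line styles in network exports) and the per-taxon instability
score (the D-degree), never edge existence.  The published letter
definitions of the original method are not restated in full anywhere we
could verify them; this operational table reproduces the reported
symmetry groupings, and C-versus-E naming should be treated as a
package-level convention.

## Gene-tree jackknife

Baseline and k leave-one-out replicates — exactly k+1 network builds,
independent of locus order.  *Stabilizing* means strictly positive edge
delta; ties at zero are non-candidates.  Candidate reports annotate each
stabilizing locus with its taxon count and missing-taxon list but apply
no automatic realism filter: whether a candidate is worth sequencing is
a judgement about specimens and budgets, not graph structure.

A subtle and initially counter-intuitive behaviour, reproduced faithfully
here: removing the *host* locus of a single-locus taxon usually
*decreases* the edge count, because the taxon leaves the matrix and its
D-type edges vanish.  Stabilizing loci are typically taxon-rich loci the
unstable taxon is *missing* from — which is exactly what makes them
sequencing targets.  `evaluate_graft` closes the loop: grafting the taxon
onto a candidate locus (sister to its nearest sampled relative in a
reference topology) pins its position, converts its free D-edges into
conflicts, and the edge count drops.

## Gene-sampling sufficiency

d = (Σ_l n_l/n)/k at full precision; k_min from the approximation
log(n³/6p) / −log(1 − d⁴) (base-invariant ratio; natural logs used);
ζ = ln(k/k_min) with the **unrounded** k_min.  Reported k_min is rounded
half-up; d and ζ are displayed at 2 d.p. with full precision retained.
ζ is defined so that ζ ≥ 0 ⇔ k ≥ k_min, i.e. non-negative means enough
loci for probable decisiveness.  p defaults to 0.05.  If any locus
covers every taxon the pattern is decisive a priori: k_min is reported
as 1 with a flag, and the formula (undefined at d = 1) is bypassed.
The approximation assumes uniform random taxon sampling over many
equally informative loci — an assumption essentially never met by real
data sets, which is why the package reports it side by side with the
tree-aware diagnostics rather than as a verdict.

## Terraces and permitted supertrees

Counting uses a top-down recursive decomposition.  A rooted triplet
ab|c (from any input subtree) forces a and b onto the same side of the
root of any subtree containing all three; hence the root partition of a
leaf subset X must keep each connected component of the triplet graph on
X intact, and

    N(X) = Σ over bipartitions (A, B) of the components  N(A) · N(B),

memoised on X, with two base cases: one component and |X| > 2 means no
binary tree displays the triplets (count 0); no internal triplet at all
means every rooted binary tree qualifies, (2|X|−3)!! in closed form.
Counts are exact big integers.  Enumeration follows the same recursion
and is capped (default 10⁶); above the cap only the count is returned.
The strict consensus of the terrace is computed by cluster-set
intersection of the enumerated trees, and is therefore only available
when the terrace was enumerated — a deliberate trade: no in-scope
analysis exceeds the cap, and consensus-without-enumeration would
require a separate algorithm.

Polytomies are **soft** throughout: only the triplets a tree actually
resolves constrain the count, so an unresolved input admits all its
binary resolutions.  This matters in practice: feeding a poorly resolved
consensus as the parent tree can inflate the terrace by orders of
magnitude relative to feeding one of its binary resolutions, and the
package leaves that choice to the user.

Everything is rooted; the three permitted supertrees of the classic
worked example are distinct only as rooted trees.  Unrooted inputs should
be rooted on a formal outgroup first.

## Desk-scale parsimony

Fitch scoring generalises to polytomies via the two-state majority-vote
(Hartigan) rule — exact for any vertex degree, verified in the tests
against exhaustive internal-state enumeration; `?` carries the full
state set and never contributes steps.  The search enumerates rooted
binary trees with a designated outgroup fixed as a child of the root
(default: first taxon alphabetically, logged), scoring all columns
simultaneously with vectorised masks.  Exhaustive enumeration is used
for small taxon counts, branch and bound (stepwise addition ordered by
decreasing non-missing count, partial score as the bound) up to the cap
of 11 taxa; both return the complete MPT set, and they are asserted
identical on common inputs.  Beyond the cap the package refuses and
points to the NEXUS export — heuristic search is the job of dedicated
parsimony software, not of this toolkit.

## Synthetic data: what it emulates, and what it does not

`simulate` draws a uniform random rooted binary species tree (sequential
random attachment — each labelled shape arises from exactly one
insertion sequence, hence uniform), samples each locus's taxon set
(Bernoulli per taxon, or fixed per-locus counts), and takes gene trees
to be restrictions of the species tree, optionally perturbed by local
NNI moves (`conflict_nni` per locus) to inject incongruence.  Rogue
taxa are placed in exactly one host locus; with `placement="polytomy"`
the edge above the rogue's attachment is collapsed, reproducing the
situation where the one tree containing the taxon is uninformative
about its position.  Defaults (coverage 0.6; NNI off) represent a
mid-density multilocus data set with congruent gene trees.

Two pragmatic repairs keep configurations valid: loci are topped up to
three sampled taxa, and a taxon left uncovered by the Bernoulli draw is
assigned to one random locus — both under the same seeded generator, so
outputs remain fully reproducible from the seed.

The generator produces *topologies only*: no sequences, no branch
lengths, no inference error, no alignment or model-selection artefacts,
no missing-at-the-sequence-level data (partial genes), and NNI conflict
is local by construction (no deep reticulate or ILS-style discordance).
Passing tests on these fixtures therefore demonstrates the correctness
of the diagnostics' logic — that the pipeline flags planted rogues,
ranks loci, and that grafting mitigates planted instability — not that
real data sets will be as clean; on empirical data, gene-tree estimation
error adds incompatibilities that the concatabomination test will count
as real conflict.

## Problem sizes and numerical conventions

The test suite and the acceptance script run at desk scale by design:
exhaustive oracles up to 8 leaves (135 135 rooted trees), network
fixtures of 10–21 taxa and 3–6 loci, parsimony searches to 7 taxa
exhaustively.  These sizes were chosen to make every non-trivial
computation checkable against an independent brute-force oracle in the
same run.  Rounding: k_min half-up; 2 d.p. displays round-half-even via
Python's `round` (no reported quantity sits on a .005 boundary);
terrace sizes and double factorials are exact integers; all equality
tests on floats use explicit tolerances.

## Known limitations

* The concatabomination cost test is compatibility-based; on very large,
  conflict-saturated matrices pairwise incompatibility approaches its
  maximum and the test loses discrimination.  A parsimony-based cost
  variant (tree-length effect of the merge) is a natural extension and
  is out of scope here.
* Terrace counting is exponential in the number of independent
  components at each recursion level; it is intended for diagnosis at
  moderate sizes, not for phylogenomic matrices with hundreds of taxa.
* Higher-order (pairwise) locus jackknives are not implemented; the
  "incomplete ineffective overlap" phenomenon — instability visible only
  in some locus subsets — can be explored by exporting each replicate's
  network, but no summary statistic for it is invented here.
* The sufficiency formulas inherit their literature assumptions (random
  uniform coverage, no gene-tree conflict, binary trees); the package
  reports them for comparison, not endorsement.
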