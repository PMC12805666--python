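"""Permitted supertrees, terraces and decisiveness.

Given a set of rooted (induced) subtrees, the *permitted supertrees* are
the plenary rooted binary trees on the union leaf set that display every
subtree.  A parent tree plus a taxon coverage pattern induces one subtree
per locus; the permitted supertrees of those restrictions form the
*terrace* of the parent, and the coverage pattern is *decisive* for the
parent exactly when the terrace has size one.

Counting uses a recursive top-down decomposition: a rooted triplet ab|c
forces a and b onto the same side of the root of any subtree containing
all three leaves, so the root partition of a leaf subset X must keep each
connected component of the triplet graph on X intact.  Summing the product
of subproblem counts over all bipartitions of the components, with
memoization on leaf subsets, gives the exact count as a big integer; leaf
subsets internally free of triplets short-circuit to the closed form
(2m-3)!! for m leaves.  Polytomies in the inputs are soft: only the
triplets they actually resolve constrain the count, so all binary
resolutions are permitted.

Enumeration follows the same recursion and is capped (default 10^6
trees); beyond the cap only the exact count is reported and the strict
consensus is left unset.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Optional, Sequence, Set, Tuple

from .sufficiency import CoveragePattern
from .trees import PhyloTree, TreeError, double_factorial, restrict, strict_consensus

__all__ = [
    "TerraceResult",
    "permitted_supertrees",
    "terrace",
    "is_decisive",
    "DEFAULT_ENUM_CAP",
]

DEFAULT_ENUM_CAP = 10**6


@dataclass(frozen=True)
class TerraceResult:
    """Size (exact big integer), optionally the trees, and their consensus."""

    size: int
    trees: Optional[Tuple[PhyloTree, ...]]
    sc: Optional[PhyloTree]
    enumerated: bool

    @property
    def decisive(self) -> bool:
        return self.size == 1


def _triplet_index(subtrees: Sequence[PhyloTree]) -> Dict[frozenset, Set[str]]:
    """Map each unordered leaf pair to the witnesses c of triplets ab|c."""
    index: Dict[frozenset, Set[str]] = {}
    for t in subtrees:
        for cluster in t.clusters:
            out = t.leaves - cluster
            for a, b in combinations(sorted(cluster), 2):
                key = frozenset((a, b))
                if key in index:
                    index[key] |= out
                else:
                    index[key] = set(out)
    return index


def _components(X: FrozenSet[str], index) -> list:
    """Connected components of the triplet graph restricted to X."""
    leaves = sorted(X)
    parent = {lf: lf for lf in leaves}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in combinations(leaves, 2):
        wit = index.get(frozenset((a, b)))
        if wit and not wit.isdisjoint(X):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups: Dict[str, set] = {}
    for lf in leaves:
        groups.setdefault(find(lf), set()).add(lf)
    return [frozenset(g) for g in groups.values()]


def _count(X: FrozenSet[str], index, memo) -> int:
    if len(X) <= 2:
        return 1
    got = memo.get(X)
    if got is not None:
        return got
    comps = _components(X, index)
    if len(comps) == len(X):
        # no triplet constrains X: every rooted binary tree qualifies
        total = double_factorial(2 * len(X) - 3)
    elif len(comps) == 1:
        total = 0
    else:
        comps = sorted(comps, key=min)
        rest = comps[1:]
        total = 0
        for bits in range(2 ** len(rest) - 1):
            side_a = set(comps[0])
            side_b: set = set()
            for i, comp in enumerate(rest):
                (side_a if bits >> i & 1 else side_b).update(comp)
            total += _count(frozenset(side_a), index, memo) * _count(
                frozenset(side_b), index, memo
            )
    memo[X] = total
    return total


def _enumerate(X: FrozenSet[str], index, memo) -> list:
    """All cluster sets of rooted binary trees on X displaying the triplets."""
    if len(X) <= 2:
        return [frozenset()]
    got = memo.get(X)
    if got is not None:
        return got
    comps = sorted(_components(X, index), key=min)
    out = []
    if len(comps) >= 2:
        rest = comps[1:]
        for bits in range(2 ** len(rest) - 1):
            side_a = set(comps[0])
            side_b: set = set()
            for i, comp in enumerate(rest):
                (side_a if bits >> i & 1 else side_b).update(comp)
            fa, fb = frozenset(side_a), frozenset(side_b)
            extra = [c for c in (fa, fb) if len(c) >= 2]
            for ca in _enumerate(fa, index, memo):
                for cb in _enumerate(fb, index, memo):
                    out.append(ca | cb | frozenset(extra))
    memo[X] = out
    return out


def permitted_supertrees(
    subtrees: Sequence[PhyloTree], enum_cap: int = DEFAULT_ENUM_CAP
) -> TerraceResult:
    """Count (and enumerate up to the cap) the permitted plenary supertrees."""
    subtrees = list(subtrees)
    if not subtrees:
        raise TreeError("need at least one subtree")
    universe = frozenset().union(*(t.leaves for t in subtrees))
    if len(universe) < 3:
        raise TreeError("the union leaf set must have at least 3 taxa")
    index = _triplet_index(subtrees)
    size = _count(universe, index, {})
    if size == 0:
        return TerraceResult(size=0, trees=(), sc=None, enumerated=True)
    if size > enum_cap:
        return TerraceResult(size=size, trees=None, sc=None, enumerated=False)
    cluster_sets = _enumerate(universe, index, {})
    trees = tuple(
        sorted(
            (PhyloTree(universe, cs, validate=False) for cs in cluster_sets),
            key=lambda t: t.to_newick(),
        )
    )
    assert len(trees) == size
    sc = strict_consensus(trees)
    return TerraceResult(size=size, trees=trees, sc=sc, enumerated=True)


def terrace(
    parent: PhyloTree, pattern: CoveragePattern, enum_cap: int = DEFAULT_ENUM_CAP
) -> TerraceResult:
    """Terrace of a parent tree under a taxon coverage pattern.

    The subtrees are the restrictions of the parent to each locus's sampled
    taxa; polytomies in the parent are treated as soft.
    """
    if not pattern.loci:
        raise ValueError("empty coverage pattern")
    if not pattern.universe <= parent.leaves:
        extra = pattern.universe - parent.leaves
        raise TreeError(
            f"coverage universe not contained in the parent tree: {sorted(extra)}"
        )
    subtrees = [restrict(parent, pattern.sampled[l]) for l in pattern.loci]
    return permitted_supertrees(subtrees, enum_cap=enum_cap)


def is_decisive(parent: PhyloTree, pattern: CoveragePattern) -> bool:
    """True iff the parent is the unique supertree of its induced subtrees."""
    return terrace(parent, pattern, enum_cap=1).size == 1
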