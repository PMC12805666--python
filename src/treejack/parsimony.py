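"""Desk-scale MRP: Fitch scoring and exact most-parsimonious-tree search.

``fitch_length`` scores an MR matrix on a given rooted topology with the
two-state generalisation of Fitch's algorithm to multifurcating vertices
(majority-vote form, exact for any vertex degree); missing entries carry
the full state set and never add steps.

``search_mpts`` finds *all* binary rooted most-parsimonious trees for
small matrices, either by exhaustive enumeration or by branch and bound
over stepwise leaf addition (the score of a partial tree on the restricted
matrix is a lower bound for any completion).  The search keeps a
designated outgroup leaf as a child of the root, which fixes the rooting
without affecting parsimony scores; larger matrices should be exported to
NEXUS and analysed with external software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .matrix_rep import MRMatrix
from .trees import PhyloTree, TreeError, strict_consensus

__all__ = ["ParsimonyResult", "fitch_length", "search_mpts"]

DEFAULT_MAX_LEAVES = 11
EXHAUSTIVE_LIMIT = 9
_AUTO_EXHAUSTIVE = 8  # below this, plain enumeration beats the bound bookkeeping

# state-set encoding: {0} -> 1, {1} -> 2, {0,1} -> 3


def fitch_length(matrix: MRMatrix, tree: PhyloTree) -> int:
    """Parsimony steps of all matrix columns on the given rooted tree."""
    missing = set(matrix.taxa) - set(tree.leaves)
    if missing:
        raise TreeError(
            f"matrix taxa not on the tree: {', '.join(sorted(missing))}"
        )
    if matrix.n_columns == 0:
        return 0
    children = tree.children_map()
    leaf_masks = {}
    for lf in tree.leaves:
        if lf in set(matrix.taxa):
            row = [
                3 if s is None else (2 if s == 1 else 1)
                for s in matrix.row(lf)
            ]
        else:
            row = [3] * matrix.n_columns
        leaf_masks[lf] = np.array(row, dtype=np.uint8)

    steps = 0

    def visit(node: frozenset) -> np.ndarray:
        nonlocal steps
        if len(node) == 1:
            return leaf_masks[next(iter(node))]
        kid_masks = [visit(k) for k in children[node]]
        # Hartigan for two states: keep the majority states, one step per
        # child short of the maximum vote
        votes0 = sum((m & 1).astype(np.int32) for m in kid_masks)
        votes1 = sum(((m >> 1) & 1).astype(np.int32) for m in kid_masks)
        top = np.maximum(votes0, votes1)
        steps += int(np.sum(len(kid_masks) - top))
        out = ((votes0 == top).astype(np.uint8)) | (
            ((votes1 == top).astype(np.uint8)) << 1
        )
        return out

    visit(tree.leaves)
    return steps


@dataclass(frozen=True)
class ParsimonyResult:
    best_length: int
    mpts: Tuple[PhyloTree, ...]
    search_mode: str
    sc: PhyloTree


# --- search internals: trees as nested 2-tuples with string leaves --------


def _insertions(t, leaf):
    """Yield every tree obtained by inserting ``leaf`` on an edge of t."""
    yield (t, leaf)
    if isinstance(t, tuple):
        left, right = t
        for sub in _insertions(left, leaf):
            yield (sub, right)
        for sub in _insertions(right, leaf):
            yield (left, sub)


def _score(t, leaf_masks, m) -> int:
    """Vectorised binary Fitch over all columns of a nested-tuple tree."""
    steps = 0

    def visit(node):
        nonlocal steps
        if isinstance(node, str):
            return leaf_masks.get(node)
        a = visit(node[0])
        b = visit(node[1])
        if a is None:
            return b
        if b is None:
            return a
        inter = a & b
        empty = inter == 0
        steps += int(np.sum(empty))
        return np.where(empty, a | b, inter).astype(np.uint8)

    visit(t)
    return steps


def _clusters_of(t, acc) -> frozenset:
    if isinstance(t, str):
        return frozenset((t,))
    left = _clusters_of(t[0], acc)
    right = _clusters_of(t[1], acc)
    cl = left | right
    acc.append(cl)
    return cl


def _to_phylo(root_tuple) -> PhyloTree:
    acc: list = []
    leaves = _clusters_of(root_tuple, acc)
    return PhyloTree(leaves, acc, validate=False)


def search_mpts(
    matrix: MRMatrix,
    max_leaves: int = DEFAULT_MAX_LEAVES,
    outgroup: Optional[str] = None,
    mode: str = "auto",
) -> ParsimonyResult:
    """All binary rooted MPTs with the outgroup fixed as a child of the root.

    ``mode`` is ``auto``, ``exhaustive`` or ``branch-and-bound``; exhaustive
    search is limited to 9 taxa, branch and bound to ``max_leaves``.
    """
    taxa = sorted(matrix.taxa)
    n = len(taxa)
    if n < 3:
        raise TreeError("search needs at least 3 taxa")
    if n > max_leaves:
        raise TreeError(
            f"{n} taxa exceeds the desk-scale cap ({max_leaves}); "
            "export to NEXUS for external parsimony software"
        )
    if outgroup is None:
        outgroup = taxa[0]
    elif outgroup not in taxa:
        raise TreeError(f"outgroup not in matrix: {outgroup}")
    if mode == "auto":
        mode = "exhaustive" if n <= _AUTO_EXHAUSTIVE else "branch-and-bound"
    if mode == "exhaustive" and n > EXHAUSTIVE_LIMIT:
        raise TreeError(f"exhaustive search is limited to {EXHAUSTIVE_LIMIT} taxa")
    if mode not in ("exhaustive", "branch-and-bound"):
        raise ValueError(f"unknown search mode: {mode}")

    m = matrix.n_columns
    leaf_masks = {}
    for t in taxa:
        row = [3 if s is None else (2 if s == 1 else 1) for s in matrix.row(t)]
        leaf_masks[t] = np.array(row, dtype=np.uint8)

    ingroup = [t for t in taxa if t != outgroup]
    # addition order: most completely scored taxa first, for tighter bounds
    ingroup.sort(key=lambda t: (-len(matrix.scored_columns(t)), t))

    best = None
    best_trees: list = []

    def full_score(inner) -> int:
        return _score((outgroup, inner), leaf_masks, m)

    if mode == "exhaustive":
        trees = [ingroup[0]]
        for leaf in ingroup[1:]:
            trees = [t2 for t1 in trees for t2 in _insertions(t1, leaf)]
        for inner in trees:
            s = full_score(inner)
            if best is None or s < best:
                best, best_trees = s, [inner]
            elif s == best:
                best_trees.append(inner)
    else:

        def grow(inner, remaining):
            nonlocal best, best_trees
            s = full_score(inner)
            if best is not None and s > best:
                return
            if not remaining:
                if best is None or s < best:
                    best, best_trees = s, [inner]
                elif s == best:
                    best_trees.append(inner)
                return
            leaf, rest = remaining[0], remaining[1:]
            for t2 in _insertions(inner, leaf):
                grow(t2, rest)

        grow(ingroup[0], ingroup[1:])

    mpts = tuple(
        sorted(
            (_to_phylo((best_trees_i, outgroup)) for best_trees_i in best_trees),
            key=lambda t: t.to_newick(),
        )
    )
    return ParsimonyResult(
        best_length=int(best),
        mpts=mpts,
        search_mode=mode,
        sc=strict_consensus(mpts),
    )
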