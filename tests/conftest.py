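"""Shared fixtures and independent brute-force oracles.

The enumeration helpers here are deliberately written as stepwise-insertion
generators over nested tuples -- a different algorithm from the library's
bipartition recursion -- so they can serve as independent oracles for
terrace counting, consistency counting (CIC) and parsimony search.
"""

from __future__ import annotations

import itertools

import pytest

from treejack.trees import PhyloTree


def _tuple_insertions(t, leaf):
    yield (t, leaf)
    if isinstance(t, tuple):
        left, right = t
        for sub in _tuple_insertions(left, leaf):
            yield (sub, right)
        for sub in _tuple_insertions(right, leaf):
            yield (left, sub)


def _tuple_clusters(t, acc):
    if isinstance(t, str):
        return frozenset((t,))
    cl = _tuple_clusters(t[0], acc) | _tuple_clusters(t[1], acc)
    acc.append(cl)
    return cl


def iter_rooted_binary(leaves):
    """Every rooted binary tree on ``leaves``, by stepwise leaf insertion."""
    leaves = sorted(leaves)
    if len(leaves) == 1:
        yield PhyloTree(leaves)
        return
    shapes = [(leaves[0], leaves[1])]
    for leaf in leaves[2:]:
        shapes = [s2 for s1 in shapes for s2 in _tuple_insertions(s1, leaf)]
    for shape in shapes:
        acc = []
        universe = _tuple_clusters(shape, acc)
        yield PhyloTree(universe, acc, validate=False)


def unrooted_splits(tree: PhyloTree) -> frozenset:
    """Non-trivial splits of the unrooted form, as the side without the
    alphabetically first leaf."""
    ref = min(tree.leaves)
    n = tree.n_leaves
    out = set()
    for c in tree.clusters:
        side = tree.leaves - c if ref in c else c
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return frozenset(out)


def iter_unrooted_binary(leaves):
    """Every unrooted binary tree on ``leaves`` as a frozenset of splits.

    Realised as rooted binary trees on all leaves but the first, with the
    first leaf joined at the root: each unrooted shape arises exactly once.
    """
    leaves = sorted(leaves)
    first, rest = leaves[0], leaves[1:]
    for sub in iter_rooted_binary(rest):
        full = PhyloTree(leaves, set(sub.clusters) | {frozenset(rest)}, validate=False)
        yield unrooted_splits(full)


def brute_force_min_steps(tree: PhyloTree, states: dict) -> int:
    """Exact parsimony steps of one binary character by enumerating all
    internal-vertex state assignments (oracle for Fitch/Hartigan scoring).

    ``states`` maps leaf -> 0, 1 or None (missing, free to take any state).
    """
    children = tree.children_map()
    internal = [tree.leaves] + sorted(tree.clusters, key=len, reverse=True)
    free_leaves = [l for l in tree.leaves if states.get(l) is None]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internal) + len(free_leaves)):
        label = dict(zip((tuple(sorted(v)) for v in internal), assign))
        for l, s in zip(free_leaves, assign[len(internal):]):
            label[(l,)] = s
        for l in tree.leaves:
            if states.get(l) is not None:
                label[(l,)] = states[l]
        steps = 0
        for node in internal:
            key = tuple(sorted(node))
            for kid in children[node]:
                if label[key] != label[tuple(sorted(kid))]:
                    steps += 1
        if best is None or steps < best:
            best = steps
    return best


@pytest.fixture
def quartet():
    from treejack.trees import parse_newick

    return parse_newick("(((A,B),C),D);")
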