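"""Rooted leaf-labelled trees and their summary statistics.

A :class:`PhyloTree` is stored as a leaf set plus the set of *proper,
non-trivial clusters* (clades in the rooted sense): every internal vertex
other than the root corresponds to one cluster with at least two leaves.
This representation makes restriction, display testing, consensus and
grafting pure set operations, collapses degree-2 vertices automatically,
and is independent of child order and branch lengths.

Two tree-shape statistics are provided:

* ``resolution`` -- the normalised consensus fork rho, the fraction of the
  n-1 possible internal vertices (rooted sense, root included) that are
  realised.  rho = 1 exactly for fully binary rooted trees.
* ``cic`` -- cladistic information content in bits, computed on the
  unrooted form of the tree: log2 of the number of unrooted binary trees
  on n leaves minus log2 of the number of such trees consistent with the
  given (possibly polytomous) tree, using exact big-integer double
  factorials.  The star tree scores 0.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "TreeError",
    "NewickError",
    "PhyloTree",
    "TreeStats",
    "parse_newick",
    "parse_newick_list",
    "read_newick",
    "read_newick_dir",
    "write_newick",
    "restrict",
    "displays",
    "strict_consensus",
    "graft",
    "nearest_sampled_relative",
    "resolution",
    "cic",
    "double_factorial",
    "n_unrooted_binary",
    "stats",
]


class TreeError(ValueError):
    """Invalid tree, leaf set, or tree operation."""


class NewickError(TreeError):
    """Malformed Newick input."""


def double_factorial(k: int) -> int:
    """Exact k!! for odd k >= -1 (big integer)."""
    if k < -1:
        raise ValueError(f"double factorial undefined for k={k}")
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def n_unrooted_binary(n: int) -> int:
    """Number of unrooted binary trees on n >= 3 labelled leaves: (2n-5)!!."""
    if n < 3:
        raise ValueError("need at least 3 leaves")
    return double_factorial(2 * n - 5)


class PhyloTree:
    """Immutable rooted tree identified by its leaf set and cluster set.

    Parameters
    ----------
    leaves:
        Iterable of unique, non-empty taxon labels.
    clusters:
        Iterable of leaf subsets, one per non-root internal vertex.  Trivial
        clusters (singletons, the full leaf set) are dropped silently, so a
        degree-2 vertex can never be represented.
    validate:
        When true (default), check that clusters are pairwise nested or
        disjoint, i.e. that they jointly describe a tree.
    """

    __slots__ = ("_leaves", "_clusters")

    def __init__(
        self,
        leaves: Iterable[str],
        clusters: Iterable[Iterable[str]] = (),
        *,
        validate: bool = True,
    ) -> None:
        leafset = frozenset(leaves)
        if not leafset:
            raise TreeError("a tree needs at least one leaf")
        for lf in leafset:
            if not isinstance(lf, str) or not lf:
                raise TreeError(f"leaf labels must be non-empty strings, got {lf!r}")
        n = len(leafset)
        cl = set()
        for c in clusters:
            cf = frozenset(c)
            if not cf <= leafset:
                raise TreeError(
                    f"cluster {sorted(cf)} contains labels not in the leaf set"
                )
            if 2 <= len(cf) < n:
                cl.add(cf)
        clset = frozenset(cl)
        if validate:
            ordered = sorted(clset, key=len)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1 :]:
                    inter = a & b
                    if inter and inter != a:
                        raise TreeError(
                            f"clusters {sorted(a)} and {sorted(b)} overlap without nesting"
                        )
        object.__setattr__(self, "_leaves", leafset)
        object.__setattr__(self, "_clusters", clset)

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("PhyloTree is immutable")

    @property
    def leaves(self) -> frozenset:
        return self._leaves

    @property
    def clusters(self) -> frozenset:
        """Proper non-trivial clusters (root and singletons excluded)."""
        return self._clusters

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def n_internal(self) -> int:
        """Internal vertex count in the rooted sense, root included."""
        return len(self._clusters) + 1

    def is_binary(self) -> bool:
        return len(self._clusters) == self.n_leaves - 2

    def children_map(self) -> dict:
        """Hierarchy as ``{vertex: [children]}`` with vertices as frozensets.

        The root is ``self.leaves``; leaves appear as singleton frozensets.
        """
        universe = self._leaves
        nodes = sorted(self._clusters, key=len, reverse=True)
        children: dict = {universe: []}
        parent_of: dict = {}
        for c in nodes:
            parent = universe
            # nodes are visited largest-first, so the last strict superset
            # seen is the immediate parent
            for cand in nodes:
                if len(cand) <= len(c):
                    break
                if c < cand and len(cand) < len(parent):
                    parent = cand
            parent_of[c] = parent
            children[c] = []
        for c in nodes:
            children[parent_of[c]].append(c)
        for lf in universe:
            single = frozenset((lf,))
            parent = universe
            for cand in nodes:
                if lf in cand and len(cand) < len(parent):
                    parent = cand
            children[parent].append(single)
        return children

    def to_newick(self) -> str:
        """Deterministic Newick string (children sorted by smallest label)."""
        children = self.children_map()

        def fmt(node: frozenset) -> str:
            if len(node) == 1:
                return _quote_label(next(iter(node)))
            kids = sorted(children[node], key=min)
            return "(" + ",".join(fmt(k) for k in kids) + ")"

        return fmt(self._leaves) + ";"

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self._leaves == other._leaves and self._clusters == other._clusters

    def __hash__(self) -> int:
        return hash((self._leaves, self._clusters))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PhyloTree({self.to_newick()!r})"


_LABEL_NEEDS_QUOTES = re.compile(r"[\s()\[\]{}/\\,;:=*'\"`+<>~]")


def _quote_label(label: str) -> str:
    if _LABEL_NEEDS_QUOTES.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _tree_from_dendropy(dtree: "dendropy.Tree") -> PhyloTree:
    labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
    seen, dups = set(), set()
    for lab in labels:
        if lab in seen:
            dups.add(lab)
        seen.add(lab)
    if dups:
        raise NewickError(f"duplicate leaf label(s): {', '.join(sorted(dups))}")
    clusters = []
    for node in dtree.preorder_internal_node_iter():
        clusters.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    return PhyloTree(labels, clusters, validate=False)


def _find_duplicate_label(text: str) -> str | None:
    # best-effort scan for the offending label, for the error message only;
    # dendropy has already rejected the string as containing duplicates
    tokens = re.findall(r"'(?:[^']|'')*'|[^\s()\[\],;:]+", text)
    seen: set = set()
    for tok in tokens:
        if tok.startswith("'"):
            tok = tok[1:-1].replace("''", "'")
        label = tok.split(":")[0]
        if not label or label.replace(".", "").replace("-", "").isdigit():
            continue
        if label in seen:
            return label
        seen.add(label)
    return None


def _parse_one(text: str) -> "dendropy.Tree":
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "Multiple occurrences" in msg or "uplicate" in msg:
            dup = _find_duplicate_label(text)
            raise NewickError(
                f"duplicate leaf label: {dup}" if dup else f"duplicate leaf label ({msg})"
            ) from exc
        raise NewickError(f"malformed Newick: {msg}") from exc


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick string into a :class:`PhyloTree`.

    Quoted labels are unquoted, ``[...]`` comments skipped, branch lengths
    accepted but discarded, and degree-2 internal vertices suppressed.
    """
    return _tree_from_dendropy(_parse_one(text))


def parse_newick_list(text: str) -> list:
    """Parse a multi-tree Newick document (one tree per statement)."""
    try:
        tlist = dendropy.TreeList.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise NewickError(f"malformed Newick: {exc}") from exc
    out = []
    for dtree in tlist:
        out.append(_tree_from_dendropy(dtree))
    return out


def read_newick(path) -> list:
    """Read one or more trees from a Newick file."""
    return parse_newick_list(Path(path).read_text())


def read_newick_dir(directory, pattern: str = "*.nwk") -> dict:
    """Read one tree per file from a directory; locus label = file stem.

    Files matching ``*.nwk``, ``*.tre``, ``*.newick`` and ``*.tree`` are
    accepted when the default pattern finds nothing.
    """
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        for alt in ("*.tre", "*.newick", "*.tree", "*.txt"):
            paths = sorted(directory.glob(alt))
            if paths:
                break
    trees = {}
    for p in paths:
        parsed = read_newick(p)
        if len(parsed) != 1:
            raise NewickError(f"{p}: expected exactly one tree, found {len(parsed)}")
        trees[p.stem] = parsed[0]
    return trees


def write_newick(trees, path) -> None:
    """Write a tree, list of trees, or ``{label: tree}`` map, one per line."""
    if isinstance(trees, PhyloTree):
        trees = [trees]
    if isinstance(trees, Mapping):
        trees = list(trees.values())
    Path(path).write_text("".join(t.to_newick() + "\n" for t in trees))


def restrict(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Induced subtree on ``keep`` with degree-2 vertices suppressed."""
    keep = frozenset(keep)
    if not keep:
        raise TreeError("cannot restrict to an empty leaf set")
    extra = keep - tree.leaves
    if extra:
        raise TreeError(f"labels not in tree: {', '.join(sorted(extra))}")
    m = len(keep)
    clusters = {c & keep for c in tree.clusters}
    clusters = {c for c in clusters if 2 <= len(c) < m}
    return PhyloTree(keep, clusters, validate=False)


def displays(supertree: PhyloTree, subtree: PhyloTree) -> bool:
    """True iff the supertree restricted to the subtree's leaves refines it."""
    if not subtree.leaves <= supertree.leaves:
        missing = subtree.leaves - supertree.leaves
        raise TreeError(
            f"subtree leaves missing from supertree: {', '.join(sorted(missing))}"
        )
    restriction = restrict(supertree, subtree.leaves)
    return subtree.clusters <= restriction.clusters


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the clusters shared by every input tree."""
    trees = list(trees)
    if not trees:
        raise TreeError("strict consensus of an empty tree list")
    leaves = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leaves:
            diff = t.leaves ^ leaves
            raise TreeError(
                f"leaf sets differ (symmetric difference: {', '.join(sorted(diff))})"
            )
    common = frozenset.intersection(*(t.clusters for t in trees))
    return PhyloTree(leaves, common, validate=False)


def graft(tree: PhyloTree, new_leaf: str, sister: str) -> PhyloTree:
    """Attach ``new_leaf`` as sister to the leaf ``sister`` (a new cherry)."""
    if new_leaf in tree.leaves:
        raise TreeError(f"leaf already present: {new_leaf}")
    if sister not in tree.leaves:
        raise TreeError(f"sister leaf not in tree: {sister}")
    clusters = {c | {new_leaf} if sister in c else c for c in tree.clusters}
    clusters.add(frozenset((sister, new_leaf)))
    return PhyloTree(tree.leaves | {new_leaf}, clusters, validate=False)


def nearest_sampled_relative(
    reference: PhyloTree, target: str, sampled: Iterable[str]
) -> str:
    """Closest leaf to ``target`` among ``sampled``, per the reference tree.

    The reference is restricted to ``sampled + {target}``; the sister group
    of ``target`` in that restriction is found, and its alphabetically first
    leaf returned (the tie-break for multi-leaf sister groups).
    """
    sampled = frozenset(sampled)
    if target not in reference.leaves:
        raise TreeError(f"target not in reference tree: {target}")
    if target in sampled:
        raise TreeError("target must not be in the sampled set")
    if not sampled:
        raise TreeError("sampled set is empty")
    extra = sampled - reference.leaves
    if extra:
        raise TreeError(f"sampled labels not in reference: {', '.join(sorted(extra))}")
    r = restrict(reference, sampled | {target})
    parent = r.leaves
    for c in r.clusters:
        if target in c and len(c) < len(parent):
            parent = c
    sister_group = parent - {target}
    return min(sister_group)


def resolution(tree: PhyloTree) -> float:
    """Normalised consensus fork rho = internal vertices / (n - 1), rooted."""
    n = tree.n_leaves
    if n < 3:
        raise TreeError("resolution needs at least 3 leaves")
    return tree.n_internal / (n - 1)


def cic(tree: PhyloTree) -> float:
    """Cladistic information content in bits, on the unrooted form.

    cic = log2 B(n) - log2 R(T) with B(n) = (2n-5)!! the number of unrooted
    binary trees and R(T) = prod over internal vertices v of (2 deg(v)-5)!!
    the number of those consistent with T (deg = unrooted vertex degree).
    """
    n = tree.n_leaves
    if n < 3:
        raise TreeError("cic needs at least 3 leaves")
    children = tree.children_map()
    root_kids = children[tree.leaves]
    consistent = 1
    if len(root_kids) == 2:
        # root is suppressed when unrooted; its two children join directly,
        # leaving their degrees unchanged
        internal_degrees = [len(children[c]) + 1 for c in tree.clusters]
    else:
        internal_degrees = [len(root_kids)]
        internal_degrees += [len(children[c]) + 1 for c in tree.clusters]
    for deg in internal_degrees:
        consistent *= double_factorial(2 * deg - 5)
    return math.log2(n_unrooted_binary(n)) - math.log2(consistent)


@dataclass(frozen=True)
class TreeStats:
    """Resolution and information content of one tree."""

    n_leaves: int
    rho: float
    cic_bits: float


def stats(tree: PhyloTree) -> TreeStats:
    return TreeStats(n_leaves=tree.n_leaves, rho=resolution(tree), cic_bits=cic(tree))
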