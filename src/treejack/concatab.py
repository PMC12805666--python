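"""Concatabominations on a matrix representation.

A *concatabomination* (chimera) merges the non-conflicting character data
of two leaves, which is analogous to forcing them together on a tree.  If
replacing the two rows by their chimera introduces no new pairwise
character incompatibility, there is "no cost" to the merge and the pair
are potential taxonomic equivalents.  Leaves participating in many such
no-cost merges -- especially of the D type, where the two leaves share no
scored characters at all -- can occupy many positions on equally optimal
trees and are flagged as candidate rogues.

Edges are typed by the relation between the two rows' scored column sets:

====  =========================================================
A     both rows complete (scored in every column)
C     identical incomplete scored sets
B     one scored set a proper subset of the other (asymmetric)
D     disjoint scored sets
E     partial overlap, each side with unique scored columns
====  =========================================================

The per-taxon instability score is the number of D-type edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import networkx as nx
import numpy as np

from .compatibility import _combo_counts, _incompatible_mask, incompatibilities
from .matrix_rep import MRMatrix

__all__ = [
    "Chimera",
    "ConcatNetwork",
    "build_chimera",
    "no_cost",
    "categorize",
    "build_network",
    "edge_count",
    "write_sif",
    "write_graphml",
    "write_edge_tsv",
    "summary_json",
]

SYMMETRIC_CATEGORIES = frozenset("ACDE")


@dataclass(frozen=True)
class Chimera:
    """Combined row of two leaves with non-conflicting data."""

    member_x: str
    member_y: str
    states: Tuple[Optional[int], ...]


def build_chimera(matrix: MRMatrix, x: str, y: str) -> Optional[Chimera]:
    """Combined row of ``x`` and ``y``; None when any shared column conflicts."""
    if x == y:
        raise ValueError("a chimera needs two distinct taxa")
    for t in (x, y):
        if t not in matrix.taxa:
            raise KeyError(f"unknown taxon: {t}")
    states = []
    for col in matrix.columns:
        sx, sy = col.state(x), col.state(y)
        if sx is not None and sy is not None and sx != sy:
            return None
        states.append(sx if sx is not None else sy)
    return Chimera(member_x=x, member_y=y, states=tuple(states))


def no_cost(matrix: MRMatrix, x: str, y: str) -> bool:
    """True iff merging ``x`` and ``y`` adds no new incompatible column pair.

    The chimera *replaces* both member rows, and the criterion is set
    inclusion: every incompatible pair of the modified matrix must already
    be incompatible in the original.  Pairs conflicting on a shared column
    are defined to have cost.
    """
    chim = build_chimera(matrix, x, y)
    if chim is None:
        return False
    baseline = incompatibilities(matrix)
    ones, zeros = matrix.to_arrays()
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    new_pairs = _new_incompatibilities(
        ones, zeros, idx[x], idx[y], chim.states, baseline_mask=None
    )
    return all(p in baseline.pairs for p in new_pairs)


def _chimera_indicators(states):
    s1 = np.fromiter((1 if s == 1 else 0 for s in states), dtype=np.int32)
    s0 = np.fromiter((1 if s == 0 else 0 for s in states), dtype=np.int32)
    return s1, s0


def _new_incompatibilities(ones, zeros, ix, iy, states, baseline_mask):
    """Incompatible pairs of the row-replaced matrix, as (i, j) tuples.

    Uses the rank-two update: combination counts are sums of per-taxon
    outer products, so removing rows ix, iy and adding the chimera row
    adjusts each count matrix by three outer products.
    """
    o = ones.astype(np.int32)
    z = zeros.astype(np.int32)
    c11, c10, c01, c00 = _combo_counts(ones, zeros)
    ox, zx = o[:, ix], z[:, ix]
    oy, zy = o[:, iy], z[:, iy]
    s1, s0 = _chimera_indicators(states)
    c11 = c11 - np.outer(ox, ox) - np.outer(oy, oy) + np.outer(s1, s1)
    c10 = c10 - np.outer(ox, zx) - np.outer(oy, zy) + np.outer(s1, s0)
    c01 = c01 - np.outer(zx, ox) - np.outer(zy, oy) + np.outer(s0, s1)
    c00 = c00 - np.outer(zx, zx) - np.outer(zy, zy) + np.outer(s0, s0)
    mask = _incompatible_mask(c11, c10, c01, c00)
    if baseline_mask is not None:
        mask = mask & ~baseline_mask
    iu = np.triu_indices(mask.shape[0], k=1)
    sel = mask[iu]
    return [(int(i), int(j)) for i, j, b in zip(iu[0], iu[1], sel) if b]


def categorize(matrix: MRMatrix, x: str, y: str) -> str:
    """Equivalence category A-E from the two rows' scored column sets."""
    if build_chimera(matrix, x, y) is None:
        raise ValueError(f"conflicting pair has no category: {x}, {y}")
    sx = matrix.scored_columns(x)
    sy = matrix.scored_columns(y)
    return _category(sx, sy, matrix.n_columns)


def _category(sx: frozenset, sy: frozenset, n_columns: int) -> str:
    full = len(sx) == n_columns and len(sy) == n_columns
    if sx == sy:
        return "A" if full else "C"
    if sx < sy or sy < sx:
        return "B"
    if not sx & sy:
        return "D"
    return "E"


@dataclass(frozen=True)
class ConcatNetwork:
    """Concatabomination network: taxa as nodes, no-cost merges as edges.

    Self-loops are structurally impossible (pairs are unordered and
    distinct).  Connected components are classified as singletons (isolated
    nodes), dyads (two nodes, one edge) and clusters (three or more nodes).
    """

    graph: nx.Graph

    @property
    def nodes(self) -> tuple:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> tuple:
        return tuple(
            sorted((min(u, v), max(u, v), d["category"]) for u, v, d in self.graph.edges(data=True))
        )

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, taxon: str) -> int:
        return self.graph.degree[taxon]

    def d_degree(self, taxon: str) -> int:
        """Instability score: number of D-type edges at the taxon."""
        return sum(
            1 for _, _, d in self.graph.edges(taxon, data=True) if d["category"] == "D"
        )

    @property
    def components(self) -> dict:
        singles, dyads, clusters = [], [], []
        for comp in nx.connected_components(self.graph):
            comp = tuple(sorted(comp))
            if len(comp) == 1:
                singles.append(comp[0])
            elif len(comp) == 2:
                dyads.append(comp)
            else:
                clusters.append(comp)
        return {
            "singletons": sorted(singles),
            "dyads": sorted(dyads),
            "clusters": sorted(clusters),
        }

    def summary(self) -> dict:
        comp = self.components
        return {
            "singletons": len(comp["singletons"]),
            "dyads": len(comp["dyads"]),
            "clusters": len(comp["clusters"]),
            "edge_count": self.edge_count,
        }


def build_network(matrix: MRMatrix) -> ConcatNetwork:
    """Concatabomination network over all unordered taxon pairs.

    An edge joins every non-conflicting pair whose chimera adds no new
    incompatible column pair; conflicting pairs are silently non-edges.
    """
    taxa = list(matrix.taxa)
    if len(taxa) < 2:
        raise ValueError("a network needs at least 2 taxa")
    g = nx.Graph()
    g.add_nodes_from(taxa)
    m = matrix.n_columns
    if m == 0:
        for t in taxa:
            g.nodes[t]["degree"] = 0
            g.nodes[t]["d_degree"] = 0
        return ConcatNetwork(graph=g)

    ones, zeros = matrix.to_arrays()
    o = ones.astype(np.int32)
    z = zeros.astype(np.int32)
    c11, c10, c01, c00 = _combo_counts(ones, zeros)
    baseline_mask = _incompatible_mask(c11, c10, c01, c00)
    scored = {t: matrix.scored_columns(t) for t in taxa}
    iu = np.triu_indices(m, k=1)

    for a in range(len(taxa)):
        oa, za = o[:, a], z[:, a]
        for b in range(a + 1, len(taxa)):
            ob, zb = o[:, b], z[:, b]
            # conflict: some column scores both taxa with different states
            if np.any(oa & zb) or np.any(za & ob):
                continue
            s1 = oa | ob
            s0 = za | zb
            n11 = c11 - np.outer(oa, oa) - np.outer(ob, ob) + np.outer(s1, s1)
            n10 = c10 - np.outer(oa, za) - np.outer(ob, zb) + np.outer(s1, s0)
            n01 = c01 - np.outer(za, oa) - np.outer(zb, ob) + np.outer(s0, s1)
            n00 = c00 - np.outer(za, za) - np.outer(zb, zb) + np.outer(s0, s0)
            new_mask = _incompatible_mask(n11, n10, n01, n00) & ~baseline_mask
            if new_mask[iu].any():
                continue
            x, y = taxa[a], taxa[b]
            g.add_edge(x, y, category=_category(scored[x], scored[y], m))

    for t in taxa:
        g.nodes[t]["degree"] = g.degree[t]
        g.nodes[t]["d_degree"] = sum(
            1 for _, _, d in g.edges(t, data=True) if d["category"] == "D"
        )
    return ConcatNetwork(graph=g)


def edge_count(network: ConcatNetwork) -> int:
    """Number of edges (self-loops are structurally impossible)."""
    return network.edge_count


# ---------------------------------------------------------------------------
# exports (Cytoscape-friendly)


def write_sif(network: ConcatNetwork, path) -> None:
    """SIF: ``taxon  category  taxon`` per edge; isolated nodes on own lines."""
    lines = [f"{u}\t{cat}\t{v}" for u, v, cat in network.edges]
    connected = {u for u, v, _ in network.edges} | {v for _, v, _ in network.edges}
    lines += [t for t in network.nodes if t not in connected]
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(network: ConcatNetwork, path) -> None:
    nx.write_graphml(network.graph, str(path))


def write_edge_tsv(network: ConcatNetwork, path) -> None:
    lines = ["taxon_a\tcategory\ttaxon_b"]
    lines += [f"{u}\t{cat}\t{v}" for u, v, cat in network.edges]
    Path(path).write_text("\n".join(lines) + "\n")


def summary_json(network: ConcatNetwork, path=None) -> str:
    text = json.dumps(network.summary(), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
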