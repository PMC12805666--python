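"""Pairwise compatibility of binary characters with missing data.

Two binary characters are compatible exactly when, among the taxa scored
in both, fewer than all four state combinations {00, 01, 10, 11} occur
(the four-gamete condition); this is equivalent to the existence of a tree
on which both characters evolve without homoplasy.  Missing entries simply
do not contribute combinations, so masking entries can never make a
compatible pair incompatible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Tuple

import numpy as np

from .matrix_rep import MRColumn, MRMatrix

__all__ = ["IncompatibilitySet", "pair_compatible", "incompatibilities", "write_pairs_tsv"]


@dataclass(frozen=True)
class IncompatibilitySet:
    """Unordered column-index pairs that fail the four-gamete test."""

    pairs: FrozenSet[Tuple[int, int]]

    @property
    def count(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs


def pair_compatible(col_a: MRColumn, col_b: MRColumn) -> bool:
    """Four-gamete test on the taxa scored in both columns."""
    shared = col_a.source_leaves & col_b.source_leaves
    combos = set()
    for t in shared:
        combos.add((t in col_a.cluster, t in col_b.cluster))
        if len(combos) == 4:
            return False
    return True


def _combo_counts(ones: np.ndarray, zeros: np.ndarray):
    """Taxon-summed combination counts between all column pairs.

    Returns the four m x m integer matrices C11, C10, C01, C00 where
    C11[i, j] counts taxa scored 1 in column i and 1 in column j, etc.
    Each is a sum of per-taxon outer products, which is what makes the
    chimera row-replacement in the concatabomination test a cheap rank-two
    update (see :mod:`treejack.concatab`).
    """
    o = ones.astype(np.int32)
    z = zeros.astype(np.int32)
    return o @ o.T, o @ z.T, z @ o.T, z @ z.T


def _incompatible_mask(c11, c10, c01, c00) -> np.ndarray:
    return (c11 > 0) & (c10 > 0) & (c01 > 0) & (c00 > 0)


def incompatibilities(matrix: MRMatrix) -> IncompatibilitySet:
    """All unordered incompatible column pairs of the matrix."""
    m = matrix.n_columns
    if m < 2:
        return IncompatibilitySet(frozenset())
    ones, zeros = matrix.to_arrays()
    mask = _incompatible_mask(*_combo_counts(ones, zeros))
    iu = np.triu_indices(m, k=1)
    bad = mask[iu]
    pairs = frozenset(
        (int(i), int(j)) for i, j, b in zip(iu[0], iu[1], bad) if b
    )
    return IncompatibilitySet(pairs)


def write_pairs_tsv(matrix: MRMatrix, inc: IncompatibilitySet, path) -> None:
    """Dump incompatible pairs with locus provenance."""
    lines = ["col_i\tlocus_i\tcol_j\tlocus_j"]
    for i, j in sorted(inc.pairs):
        lines.append(
            f"{i}\t{matrix.columns[i].locus}\t{j}\t{matrix.columns[j].locus}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
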