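"""Baum-Ragan matrix representation (MR) of trees.

Each non-trivial cluster of a rooted gene tree becomes one binary
character: members of the cluster are scored 1, the other leaves of that
tree 0, and taxa absent from the tree ``?``.  Concatenating the per-locus
matrices yields the input for parsimony supertree construction (MRP) and
for the concatabomination analyses.

The matrix is exported as NEXUS (for external parsimony programs such as
PAUP*), relaxed PHYLIP, or TSV; NEXUS and TSV round-trip losslessly
because a column's cluster is exactly its set of 1-scored taxa and its
source leaf set exactly its set of non-missing taxa.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .trees import PhyloTree, TreeError

__all__ = [
    "MRColumn",
    "MRMatrix",
    "encode_tree",
    "concatenate",
    "drop_locus",
    "write_nexus",
    "read_nexus",
    "write_tsv",
    "read_tsv",
    "write_phylip",
]

log = logging.getLogger(__name__)

MISSING = "?"


@dataclass(frozen=True)
class MRColumn:
    """One binary character: the cluster that received state 1.

    ``state(t)`` is 1 for cluster members, 0 for other leaves of the source
    tree, and None (missing) for taxa outside the source tree.
    """

    locus: str
    cluster: frozenset
    source_leaves: frozenset

    def __post_init__(self):
        if not self.cluster <= self.source_leaves:
            raise ValueError("cluster must be a subset of the source leaves")
        if len(self.cluster) < 1 or len(self.source_leaves - self.cluster) < 1:
            raise ValueError("column must score at least one 1 and one 0")

    def state(self, taxon: str) -> Optional[int]:
        if taxon not in self.source_leaves:
            return None
        return 1 if taxon in self.cluster else 0

    def symbol(self, taxon: str) -> str:
        s = self.state(taxon)
        return MISSING if s is None else str(s)


@dataclass(frozen=True)
class MRMatrix:
    """Taxa x binary characters matrix with missing entries."""

    taxa: tuple
    columns: tuple = field(default_factory=tuple)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def loci(self) -> tuple:
        """Locus labels in first-appearance order."""
        seen, out = set(), []
        for col in self.columns:
            if col.locus not in seen:
                seen.add(col.locus)
                out.append(col.locus)
        return tuple(out)

    def row(self, taxon: str) -> tuple:
        if taxon not in self.taxa:
            raise KeyError(taxon)
        return tuple(col.state(taxon) for col in self.columns)

    @property
    def uncovered_taxa(self) -> tuple:
        """Taxa whose rows are entirely missing (retained but flagged)."""
        return tuple(
            t
            for t in self.taxa
            if all(t not in col.source_leaves for col in self.columns)
        )

    def scored_columns(self, taxon: str) -> frozenset:
        """Indices of columns in which ``taxon`` is scored (non-missing)."""
        return frozenset(
            j for j, col in enumerate(self.columns) if taxon in col.source_leaves
        )

    def to_arrays(self):
        """(ones, zeros) uint8 arrays of shape (n_columns, n_taxa)."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        m, n = self.n_columns, self.n_taxa
        ones = np.zeros((m, n), dtype=np.uint8)
        zeros = np.zeros((m, n), dtype=np.uint8)
        for j, col in enumerate(self.columns):
            for t in col.cluster:
                if t in idx:
                    ones[j, idx[t]] = 1
            for t in col.source_leaves - col.cluster:
                if t in idx:
                    zeros[j, idx[t]] = 1
        return ones, zeros


def encode_tree(tree: PhyloTree, universe: Iterable[str], locus: str) -> MRMatrix:
    """Standard MR coding of one rooted tree over a taxon universe.

    One column per non-trivial cluster; the root cluster and singletons are
    excluded.  Trees contributing no cluster yield an empty matrix.
    """
    universe = frozenset(universe)
    if not tree.leaves <= universe:
        extra = tree.leaves - universe
        raise TreeError(f"tree leaves outside the universe: {', '.join(sorted(extra))}")
    taxa = tuple(sorted(universe))
    clusters = sorted(tree.clusters, key=lambda c: (len(c), sorted(c)))
    if not clusters:
        log.info("locus %s: tree has no non-trivial cluster; empty MR", locus)
        return MRMatrix(taxa=taxa, columns=())
    cols = tuple(
        MRColumn(locus=locus, cluster=c, source_leaves=tree.leaves) for c in clusters
    )
    return MRMatrix(taxa=taxa, columns=cols)


def concatenate(matrices: Sequence[MRMatrix]) -> MRMatrix:
    """Concatenate per-locus MRs: union of taxa, columns appended in order."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("concatenate() needs at least one matrix")
    taxa = sorted(set().union(*(set(m.taxa) for m in matrices)))
    cols = tuple(col for m in matrices for col in m.columns)
    out = MRMatrix(taxa=tuple(taxa), columns=cols)
    if out.uncovered_taxa:
        log.info("concatenated MR has all-missing rows: %s", ", ".join(out.uncovered_taxa))
    return out


def drop_locus(matrix: MRMatrix, locus: str):
    """Remove all columns of one locus.

    Taxa whose rows become entirely missing are removed from the matrix and
    reported.  Returns ``(reduced_matrix, dropped_taxa)``.
    """
    if locus not in matrix.loci:
        raise KeyError(f"locus not present in matrix: {locus}")
    cols = tuple(c for c in matrix.columns if c.locus != locus)
    covered = set().union(*(c.source_leaves for c in cols)) if cols else set()
    dropped = tuple(t for t in matrix.taxa if t not in covered)
    taxa = tuple(t for t in matrix.taxa if t in covered)
    if dropped:
        log.info("drop_locus(%s): removed all-missing taxa: %s", locus, ", ".join(dropped))
    return MRMatrix(taxa=taxa, columns=cols), dropped


# ---------------------------------------------------------------------------
# I/O

_PAUP_BLOCK = """begin paup;
    set autoclose=yes warntree=no warnreset=no;
    outgroup {outgroup};
    hsearch addseq=random nreps=1000 swap=tbr multrees=yes;
    savetrees file={stem}.mpts.tre replace=yes;
end;
"""


def write_nexus(
    matrix: MRMatrix,
    path,
    *,
    paup_block: bool = False,
    outgroup: Optional[str] = None,
    mrp_outgroup_row: bool = False,
) -> None:
    """Write a NEXUS DATA block (datatype=standard, symbols 0 1, missing ?).

    ``paup_block`` appends a PAUP block with a 1000-replicate random-addition
    heuristic search.  ``mrp_outgroup_row`` adds an optional all-zero
    pseudo-outgroup row named ``MRP_outgroup``.
    """
    path = Path(path)
    taxa = list(matrix.taxa)
    rows = {t: "".join(col.symbol(t) for col in matrix.columns) for t in taxa}
    if mrp_outgroup_row:
        taxa = ["MRP_outgroup"] + taxa
        rows["MRP_outgroup"] = "0" * matrix.n_columns
    name_w = max((len(t) for t in taxa), default=1) + 2
    lines = [
        "#NEXUS",
        "begin data;",
        f"    dimensions ntax={len(taxa)} nchar={matrix.n_columns};",
        '    format datatype=standard symbols="0 1" missing=? gap=-;',
        "    matrix",
    ]
    for t in taxa:
        lines.append(f"    {_nexus_name(t):<{name_w}}{rows[t]}")
    lines += ["    ;", "end;", ""]
    # per-locus character sets preserve provenance through a round-trip
    lines.append("begin sets;")
    start = 1
    for locus in matrix.loci:
        width = sum(1 for c in matrix.columns if c.locus == locus)
        lines.append(f"    charset {_nexus_name(locus)} = {start}-{start + width - 1};")
        start += width
    lines += ["end;", ""]
    if paup_block:
        og = outgroup or min(matrix.taxa)
        lines.append(_PAUP_BLOCK.format(outgroup=_nexus_name(og), stem=path.stem))
    path.write_text("\n".join(lines))


def _nexus_name(label: str) -> str:
    if re.search(r"[\s()\[\]{};'\",=*-]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_nexus(path) -> MRMatrix:
    """Read a standard-datatype NEXUS matrix written by :func:`write_nexus`."""
    import dendropy

    path = Path(path)
    data = dendropy.StandardCharacterMatrix.get(
        path=str(path), schema="nexus", preserve_underscores=True
    )
    taxa = sorted(t.label for t in data.taxon_namespace)
    states = {}
    for taxon in data.taxon_namespace:
        seq = data[taxon]
        states[taxon.label] = [str(ch) for ch in seq.symbols_as_list()]
    n_char = len(next(iter(states.values()))) if states else 0
    charsets = _read_charsets(path.read_text())
    if not charsets:
        charsets = [("all", 0, n_char)]
    cols = []
    for locus, lo, hi in charsets:
        for j in range(lo, hi):
            cluster = frozenset(t for t in taxa if states[t][j] == "1")
            source = frozenset(t for t in taxa if states[t][j] in ("0", "1"))
            cols.append(MRColumn(locus=locus, cluster=cluster, source_leaves=source))
    return MRMatrix(taxa=tuple(taxa), columns=tuple(cols))


def _read_charsets(text: str):
    out = []
    for m in re.finditer(
        r"charset\s+('(?:[^']|'')*'|\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*;", text, re.I
    ):
        name = m.group(1)
        if name.startswith("'"):
            name = name[1:-1].replace("''", "'")
        out.append((name, int(m.group(2)) - 1, int(m.group(3))))
    return out


def write_tsv(matrix: MRMatrix, path) -> None:
    """Raw matrix as TSV; header cells are ``locus|index`` for provenance."""
    header = ["taxon"] + [f"{c.locus}|{j}" for j, c in enumerate(matrix.columns)]
    lines = ["\t".join(header)]
    for t in matrix.taxa:
        lines.append("\t".join([t] + [c.symbol(t) for c in matrix.columns]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tsv(path) -> MRMatrix:
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")[1:]
    taxa, body = [], []
    for line in lines[1:]:
        cells = line.split("\t")
        taxa.append(cells[0])
        body.append(cells[1:])
    cols = []
    for j, name in enumerate(header):
        locus = name.rsplit("|", 1)[0]
        cluster = frozenset(t for t, row in zip(taxa, body) if row[j] == "1")
        source = frozenset(t for t, row in zip(taxa, body) if row[j] in ("0", "1"))
        cols.append(MRColumn(locus=locus, cluster=cluster, source_leaves=source))
    return MRMatrix(taxa=tuple(taxa), columns=tuple(cols))


def write_phylip(matrix: MRMatrix, path) -> None:
    """Relaxed PHYLIP export of the raw matrix."""
    lines = [f"{matrix.n_taxa} {matrix.n_columns}"]
    for t in matrix.taxa:
        lines.append(f"{t}  " + "".join(c.symbol(t) for c in matrix.columns))
    Path(path).write_text("\n".join(lines) + "\n")
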