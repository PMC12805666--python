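"""Chimera construction, the no-cost test and network building."""

import itertools
import random

import pytest

from treejack.compatibility import pair_compatible
from treejack.concatab import (
    build_chimera,
    build_network,
    categorize,
    edge_count,
    no_cost,
    write_sif,
)
from treejack.matrix_rep import MRColumn, MRMatrix, concatenate, encode_tree
from treejack.fixtures import FixtureConfig, RogueSpec, random_binary_tree, simulate
from treejack.trees import parse_newick

from conftest import iter_rooted_binary


def matrix_from_rows(rows, locus="g"):
    """Build a matrix from {taxon: '01?' string} rows."""
    taxa = tuple(sorted(rows))
    m = len(next(iter(rows.values())))
    cols = []
    for j in range(m):
        cluster = frozenset(t for t in taxa if rows[t][j] == "1")
        source = frozenset(t for t in taxa if rows[t][j] in "01")
        cols.append(MRColumn(locus=f"{locus}{j}", cluster=cluster, source_leaves=source))
    return MRMatrix(taxa=taxa, columns=tuple(cols))


class TestChimera:
    def test_union_with_agreement(self):
        m = matrix_from_rows({"x": "1??0", "y": "?010", "w": "0101", "v": "1010"})
        chim = build_chimera(m, "x", "y")
        assert chim.states == (1, 0, 1, 0)

    def test_conflict_marker(self):
        m = matrix_from_rows({"x": "1?", "y": "0?", "z": "01", "w": "10"})
        assert build_chimera(m, "x", "y") is None

    def test_identical_rows(self):
        m = matrix_from_rows({"x": "11", "y": "11", "z": "00"})
        assert build_chimera(m, "x", "y").states == (1, 1)

    def test_unknown_taxon_errors(self):
        m = matrix_from_rows({"x": "10", "y": "01"})
        with pytest.raises(KeyError):
            build_chimera(m, "x", "nope")


class TestNoCost:
    def test_completing_all_four_gametes_has_cost(self):
        m = matrix_from_rows({"u": "10", "v": "01", "w": "00", "x": "1?", "y": "?1"})
        assert not no_cost(m, "x", "y")

    def test_merge_adding_no_new_combination_is_free(self):
        m = matrix_from_rows({"u": "10", "v": "01", "w": "00", "x": "1?", "y": "?0"})
        assert no_cost(m, "x", "y")

    def test_identical_complete_rows_are_free(self):
        m = matrix_from_rows({"u": "10", "v": "01", "x": "10", "y": "10"})
        assert no_cost(m, "x", "y")

    def test_conflicting_pair_has_cost_by_definition(self):
        m = matrix_from_rows({"x": "1?", "y": "0?", "z": "01", "w": "10"})
        assert not no_cost(m, "x", "y")

    def test_symmetric(self):
        rng = random.Random(17)
        for _ in range(20):
            rows = {
                f"t{i}": "".join(rng.choice("01?") for _ in range(5)) for i in range(6)
            }
            try:
                m = matrix_from_rows(rows)
            except ValueError:
                continue  # a column without both states; irrelevant here
            for x, y in itertools.combinations(sorted(rows), 2):
                assert no_cost(m, x, y) == no_cost(m, y, x)


class TestCategorize:
    def test_scored_set_relations(self):
        m = matrix_from_rows(
            {
                "full1": "1010",
                "full2": "1010",
                "left": "10??",
                "right": "??10",
                "sub": "1???",
                "overlap": "?01?",
                "anchor": "0101",
            }
        )
        assert categorize(m, "full1", "full2") == "A"
        assert categorize(m, "left", "right") == "D"
        assert categorize(m, "left", "sub") == "B"
        assert categorize(m, "left", "overlap") == "E"
        m2 = matrix_from_rows({"p": "10?", "q": "10?", "r": "011", "s": "010"})
        assert categorize(m2, "p", "q") == "C"

    def test_conflicting_pair_has_no_category(self):
        m = matrix_from_rows({"x": "1?", "y": "0?", "z": "01", "w": "10"})
        with pytest.raises(ValueError):
            categorize(m, "x", "y")


class TestBuildNetwork:
    def test_effective_overlap_yields_only_cherry_dyads(self):
        """With one full-coverage binary tree, the only no-cost merges are
        cherries: exhaustively checked over every rooted binary 5-leaf tree."""
        leaves = ["a", "b", "c", "d", "e"]
        count = 0
        for tree in iter_rooted_binary(leaves):
            m = encode_tree(tree, leaves, "g1")
            net = build_network(m)
            cherries = {
                tuple(sorted(c)) for c in tree.clusters if len(c) == 2
            }
            got = {(u, v) for u, v, _ in net.edges}
            assert got == cherries
            count += 1
        assert count == 105  # (2*5-3)!! rooted binary trees

    def test_rogue_cluster_matches_naive_recount(self):
        """Vectorised network equals an exhaustive O(n^2 m^2) recount."""
        data = simulate(
            FixtureConfig(
                n_taxa=10,
                k_loci=3,
                coverage=0.7,
                rogues=(RogueSpec("rogue1", "L1", "polytomy"),),
                seed=1,
            )
        )
        uni = data.coverage.universe
        m = concatenate(
            [encode_tree(data.gene_trees[l], uni, l) for l in sorted(data.gene_trees)]
        )
        net = build_network(m)
        assert edge_count(net) == len(_naive_edges(m))
        assert {(u, v) for u, v, _ in net.edges} == _naive_edges(m)

    def test_minimal_matrices_single_edge_or_none(self):
        # two taxa scored with opposite states conflict in every column
        m2 = matrix_from_rows({"x": "10", "y": "01"})
        assert edge_count(build_network(m2)) == 0
        # a taxon missing from one column can merge with an agreeing one
        m3 = matrix_from_rows({"x": "10", "y": "1?", "z": "01"})
        assert {(u, v) for u, v, _ in build_network(m3).edges} == {("x", "y")}

    def test_invariant_to_taxon_and_column_order(self):
        rng = random.Random(23)
        rows = {f"t{i}": "".join(rng.choice("01?") for _ in range(6)) for i in range(6)}
        rows["t0"] = "101010"  # ensure every column has a 0 and a 1
        rows["t1"] = "010101"
        m = matrix_from_rows(rows)
        net = build_network(m)
        shuffled = MRMatrix(
            taxa=tuple(reversed(m.taxa)), columns=tuple(reversed(m.columns))
        )
        assert build_network(shuffled).edges == net.edges

    def test_identical_rows_always_form_an_edge(self):
        rng = random.Random(29)
        for _ in range(10):
            rows = {
                f"t{i}": "".join(rng.choice("01?") for _ in range(5)) for i in range(5)
            }
            rows["t1"] = "10110"
            rows["dup"] = rows["t1"]
            rows["t0"] = "01001"
            m = matrix_from_rows(rows)
            net = build_network(m)
            assert ("dup", "t1") in {(u, v) for u, v, _ in net.edges}

    def test_component_summary_and_sif(self, tmp_path):
        data = simulate(
            FixtureConfig(
                n_taxa=10,
                k_loci=3,
                coverage=0.7,
                rogues=(RogueSpec("rogue1", "L1", "polytomy"),),
                seed=1,
            )
        )
        uni = data.coverage.universe
        m = concatenate(
            [encode_tree(data.gene_trees[l], uni, l) for l in sorted(data.gene_trees)]
        )
        net = build_network(m)
        s = net.summary()
        comp = net.components
        assert s["singletons"] == len(comp["singletons"])
        assert s["edge_count"] == edge_count(net)
        sif = tmp_path / "n.sif"
        write_sif(net, sif)
        assert len(sif.read_text().strip().splitlines()) >= s["edge_count"]


def _naive_edges(matrix):
    """Independent recount: explicit row lists, python-set four-gamete."""
    taxa = list(matrix.taxa)
    rows = {t: [c.state(t) for c in matrix.columns] for t in taxa}
    m = matrix.n_columns

    def incompat(rowmap):
        pairs = set()
        names = list(rowmap)
        for i in range(m):
            for j in range(i + 1, m):
                combos = set()
                for t in names:
                    a, b = rowmap[t][i], rowmap[t][j]
                    if a is not None and b is not None:
                        combos.add((a, b))
                if len(combos) == 4:
                    pairs.add((i, j))
        return pairs

    base = incompat(rows)
    edges = set()
    for x, y in itertools.combinations(taxa, 2):
        merged = []
        ok = True
        for a, b in zip(rows[x], rows[y]):
            if a is not None and b is not None and a != b:
                ok = False
                break
            merged.append(a if a is not None else b)
        if not ok:
            continue
        newrows = {t: rows[t] for t in taxa if t not in (x, y)}
        newrows["chimera"] = merged
        if incompat(newrows) <= base:
            edges.add((x, y))
    return edges
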