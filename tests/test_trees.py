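"""Tree model, Newick I/O, restriction, consensus, grafting, rho and CIC."""

import math
import random

import pytest

from treejack.trees import (
    NewickError,
    PhyloTree,
    TreeError,
    cic,
    displays,
    double_factorial,
    graft,
    nearest_sampled_relative,
    parse_newick,
    parse_newick_list,
    resolution,
    restrict,
    strict_consensus,
)
from treejack.fixtures import random_binary_tree

from conftest import iter_unrooted_binary, unrooted_splits


def clset(*groups):
    return frozenset(frozenset(g) for g in groups)


class TestParseNewick:
    def test_caterpillar_clusters(self):
        t = parse_newick("(((A,B),C),D);")
        assert t.leaves == frozenset("ABCD")
        assert t.clusters == clset("AB", "ABC")

    def test_star_tree_single_internal_vertex(self):
        t = parse_newick("(A,B,C,D);")
        assert t.clusters == frozenset()
        assert t.n_internal == 1

    def test_duplicate_label_is_an_error_naming_the_label(self):
        with pytest.raises(NewickError, match="A"):
            parse_newick("((A,A),B);")

    def test_malformed_string_reports_position(self):
        with pytest.raises(NewickError, match=r"(?i)column|position|parenthes"):
            parse_newick("((A,B,;")

    def test_quoted_labels_comments_and_branch_lengths(self):
        t = parse_newick("(('Homo sapiens':0.1,B[&support=1]):0.2,C);")
        assert "Homo sapiens" in t.leaves
        assert t.clusters == clset({"Homo sapiens", "B"})

    def test_underscores_preserved(self):
        t = parse_newick("((Homo_sapiens,B),C);")
        assert "Homo_sapiens" in t.leaves

    def test_degree_two_vertices_suppressed(self):
        assert parse_newick("(((A,B)),C);") == parse_newick("((A,B),C);")

    def test_rotation_invariance(self):
        assert parse_newick("(((A,B),C),D);") == parse_newick("(D,(C,(B,A)));")

    def test_newick_round_trip(self):
        for nwk in ["(((A,B),C),D);", "((A,B),(C,D),E);", "(A,B,C);"]:
            t = parse_newick(nwk)
            assert parse_newick(t.to_newick()) == t

    def test_multi_tree_document(self):
        trees = parse_newick_list("((A,B),C);\n((A,C),B);\n")
        assert len(trees) == 2 and trees[0] != trees[1]


class TestRestrictAndDisplays:
    def test_induced_subtrees(self):
        t = parse_newick("(((A,B),C),D);")
        assert restrict(t, "ACD") == parse_newick("((A,C),D);")
        assert restrict(t, "ABC") == parse_newick("((A,B),C);")
        assert restrict(t, t.leaves) == t

    def test_restrict_unknown_label_errors(self):
        with pytest.raises(TreeError, match="Z"):
            restrict(parse_newick("((A,B),C);"), {"A", "Z"})

    def test_restriction_composes(self):
        rng = random.Random(7)
        for _ in range(20):
            t = random_binary_tree([f"t{i}" for i in range(10)], rng)
            s1 = set(rng.sample(sorted(t.leaves), 7))
            s2 = set(rng.sample(sorted(s1), 4))
            assert restrict(restrict(t, s1), s2) == restrict(t, s2)

    def test_displays_worked_examples(self):
        assert displays(parse_newick("(((A,B),C),D);"), parse_newick("((A,B),C);"))
        assert not displays(parse_newick("((A,B),(C,D));"), parse_newick("((A,C),D);"))

    def test_star_subtree_always_displayed(self):
        t = parse_newick("(((A,B),C),D);")
        assert displays(t, parse_newick("(A,C,D);"))

    def test_every_restriction_is_displayed(self):
        rng = random.Random(11)
        for _ in range(20):
            t = random_binary_tree([f"t{i}" for i in range(9)], rng)
            keep = rng.sample(sorted(t.leaves), rng.randint(2, 8))
            assert displays(t, restrict(t, keep))

    def test_displays_leafset_violation_errors(self):
        with pytest.raises(TreeError):
            displays(parse_newick("((A,B),C);"), parse_newick("((A,Z),B);"))


class TestStrictConsensus:
    def test_shared_cluster_only(self):
        trees = [
            parse_newick("(((A,B),C),D);"),
            parse_newick("((A,B),(C,D));"),
            parse_newick("(((A,B),D),C);"),
        ]
        assert strict_consensus(trees) == parse_newick("((A,B),C,D);")

    def test_identity_cases(self):
        t = parse_newick("(((A,B),C),D);")
        assert strict_consensus([t]) == t
        assert strict_consensus([t, t]) == t

    def test_idempotent_and_order_invariant(self):
        trees = [
            parse_newick("(((A,B),C),D);"),
            parse_newick("((A,B),(C,D));"),
        ]
        sc = strict_consensus(trees)
        assert strict_consensus([sc, sc]) == sc
        assert strict_consensus(list(reversed(trees))) == sc

    def test_mismatched_leaf_sets_error_lists_difference(self):
        with pytest.raises(TreeError, match="D"):
            strict_consensus([parse_newick("((A,B),C);"), parse_newick("((A,B),D);")])


class TestGraft:
    def test_graft_onto_cherry_leaf(self):
        t = graft(parse_newick("(((A,B),C),D);"), "X", "B")
        assert t == parse_newick("(((A,(B,X)),C),D);")

    def test_graft_onto_polytomy_member(self):
        t = graft(parse_newick("((A,B),C,D);"), "X", "D")
        assert t == parse_newick("((A,B),C,(D,X));")

    def test_graft_existing_leaf_errors(self):
        with pytest.raises(TreeError):
            graft(parse_newick("((A,B),C);"), "A", "B")
        with pytest.raises(TreeError):
            graft(parse_newick("((A,B),C);"), "X", "Z")


class TestNearestSampledRelative:
    def test_leaf_sister_after_restriction(self):
        ref = parse_newick("((((A,B),X),C),D);")
        assert nearest_sampled_relative(ref, "X", {"A", "C", "D"}) == "A"

    def test_retained_sister_leaf(self):
        ref = parse_newick("(((A,(B,X)),C),D);")
        assert nearest_sampled_relative(ref, "X", {"A", "B", "C", "D"}) == "B"

    def test_multi_leaf_sister_group_breaks_ties_alphabetically(self):
        ref = parse_newick("((A,B),(X,(C,D)));")
        assert nearest_sampled_relative(ref, "X", {"A", "B", "C", "D"}) == "C"

    def test_precondition_errors(self):
        ref = parse_newick("((A,B),(C,X));")
        with pytest.raises(TreeError):
            nearest_sampled_relative(ref, "Z", {"A"})
        with pytest.raises(TreeError):
            nearest_sampled_relative(ref, "X", set())
        with pytest.raises(TreeError):
            nearest_sampled_relative(ref, "X", {"A", "Z"})


class TestResolution:
    def test_binary_and_star(self):
        assert resolution(parse_newick("(((A,B),C),D);")) == 1.0
        assert resolution(parse_newick("(A,B,C,D);")) == pytest.approx(1 / 3)

    def test_partial_polytomy_fourteen_leaves(self):
        leaves = "abcdefghijklmn"
        nwk = "((((((((((a,b,c,d,e),f),g),h),i),j),k),l),m),n);"
        t = parse_newick(nwk)
        assert t.n_leaves == 14
        assert resolution(t) == pytest.approx(10 / 13)

    def test_too_few_leaves(self):
        with pytest.raises(TreeError):
            resolution(parse_newick("(A,B);"))


class TestCIC:
    def test_binary_quartet_and_star(self):
        assert cic(parse_newick("(((A,B),C),D);")) == pytest.approx(math.log2(3))
        for n in (4, 6, 9):
            star = PhyloTree([f"t{i}" for i in range(n)])
            assert cic(star) == pytest.approx(0.0)

    def test_invariant_to_rotation_and_branch_lengths(self):
        a = parse_newick("(((A:1,B:2):0.5,C):3,D);")
        b = parse_newick("(D,(C,(B,A)));")
        assert cic(a) == pytest.approx(cic(b))

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_consistency_count_matches_brute_force(self, n):
        """R(T) from the double-factorial closed form equals an exhaustive
        count of unrooted binary trees refining T."""
        rng = random.Random(n)
        leaves = [f"t{i}" for i in range(n)]
        total = double_factorial(2 * n - 5)
        all_unrooted = list(iter_unrooted_binary(leaves))
        assert len(all_unrooted) == total
        for _ in range(3):
            t = random_binary_tree(leaves, rng)
            # randomly collapse clusters to create polytomies
            kept = [c for c in t.clusters if rng.random() < 0.6]
            t = PhyloTree(leaves, kept, validate=False)
            want = unrooted_splits(t)
            consistent = sum(1 for splits in all_unrooted if want <= splits)
            assert cic(t) == pytest.approx(math.log2(total) - math.log2(consistent))
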