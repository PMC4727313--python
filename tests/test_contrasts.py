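import random
from fractions import Fraction

import pytest

from tieclust.contrasts import (
    ClusterQuery,
    cc_graph,
    cc_relaxed_graph,
    cc_relaxed_set,
    cc_set,
    frequency,
    frequency_report,
    tiecase_graph_frequency,
)
from tieclust.linkage_enum import enumerate_all_topologies, felsenstein_count
from tieclust.trees import parse_newick

from conftest import random_labels, random_tree


class TestClusterQuery:
    def test_parse_dispatches_on_trailing_semicolon(self):
        g = ClusterQuery.parse("(a,(b,c));")
        assert g.has_graph and g.leaf_set == frozenset("abc")
        s = ClusterQuery.parse("a, b, c")
        assert not s.has_graph and s.leaf_set == frozenset("abc")

    def test_rejects_singleton(self):
        with pytest.raises(ValueError):
            ClusterQuery.from_leaves(["a"])

    def test_graph_method_on_set_only_query_is_an_error(self):
        D = parse_newick("((a,b),c);")
        q = ClusterQuery.from_leaves("ab")
        with pytest.raises(ValueError):
            cc_graph(q, D)
        with pytest.raises(ValueError):
            cc_relaxed_graph(q, D)

    def test_leaves_outside_dendrogram_are_an_error(self):
        D = parse_newick("((a,b),c);")
        with pytest.raises(ValueError):
            cc_set(ClusterQuery.from_leaves("xy"), D)


class TestWorkedContrasts:
    """The three illustrated contrast computations."""

    def test_branch_and_whole_tree_are_graph_matches(self):
        D = parse_newick("((c,d),a);")
        assert cc_graph(ClusterQuery.from_newick("(c,d);"), D) == 1
        assert cc_graph(ClusterQuery.from_newick("((c,d),a);"), D) == 1

    def test_same_leafset_different_structure_fails_graph_contrast(self):
        # cluster on {a,c,d} whose internal structure pairs (a,c), not (c,d)
        D = parse_newick("((c,d),a);")
        C = ClusterQuery.from_newick("((a,c),d);")
        assert cc_graph(C, D) == 0
        assert cc_set(C, D) == 1  # as a set it matches the root subtree

    def test_shared_cherry_gives_one_third_relaxed_graph(self):
        C = ClusterQuery.from_newick("(((b,c),a),x);")
        D = parse_newick("((a,x),(b,c));")
        assert cc_relaxed_graph(C, D) == Fraction(1, 3)
        assert cc_graph(C, D) == 0

    def test_relaxed_set_subset_overlap(self):
        D = parse_newick("((c,d),a);")
        assert cc_relaxed_set(ClusterQuery.from_leaves("acd"), D) == 1
        assert cc_relaxed_set(ClusterQuery.from_leaves("ad"), D) == Fraction(2, 3)
        assert cc_set(ClusterQuery.from_leaves("ad"), D) == 0


class TestToyFrequencies:
    @pytest.mark.parametrize(
        "newick, expected",
        [
            ("(a,b);", Fraction(1)),
            ("((a,b),c);", Fraction(1)),
            ("(g,i);", Fraction(1, 2)),
            ("(h,i);", Fraction(1, 2)),
            ("((g,i),h);", Fraction(1, 2)),
            ("((h,i),g);", Fraction(1, 2)),
            ("(d,e);", Fraction(1, 3)),
            ("(e,f);", Fraction(1, 3)),
            ("(d,f);", Fraction(1, 3)),
            ("((d,e),f);", Fraction(1, 3)),
        ],
    )
    def test_graph_frequencies(self, toy_trees, newick, expected):
        q = ClusterQuery.from_newick(newick)
        assert frequency(q, toy_trees, "g") == expected

    def test_each_complete_dendrogram_has_frequency_one_sixth(self, toy_trees):
        for tree in toy_trees:
            q = ClusterQuery.from_newick(tree.newick())
            assert frequency(q, toy_trees, "g") == Fraction(1, 6)

    def test_absent_cluster_has_zero_graph_frequency(self, toy_trees):
        q = ClusterQuery.from_newick("((a,d),g);")
        assert frequency(q, toy_trees, "g") == 0

    def test_stable_zone_memberships_as_sets(self, toy_trees):
        # the three well-separated groups appear as subtree leaf sets in
        # every dendrogram, whatever their internal structure
        for leaves in ("abc", "ghi", "def"):
            q = ClusterQuery.from_leaves(leaves)
            assert frequency(q, toy_trees, "s") == 1
            assert frequency(q, toy_trees, "rs") == 1


class TestFrequencyContracts:
    def test_requires_shared_leaf_set(self):
        trees = [parse_newick("((a,b),c);"), parse_newick("((a,b),d);")]
        with pytest.raises(ValueError):
            frequency(ClusterQuery.from_leaves("ab"), trees, "s")

    def test_empty_tree_set_rejected(self):
        with pytest.raises(ValueError):
            frequency(ClusterQuery.from_leaves("ab"), [], "s")

    def test_singleton_tree_set_no_tie_case(self):
        D = parse_newick("(((a,b),c),d);")
        for newick in ("(a,b);", "((a,b),c);", "(((a,b),c),d);"):
            q = ClusterQuery.from_newick(newick)
            for method in ("g", "rg", "s", "rs"):
                assert frequency(q, [D], method) == 1
        assert frequency(ClusterQuery.from_newick("(c,d);"), [D], "g") == 0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            frequency(ClusterQuery.from_leaves("ab"), [parse_newick("(a,b);")], "x")


class TestTiecaseOracle:
    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_analytic_frequency_matches_brute_force(self, n):
        labels = [f"x{i+1}" for i in range(n)]
        all_trees = enumerate_all_topologies(labels)
        rng = random.Random(n)
        for size in range(2, n + 1):
            subset = rng.sample(labels, size)
            # any internal structure: the count only depends on |L(C)|
            C = ClusterQuery.from_newick(random_tree(subset, rng).newick())
            assert frequency(C, all_trees, "g") == tiecase_graph_frequency(n, size)

    def test_closed_form_values(self):
        assert tiecase_graph_frequency(3, 2) == Fraction(1, 3)
        assert tiecase_graph_frequency(4, 2) == Fraction(1, 5)
        # a cluster spanning all of X matches only the one tree equal to it
        for n in (3, 4, 5):
            assert tiecase_graph_frequency(n, n) == Fraction(1, felsenstein_count(n))

    def test_equal_sizes_equal_frequency_and_below_one(self):
        for n in (4, 5, 6):
            for size in range(2, n + 1):
                f = tiecase_graph_frequency(n, size)
                assert f < 1
        with pytest.raises(ValueError):
            tiecase_graph_frequency(4, 1)


def _random_pair(rng):
    """Random (cluster, dendrogram) pair on overlapping leaf sets."""
    labels = random_labels(rng, n_min=3, n_max=8)
    D = random_tree(labels, rng)
    size = rng.randint(2, len(labels))
    C = ClusterQuery.from_newick(
        random_tree(rng.sample(labels, size), rng).newick()
    )
    return C, D


class TestContrastProperties:
    """Ordering and equivalence laws relating the four contrasts."""

    N_TRIALS = 300

    def test_strict_bounded_by_relaxed_and_equivalences(self):
        rng = random.Random(2024)
        for _ in range(self.N_TRIALS):
            C, D = _random_pair(rng)
            g = cc_graph(C, D)
            rg = cc_relaxed_graph(C, D)
            s = cc_set(C, D)
            rs = cc_relaxed_set(C, D)
            assert g <= rg and s <= rs
            assert (rg == 1) == (g == 1)
            if rg == 0:
                assert g == 0
            assert (s == 1) == (rs == 1)
            assert g <= s  # a branch's leaf set is always in the family
            # the root's leaf set is in N, so a valid query always overlaps
            assert rs > 0
            if len(C.leaf_set) == 2:
                # strict contrasts and relaxed-graph coincide in {0,1};
                # relaxed-set hits 1 exactly when they do, else stays < 1
                assert g == rg == s
                assert g in (0, 1)
                assert (rs == 1) == (g == 1)

    def test_positive_relaxed_graph_iff_common_cherry(self):
        rng = random.Random(99)
        for _ in range(self.N_TRIALS):
            C, D = _random_pair(rng)
            shares_cherry = bool(C.tree.cherries() & D.cherries())
            assert (cc_relaxed_graph(C, D) > 0) == shares_cherry

    def test_frequency_orderings_on_random_tree_sets(self):
        rng = random.Random(5)
        labels = random_labels(rng, n_min=5, n_max=7)
        trees = [random_tree(labels, rng) for _ in range(12)]
        for _ in range(20):
            size = rng.randint(2, len(labels))
            C = ClusterQuery.from_newick(
                random_tree(rng.sample(labels, size), rng).newick()
            )
            f = {m: frequency(C, trees, m) for m in ("g", "rg", "s", "rs")}
            assert f["g"] <= f["rg"]
            assert f["s"] <= f["rs"]
            assert f["g"] <= f["s"]


class TestFrequencyReport:
    def test_report_rows_and_invariants(self, toy_trees):
        clusters = [
            ClusterQuery.from_newick("(a,b);"),
            ClusterQuery.from_newick("(g,i);"),
            ClusterQuery.from_leaves("def"),
        ]
        report = frequency_report(clusters, toy_trees, methods=("s", "rs"))
        assert report.m == 6
        assert len(report.rows) == 6
        m = report.m
        for _cid, method, f in report.rows:
            assert 0 <= f <= 1
            if method in ("g", "s"):
                assert (f * m).denominator == 1  # integer multiple of 1/m

    def test_report_frame_rounding(self, toy_trees):
        report = frequency_report(
            [ClusterQuery.from_newick("(d,e);")], toy_trees, methods=("g",)
        )
        frame = report.to_frame(decimals=2)
        assert frame.loc[0, "frequency"] == 0.33
        assert frame.loc[0, "frequency_exact"] == pytest.approx(1 / 3)
        assert frame.loc[0, "m"] == 6

    def test_graph_method_propagates_set_only_error(self, toy_trees):
        with pytest.raises(ValueError):
            frequency_report(
                [ClusterQuery.from_leaves("ab")], toy_trees, methods=("g",)
            )
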