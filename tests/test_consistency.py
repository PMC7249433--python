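"""Order consistency (precedence graph) and tree consistency (BUILD,
supertree enumeration)."""

import random

import networkx as nx
import pytest

from superrec.consistency import (
    build_precedence_graph,
    build_supertree,
    enumerate_ancestral_orders,
    enumerate_binary_supertrees,
    is_order_consistent,
    triplet_consistent,
)
from superrec.errors import OrderInconsistencyError, TreeInconsistencyError
from superrec.ordered import is_subsequence
from superrec.trees import (
    all_binary_topologies,
    canonical_newick,
    displays,
    leaf_names,
    parse_newick,
    restrict,
)

from conftest import make_synteny


class TestPrecedenceGraph:
    def test_adjacent_and_transitive_pairs(self):
        g = build_precedence_graph(
            [make_synteny("s1", "A", "ab"), make_synteny("s2", "A", "bc")]
        )
        assert set(g.edges) == {("a", "b"), ("b", "c")}
        g2 = build_precedence_graph([make_synteny("s1", "A", "abc")])
        assert set(g2.edges) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_single_gene_syntenies_no_edges(self):
        g = build_precedence_graph(
            [make_synteny("s1", "A", "a"), make_synteny("s2", "B", "b")]
        )
        assert set(g.edges) == set() and set(g.nodes) == {"a", "b"}

    def test_cycle_detected(self):
        g = build_precedence_graph(
            [make_synteny("s1", "A", "ab"), make_synteny("s2", "B", "ba")]
        )
        assert not is_order_consistent(g)
        with pytest.raises(OrderInconsistencyError):
            enumerate_ancestral_orders(g)

    def test_empty_input_consistent(self):
        assert is_order_consistent(build_precedence_graph([]))


class TestAncestralOrders:
    @pytest.mark.parametrize(
        "edges,nodes,expect",
        [
            ({("a", "b"), ("b", "c")}, "abc", [("a", "b", "c")]),
            (set(), "ab", [("a", "b"), ("b", "a")]),
            ({("a", "b"), ("a", "c")}, "abc", [("a", "b", "c"), ("a", "c", "b")]),
        ],
    )
    def test_small_cases(self, edges, nodes, expect):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        assert enumerate_ancestral_orders(g) == sorted(expect)

    def test_orders_contain_every_synteny_as_subsequence(self):
        rnd = random.Random(7)
        fams = list("abcde")
        for _ in range(25):
            # syntenies drawn as subsequences of one hidden global order
            hidden = fams[:]
            rnd.shuffle(hidden)
            syntenies = []
            for i in range(rnd.randint(1, 4)):
                k = rnd.randint(1, 5)
                keep = sorted(rnd.sample(range(5), k))
                syntenies.append(
                    make_synteny(f"s{i}", "A", [hidden[j] for j in keep])
                )
            g = build_precedence_graph(syntenies)
            assert is_order_consistent(g)
            for order in enumerate_ancestral_orders(g, limit=500):
                for s in syntenies:
                    assert is_subsequence(s.families, order)

    def test_truncation_warns(self):
        g = nx.DiGraph()
        g.add_nodes_from("abcde")  # 5! = 120 sorts
        with pytest.warns(UserWarning, match="truncated"):
            got = enumerate_ancestral_orders(g, limit=10)
        assert len(got) == 10


class TestTripletConsistency:
    def test_identical_trees(self):
        t = parse_newick("((X1,X2),X3);")
        assert triplet_consistent([t, t.copy()])

    def test_conflicting_triplet(self):
        assert not triplet_consistent(
            [parse_newick("((X1,X2),X3);"), parse_newick("((X1,X3),X2);")]
        )

    def test_disjoint_leafsets(self):
        assert triplet_consistent(
            [parse_newick("((X1,X2),X3);"), parse_newick("((X4,X5),X6);")]
        )


class TestBuildSupertree:
    def test_single_tree_identity(self):
        t = parse_newick("((X1,X2),(X3,X4));")
        st = build_supertree([t])
        assert canonical_newick(st) == canonical_newick(t)

    def test_conflict_raises_distinct_error(self):
        with pytest.raises(TreeInconsistencyError):
            build_supertree(
                [parse_newick("((X1,X2),X3);"), parse_newick("((X1,X3),X2);")]
            )

    def test_disjoint_cherries_displayed(self):
        inputs = [parse_newick("(X1,X2);"), parse_newick("(X3,X4);")]
        st = build_supertree(inputs)
        # every binary refinement displays both cherries; check via the
        # enumeration, which refines the BUILD tree
        for t in enumerate_binary_supertrees(inputs):
            assert all(displays(t, i) for i in inputs)


class TestEnumerateBinarySupertrees:
    def test_fully_resolved_input_single_output(self):
        t = parse_newick("((X1,X2),(X3,X4));")
        out = enumerate_binary_supertrees([t])
        assert len(out) == 1
        assert canonical_newick(out[0]) == canonical_newick(t)

    def test_cherry_plus_free_leaf(self):
        # a 2-leaf tree is displayed by every tree containing its
        # leaves (the restriction to two leaves is always that cherry),
        # so the free leaf is unconstrained: all 3 topologies qualify
        out = enumerate_binary_supertrees(
            [parse_newick("(X1,X2);"), parse_newick("X3;")]
        )
        assert len(out) == 3
        assert canonical_newick(parse_newick("((X1,X2),X3);")) in {
            canonical_newick(t) for t in out
        }

    def test_triplet_constrained_cherry(self):
        # with a 3-leaf input the cherry is a real constraint
        out = enumerate_binary_supertrees([parse_newick("((X1,X2),X3);")])
        assert [canonical_newick(t) for t in out] == [
            canonical_newick(parse_newick("((X1,X2),X3);"))
        ]

    def test_three_free_leaves(self):
        out = enumerate_binary_supertrees([parse_newick(f"X{i};") for i in range(3)])
        assert len(out) == 3  # (2n-3)!! for n = 3

    def test_matches_exhaustive_display_filter(self):
        rnd = random.Random(1)
        for _ in range(20):
            nl = rnd.randint(3, 6)
            leaves = [f"X{i}" for i in range(nl)]
            topos = list(all_binary_topologies(leaves))
            hidden = rnd.choice(topos)
            inputs = [
                restrict(hidden, rnd.sample(leaves, rnd.randint(2, nl)))
                for _ in range(rnd.randint(1, 3))
            ]
            union = set().union(*(set(leaf_names(i)) for i in inputs))
            got = {canonical_newick(t) for t in enumerate_binary_supertrees(inputs)}
            want = {
                canonical_newick(t)
                for t in all_binary_topologies(sorted(union))
                if all(displays(t, i) for i in inputs)
            }
            assert got == want
            for t in enumerate_binary_supertrees(inputs):
                assert all(displays(t, i) for i in inputs)

    def test_truncation_warns(self):
        inputs = [parse_newick(f"X{i};") for i in range(6)]  # 945 topologies
        with pytest.warns(UserWarning, match="truncated"):
            out = enumerate_binary_supertrees(inputs, limit=50)
        assert len(out) == 50
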