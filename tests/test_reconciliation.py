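"""LCA mapping, event labeling, full-loss grafting and the classical
duplication-loss cost."""

import random

import pytest

from superrec.errors import ValidationError
from superrec.model import EventType
from superrec.reconciliation import (
    Backbone,
    SpeciesIndex,
    classic_dl_cost,
    graft_full_losses,
    label_events,
    lca_mapping,
)
from superrec.oracles import oracle_classic_dl
from superrec.trees import ensure_internal_names, parse_newick


def _mapped_names(tree, species_of_leaf, S):
    sidx = SpeciesIndex(ensure_internal_names(S))
    smap = lca_mapping(tree, species_of_leaf, sidx)
    return {n.name: smap[id(n)].name for n in tree.traverse()}, smap, sidx


class TestLcaMapping:
    def test_leaf_maps_to_own_species(self):
        names, _, _ = _mapped_names(
            parse_newick("g1;"), {"g1": "spA"}, parse_newick("(spA,spB);")
        )
        assert names["g1"] == "spA"

    def test_cherry_forced_to_root(self):
        S = parse_newick("(spA,spB);")
        t = parse_newick("(g1,g2)r;")
        names, _, _ = _mapped_names(t, {"g1": "spA", "g2": "spB"}, S)
        assert names["r"] == S.name

    def test_three_leaf_mapping(self):
        S = parse_newick("((spA,spB)ab,spC)r;")
        t = parse_newick("((lA,lB)i,lA2)t;")
        names, _, _ = _mapped_names(
            t, {"lA": "spA", "lB": "spB", "lA2": "spA"}, S
        )
        assert names["i"] == "ab" and names["t"] == "ab"

    def test_unknown_species_rejected(self):
        with pytest.raises(ValidationError):
            _mapped_names(parse_newick("g1;"), {"g1": "spZ"}, parse_newick("(spA,spB);"))


class TestLabelEvents:
    def test_separated_children_speciation(self):
        S = parse_newick("(spA,spB);")
        t = parse_newick("(g1,g2)r;")
        _, smap, sidx = _mapped_names(t, {"g1": "spA", "g2": "spB"}, S)
        assert label_events(t, smap, sidx)[id(t)] is EventType.SPE

    def test_same_species_duplication(self):
        S = parse_newick("(spA,spB);")
        t = parse_newick("(g1,g2)r;")
        _, smap, sidx = _mapped_names(t, {"g1": "spA", "g2": "spA"}, S)
        assert label_events(t, smap, sidx)[id(t)] is EventType.DUP

    def test_ancestor_child_duplication(self):
        # one child maps to an ancestor of the other's species: not
        # separated, hence a duplication
        S = parse_newick("((spA,spB)ab,spC)r;")
        t = parse_newick("((g1,g2)i,g3)v;")
        _, smap, sidx = _mapped_names(t, {"g1": "spA", "g2": "spB", "g3": "spA"}, S)
        events = label_events(t, smap, sidx)
        inner = next(n for n in t.traverse() if n.name == "v")
        assert events[id(inner)] is EventType.DUP

    def test_child_order_symmetry(self):
        S = parse_newick("((spA,spB),spC);")
        t1 = parse_newick("(g1,g2)r;")
        t2 = parse_newick("(g2,g1)r;")
        for t in (t1, t2):
            _, smap, sidx = _mapped_names(t, {"g1": "spA", "g2": "spC"}, S)
            assert label_events(t, smap, sidx)[id(t)] is EventType.SPE


class TestGrafting:
    def _graft(self, newick, species_of_leaf, S_newick):
        S = ensure_internal_names(parse_newick(S_newick))
        t = parse_newick(newick)
        sidx = SpeciesIndex(S)
        smap = lca_mapping(t, species_of_leaf, sidx)
        events = label_events(t, smap, sidx)
        grafted = graft_full_losses(t, smap, events, sidx)
        return t, smap, events, grafted, sidx

    def test_congruent_tree_no_grafts(self):
        _, _, _, grafted, _ = self._graft(
            "(g1,g2);", {"g1": "spA", "g2": "spB"}, "(spA,spB);"
        )
        assert grafted == []

    def test_dup_above_leaf_species(self):
        # duplication at the root of a depth-1 species tree with one
        # child mapping to a leaf species: one edge skipped, one fLoss
        t, smap, events, grafted, sidx = self._graft(
            "((g1,g2)i,g3)r;",
            {"g1": "spA", "g2": "spB", "g3": "spA"},
            "(spA,spB);",
        )
        assert len(grafted) == 1
        assert smap[id(grafted[0])].name == "spB"

    def test_speciation_skipping_two_edges(self):
        t, smap, events, grafted, sidx = self._graft(
            "(g1,g2);",
            {"g1": "spA", "g2": "spD"},
            "(((spA,spB),spC),spD);",
        )
        # child spA sits 2 edges below the child expected under the root
        assert len(grafted) == 2

    def test_edge_constraints_after_grafting(self):
        # after grafting, every edge satisfies the reconciliation
        # constraint: children of a speciation map to the two children
        # of s(v); children of a duplication map to s(v)
        rnd = random.Random(3)
        for _ in range(20):
            n = rnd.randint(2, 6)
            species = [f"sp{i}" for i in range(4)]
            leaves = {f"g{i}": rnd.choice(species) for i in range(n)}
            t, smap, events, grafted, sidx = self._graft(
                _random_newick(rnd, list(leaves)),
                leaves,
                "((sp0,sp1),(sp2,sp3));",
            )
            for node in t.traverse():
                if not node.children:
                    continue
                sv = smap[id(node)]
                if events[id(node)] is EventType.SPE:
                    assert {id(smap[id(c)]) for c in node.children} == {
                        id(c) for c in sv.children
                    }
                elif events[id(node)] is EventType.DUP:
                    assert all(smap[id(c)] is sv for c in node.children)

    def test_graft_count_equals_classical_loss_formula(self):
        rnd = random.Random(5)
        for _ in range(30):
            n = rnd.randint(2, 7)
            species = [f"sp{i}" for i in range(4)]
            leaves = {f"g{i}": rnd.choice(species) for i in range(n)}
            S = ensure_internal_names(parse_newick("((sp0,sp1),(sp2,sp3));"))
            t = parse_newick(_random_newick(rnd, list(leaves)))
            sidx = SpeciesIndex(S)
            smap = lca_mapping(t, leaves, sidx)
            events = label_events(t, smap, sidx)
            expected = 0
            for node in t.traverse():
                if not node.children:
                    continue
                spe = events[id(node)] is EventType.SPE
                for c in node.children:
                    expected += sidx.dist(smap[id(node)], smap[id(c)]) - (
                        1 if spe else 0
                    )
            grafted = graft_full_losses(t, smap, events, sidx)
            assert len(grafted) == expected


class TestClassicDL:
    def test_congruent_zero(self):
        S = parse_newick("((spA,spB),spC);")
        t = parse_newick("((g1,g2),g3);")
        sp = {"g1": "spA", "g2": "spB", "g3": "spC"}
        assert classic_dl_cost(t, sp, S) == 0

    def test_same_species_cherry(self):
        S = parse_newick("((spA,spB),spC);")
        assert classic_dl_cost(
            parse_newick("(g1,g2);"), {"g1": "spA", "g2": "spA"}, S
        ) == 1

    def test_cherry_with_one_intermediate_loss(self):
        # genes in spA and spC: speciation at the root, one loss on the
        # spA side (the spB lineage died)
        S = parse_newick("((spA,spB),spC);")
        assert classic_dl_cost(
            parse_newick("(g1,g2);"), {"g1": "spA", "g2": "spC"}, S
        ) == 1

    def test_matches_independent_event_walk(self):
        rnd = random.Random(11)
        for _ in range(40):
            n = rnd.randint(1, 7)
            species = [f"sp{i}" for i in range(4)]
            leaves = {f"g{i}": rnd.choice(species) for i in range(n)}
            S = parse_newick("((sp0,sp1),(sp2,sp3));")
            t = parse_newick(_random_newick(rnd, list(leaves)))
            assert classic_dl_cost(t, leaves, S) == oracle_classic_dl(t, leaves, S)


def _random_newick(rnd: random.Random, leaves: list[str]) -> str:
    items = leaves[:]
    rnd.shuffle(items)
    while len(items) > 1:
        a = items.pop(rnd.randrange(len(items)))
        b = items.pop(rnd.randrange(len(items)))
        items.append(f"({a},{b})")
    return items[0] + ";"


class TestBackbone:
    def test_backbone_bundles_maps(self):
        S = parse_newick("(spA,spB);")
        bb = Backbone(parse_newick("(X1,X2);"), {"X1": "spA", "X2": "spA"}, S)
        # the duplication maps to spA itself: no species edge is skipped
        assert bb.n_dup == 1 and bb.n_floss == 0
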