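"""Domain types, table parsing, synteny trees and history validation."""

import pytest

from superrec.errors import (
    DuplicateGeneError,
    FamilyInjectivityError,
    InvalidHistoryError,
    NonBinaryTreeError,
    SyntenyTableError,
)
from superrec.io import (
    history_event_table,
    history_to_newick,
    read_gene_trees,
    read_species_tree,
    read_synteny_table,
    write_synteny_table,
    write_trees,
)
from superrec.model import (
    Event,
    EventType,
    Gene,
    LabeledHistory,
    Synteny,
    history_cost,
    organize,
    synteny_tree_of,
)
from superrec.trees import (
    TreeNode,
    canonical_newick,
    label_isomorphic,
    leaf_names,
    parse_newick,
)

from conftest import make_synteny


class TestParsing:
    def test_species_tree_parse(self, tmp_path):
        p = tmp_path / "S.nwk"
        p.write_text("((a,b),c);\n")
        tree = read_species_tree(p)
        assert sorted(leaf_names(tree)) == ["a", "b", "c"]
        kids = {frozenset(leaf_names(c)) for c in tree.children}
        assert frozenset(["a", "b"]) in kids and frozenset(["c"]) in kids

    def test_branch_lengths_ignored(self):
        tree = parse_newick("((a:1.5,b:0.2):0.1,c:2);")
        assert all(n.length is None for n in tree.traverse())

    def test_non_binary_rejected(self, tmp_path):
        p = tmp_path / "S.nwk"
        p.write_text("(a,b,c);\n")
        with pytest.raises(NonBinaryTreeError):
            read_species_tree(p)

    def test_synteny_table_roundtrip(self, tmp_path):
        syntenies = [make_synteny("s1", "spX", "ab"), make_synteny("s2", "spY", "b")]
        p = tmp_path / "t.tsv"
        write_synteny_table(syntenies, p)
        back, fam_of = read_synteny_table(p)
        assert [s.id for s in back] == ["s1", "s2"]
        assert back[0].families == ("a", "b")
        assert back[0].species == "spX"
        assert fam_of["a.s1"] == "a"

    def test_table_row_parse(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "gene\tfamily\tspecies\tsynteny\tposition\n"
            "g1\tfamA\tspX\tsyn1\t1\n"
        )
        syntenies, fam_of = read_synteny_table(p)
        (s,) = syntenies
        assert s.genes == (Gene("g1", "famA", "spX"),)
        assert fam_of == {"g1": "famA"}

    def test_same_family_twice_in_synteny(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "gene\tfamily\tspecies\tsynteny\tposition\n"
            "g1\tfamA\tspX\tsyn1\t1\n"
            "g2\tfamA\tspX\tsyn1\t2\n"
        )
        with pytest.raises(FamilyInjectivityError):
            read_synteny_table(p)

    def test_non_contiguous_positions(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "gene\tfamily\tspecies\tsynteny\tposition\n"
            "g1\tfamA\tspX\tsyn1\t2\n"
        )
        with pytest.raises(SyntenyTableError):
            read_synteny_table(p)

    def test_duplicate_gene_id(self):
        with pytest.raises(DuplicateGeneError):
            organize(
                [
                    Synteny("s1", "spX", (Gene("g1", "a", "spX"),)),
                    Synteny("s2", "spX", (Gene("g1", "b", "spX"),)),
                ]
            )

    def test_tree_file_roundtrip(self, tmp_path):
        trees = [parse_newick("((g1,g2),g3);"), parse_newick("(g4,g5);")]
        p = tmp_path / "g.nwk"
        write_trees(trees, p)
        back = read_gene_trees(p)
        assert len(back) == 2
        for a, b in zip(trees, back):
            assert label_isomorphic(a, b)


class TestSyntenyTree:
    def test_relabeling(self):
        t = parse_newick("(g1,(g2,g3));")
        st = synteny_tree_of(t, {"g1": "X1", "g2": "X2", "g3": "X3"})
        assert label_isomorphic(st, parse_newick("(X1,(X2,X3));"))

    def test_single_leaf(self):
        st = synteny_tree_of(parse_newick("g1;"), {"g1": "X1"})
        assert leaf_names(st) == ["X1"]

    def test_shared_synteny_across_trees(self):
        # genes of different families in the same synteny produce the
        # same leaf label in both synteny trees: the overlap that makes
        # supertrees informative
        t1 = synteny_tree_of(parse_newick("(a1,a2);"), {"a1": "X1", "a2": "X2"})
        t2 = synteny_tree_of(parse_newick("(b1,b2);"), {"b1": "X1", "b2": "X3"})
        assert set(leaf_names(t1)) & set(leaf_names(t2)) == {"X1"}


def _node(name, synteny, event, species, *children):
    n = TreeNode(name=name)
    n.synteny = synteny
    n.event = event
    n.species = species
    for c in children:
        n.append(c)
    return n


def _speciation_only_history():
    S = parse_newick("(A,B);")
    ab = ("a", "b")
    root = _node(
        "r", ab, Event(EventType.SPE, (1, 2)), "anc0",
        _node("x1", ab, Event(EventType.EXTANT), "A"),
        _node("x2", ab, Event(EventType.EXTANT), "B"),
    )
    return LabeledHistory(root, S, ordered=True)


class TestHistory:
    def test_speciation_only_cost_zero(self):
        h = _speciation_only_history()
        assert history_cost(h) == 0

    def test_dup_floss_cost(self):
        S = parse_newick("(A,B);")
        abc = ("a", "b", "c")
        root = _node(
            "r", abc, Event(EventType.SPE, (1, 3)), "anc0",
            _node(
                "d", abc, Event(EventType.DUP, (2, 3)), "A",
                _node("x1", abc, Event(EventType.EXTANT), "A"),
                _node("x2", ("b", "c"), Event(EventType.EXTANT), "A"),
            ),
            _node("l", (), Event(EventType.FLOSS), "B"),
        )
        h = LabeledHistory(root, S, ordered=True)
        assert history_cost(h) == 2  # 1 Dup + 1 fLoss, 0 pLoss

    def test_ploss_chain(self):
        S = parse_newick("(A,B);")
        root = _node(
            "r", ("a", "b", "c"), Event(EventType.SPE, (1, 3)), "anc0",
            _node(
                "p", ("a", "b", "c"), Event(EventType.PLOSS, (2, 2)), "A",
                _node("x1", ("a", "c"), Event(EventType.EXTANT), "A"),
            ),
            _node("x2", ("a", "b", "c"), Event(EventType.EXTANT), "B"),
        )
        h = LabeledHistory(root, S, ordered=True)
        assert history_cost(h) == 1

    @pytest.mark.parametrize(
        "mutate",
        [
            # speciation child carries a different synteny
            lambda r: setattr(r.children[0], "synteny", ("a",)),
            # extant leaf with empty synteny
            lambda r: setattr(r.children[1], "synteny", ()),
            # child species not a child of the parent's species
            lambda r: setattr(r.children[0], "species", "B"),
            # bad segment
            lambda r: setattr(r, "event", Event(EventType.SPE, (1, 5))),
        ],
    )
    def test_invalid_histories_rejected(self, mutate):
        h = _speciation_only_history()
        mutate(h.root)
        with pytest.raises(InvalidHistoryError):
            h.validate()

    def test_annotated_newick_and_event_table(self):
        h = _speciation_only_history()
        text = history_to_newick(h)
        assert "[&event=Spe,segment=1-2,synteny=a|b,species=anc0]" in text
        rows = history_event_table(h)
        assert ("x1", "extant", "A", "a|b", "") in rows

    def test_canonical_newick_deterministic(self):
        t1 = parse_newick("((a,b),c);")
        t2 = parse_newick("(c,(b,a));")
        assert canonical_newick(t1) == canonical_newick(t2)
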