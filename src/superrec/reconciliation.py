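"""LCA-mapping, speciation/duplication labeling, and full-loss grafting.

These are the pieces of classical duplication-loss reconciliation that
both the ordered and unordered pipelines share.  For a minimum-cost
Super-Reconciliation the species assignment of every supertree node is
the LCA-mapping, and an internal node is a speciation exactly when its
children map to separated species (neither an ancestor of the other);
otherwise it is a duplication.

:func:`graft_full_losses` then inserts, on every edge that skips
species-tree edges, one speciation node per skipped edge with an
``fLoss`` leaf on the side that died out.  Grafted loss leaves carry
the empty synteny and sit closest to the parent (full losses before
partial ones on an edge — the convention that keeps the resulting tree
a valid history backbone).
"""

from __future__ import annotations

from typing import Mapping

from skbio import TreeNode

from .errors import ValidationError
from .model import EventType, _SpeciesIndex

__all__ = [
    "SpeciesIndex",
    "lca_mapping",
    "label_events",
    "graft_full_losses",
    "classic_dl_cost",
]

# public alias: ancestry queries on a species tree
SpeciesIndex = _SpeciesIndex


def lca_mapping(
    tree: TreeNode, species_of_leaf: Mapping[str, str], sidx: SpeciesIndex
) -> dict[int, TreeNode]:
    """Map every node of ``tree`` (keyed by ``id(node)``) to its species
    tree node: a leaf to its own species, an internal node to the LCA of
    its descendants' species."""
    smap: dict[int, TreeNode] = {}
    for node in tree.postorder():
        if not node.children:
            if node.name not in species_of_leaf:
                raise ValidationError(f"leaf {node.name!r} has no species")
            smap[id(node)] = sidx.node(species_of_leaf[node.name])
        else:
            it = iter(node.children)
            acc = smap[id(next(it))]
            for c in it:
                acc = sidx.lca(acc, smap[id(c)])
            smap[id(node)] = acc
    return smap


def label_events(
    tree: TreeNode, smap: Mapping[int, TreeNode], sidx: SpeciesIndex
) -> dict[int, EventType]:
    """Label each internal node ``Spe`` or ``Dup`` from the LCA-mapping.

    Must be called before loss grafting: every internal node has to be
    binary.
    """
    events: dict[int, EventType] = {}
    for node in tree.traverse():
        if not node.children:
            continue
        if len(node.children) != 2:
            raise ValidationError(
                f"node {node.name!r} is not binary; label before grafting losses"
            )
        l, r = node.children
        sep = sidx.separated(smap[id(l)], smap[id(r)])
        events[id(node)] = EventType.SPE if sep else EventType.DUP
    return events


def _loss_edges(
    parent_species: TreeNode,
    child_species: TreeNode,
    parent_event: EventType,
    sidx: SpeciesIndex,
) -> list[TreeNode]:
    """Species nodes at which the lineage entering ``child_species``
    passes through a speciation whose other side is lost.

    After a speciation the lineage starts at the child of the parent's
    species on the path; after a duplication it starts at the parent's
    species itself.
    """
    if parent_event is EventType.SPE:
        path = sidx.path_down(parent_species, child_species)
        start = path[1]  # the child of parent_species toward child_species
    else:
        start = parent_species
    return sidx.path_down(start, child_species)[:-1]


def graft_full_losses(
    tree: TreeNode,
    smap: dict[int, TreeNode],
    events: dict[int, EventType],
    sidx: SpeciesIndex,
) -> list[TreeNode]:
    """Graft ``fLoss`` leaves in place; return the new loss leaves.

    ``tree`` is modified; ``smap`` and ``events`` gain entries for the
    grafted speciation nodes and loss leaves (loss leaves map to the
    species-tree sibling of the surviving lineage).  Grafted nodes
    closest to the parent come first.
    """
    grafted: list[TreeNode] = []
    counter = 0
    for node in list(tree.traverse()):
        if not node.children:
            continue
        ev = events[id(node)]
        for child in list(node.children):
            stops = _loss_edges(smap[id(node)], smap[id(child)], ev, sidx)
            if not stops:
                continue
            node.remove(child)
            attach = node
            for w in stops:
                spe = TreeNode()
                loss = TreeNode(name=f"loss{counter}")
                counter += 1
                # the lost side is the child of w away from the lineage
                path_next = sidx.path_down(w, smap[id(child)])[1]
                (lost_side,) = [c for c in w.children if c is not path_next]
                smap[id(spe)] = w
                events[id(spe)] = EventType.SPE
                smap[id(loss)] = lost_side
                events[id(loss)] = EventType.FLOSS
                spe.append(loss)
                attach.append(spe)
                attach = spe
                grafted.append(loss)
            attach.append(child)
    return grafted


class Backbone:
    """A supertree prepared for the small-phylogeny DPs: copied,
    LCA-mapped, event-labeled and fLoss-grafted."""

    def __init__(
        self,
        supertree: TreeNode,
        species_of_leaf: Mapping[str, str],
        species_tree: TreeNode,
    ):
        from .trees import ensure_internal_names

        self.species_tree = ensure_internal_names(species_tree)
        self.sidx = SpeciesIndex(species_tree)
        self.tree = supertree.copy()
        self.smap = lca_mapping(self.tree, species_of_leaf, self.sidx)
        if self.tree.children:
            self.events = label_events(self.tree, self.smap, self.sidx)
        else:
            self.events = {}
        self.loss_leaves = graft_full_losses(self.tree, self.smap, self.events, self.sidx)
        ensure_internal_names(self.tree, prefix="n")

    def species_name(self, node: TreeNode) -> str:
        return self.smap[id(node)].name

    def event(self, node: TreeNode) -> EventType | None:
        return self.events.get(id(node))

    def is_floss_leaf(self, node: TreeNode) -> bool:
        return self.events.get(id(node)) is EventType.FLOSS

    @property
    def n_floss(self) -> int:
        return len(self.loss_leaves)

    @property
    def n_dup(self) -> int:
        return sum(1 for e in self.events.values() if e is EventType.DUP)


def classic_dl_cost(
    gene_tree: TreeNode, species_of_leaf: Mapping[str, str], species_tree: TreeNode
) -> int:
    """Cost of the classical LCA-reconciliation of one gene tree:
    duplications plus single-gene losses."""
    sidx = SpeciesIndex(species_tree)
    smap = lca_mapping(gene_tree, species_of_leaf, sidx)
    if not gene_tree.children:
        return 0
    events = label_events(gene_tree, smap, sidx)
    cost = 0
    for node in gene_tree.traverse():
        if not node.children:
            continue
        ev = events[id(node)]
        if ev is EventType.DUP:
            cost += 1
        for child in node.children:
            d = sidx.dist(smap[id(node)], smap[id(child)])
            cost += d - (1 if ev is EventType.SPE else 0)
    return cost
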