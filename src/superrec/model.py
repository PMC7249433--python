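"""Core domain types: genes, syntenies, trees, events and labeled
histories.

A *synteny* is an ordered run of neighboring genes on a chromosome, at
most one per gene family.  Syntenies evolve from a single ancestral one
through three kinds of events:

* ``Spe`` — speciation: the synteny is transmitted to both descendant
  species;
* ``Dup`` — segmental duplication: a contiguous block ``[i, j]`` of the
  synteny is copied elsewhere in the same genome;
* loss — a contiguous block is removed; a *partial* loss (``pLoss``)
  leaves a non-empty synteny, a *full* loss (``fLoss``) removes it
  entirely.

A :class:`LabeledHistory` is a (partially binary) synteny tree whose
nodes carry the synteny content, the event and the species, and whose
edges satisfy the event model's constraints.  Its cost is the number of
``Dup`` + ``pLoss`` + ``fLoss`` events; speciations are free.

Two flavors are supported: *ordered* histories carry gene orders (node
content is a tuple of family identifiers, events carry 1-based closed
segments ``[i, j]``) and *unordered* histories carry gene contents only
(node content is a frozenset, segments are absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Sequence

from skbio import TreeNode

from .errors import FamilyInjectivityError, InvalidHistoryError, ValidationError
from .trees import leaf_names


class EventType(str, Enum):
    SPE = "Spe"
    DUP = "Dup"
    PLOSS = "pLoss"
    FLOSS = "fLoss"
    EXTANT = "extant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: events that contribute 1 to the cost of a history
COSTED_EVENTS = frozenset({EventType.DUP, EventType.PLOSS, EventType.FLOSS})


@dataclass(frozen=True)
class Gene:
    """One gene: a globally unique id, its family and its species."""

    id: str
    family: str
    species: str


@dataclass(frozen=True)
class Synteny:
    """An ordered sequence of genes from distinct families in one species."""

    id: str
    species: str
    genes: tuple[Gene, ...]

    def __post_init__(self) -> None:
        fams = [g.family for g in self.genes]
        if len(set(fams)) != len(fams):
            dupes = sorted({f for f in fams if fams.count(f) > 1})
            raise FamilyInjectivityError(
                f"synteny {self.id!r} has several genes from families {dupes}"
            )
        for g in self.genes:
            if g.species != self.species:
                raise ValidationError(
                    f"gene {g.id!r} is in species {g.species!r} but synteny "
                    f"{self.id!r} is in {self.species!r}"
                )

    @property
    def families(self) -> tuple[str, ...]:
        """The family sequence of the synteny (its gene order at the
        family level)."""
        return tuple(g.family for g in self.genes)

    @property
    def family_set(self) -> frozenset[str]:
        """``Set(X)``: the range of the synteny, orders forgotten."""
        return frozenset(g.family for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class Event:
    """An event label: type plus, for ordered histories, the affected
    segment as a 1-based closed interval into the node's synteny."""

    type: EventType
    segment: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.segment is not None:
            i, j = self.segment
            if not (1 <= i <= j):
                raise ValidationError(f"bad segment {self.segment}")


def synteny_tree_of(gene_tree: TreeNode, synteny_of_gene: Mapping[str, str]) -> TreeNode:
    """The synteny tree of a gene tree: same topology, every leaf
    relabeled by the synteny containing its gene."""
    out = gene_tree.copy()
    for tip in out.tips() if out.children else [out]:
        if tip.name not in synteny_of_gene:
            raise ValidationError(f"gene {tip.name!r} has no synteny")
        tip.name = synteny_of_gene[tip.name]
    return out


class _SpeciesIndex:
    """Constant-ish-time ancestry queries on a species tree."""

    def __init__(self, species_tree: TreeNode):
        self.tree = species_tree
        self.by_name: dict[str, TreeNode] = {}
        self.parent: dict[int, TreeNode | None] = {id(species_tree): None}
        self.depth: dict[int, int] = {}
        for node in species_tree.preorder():
            if node.name is not None:
                if node.name in self.by_name:
                    raise ValidationError(f"duplicate species label {node.name!r}")
                self.by_name[node.name] = node
            p = self.parent.get(id(node))
            self.depth[id(node)] = 0 if p is None else self.depth[id(p)] + 1
            for c in node.children:
                self.parent[id(c)] = node

    def node(self, name: str) -> TreeNode:
        try:
            return self.by_name[name]
        except KeyError:
            raise ValidationError(f"unknown species {name!r}") from None

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        while self.depth[id(a)] > self.depth[id(b)]:
            a = self.parent[id(a)]
        while self.depth[id(b)] > self.depth[id(a)]:
            b = self.parent[id(b)]
        while a is not b:
            a = self.parent[id(a)]
            b = self.parent[id(b)]
        return a

    def dist(self, anc: TreeNode, desc: TreeNode) -> int:
        """Edge count from ancestor ``anc`` down to descendant ``desc``."""
        d = self.depth[id(desc)] - self.depth[id(anc)]
        if d < 0 or self.lca(anc, desc) is not anc:
            raise ValidationError("dist() called on a non-ancestor pair")
        return d

    def is_ancestor(self, anc: TreeNode, desc: TreeNode) -> bool:
        return self.lca(anc, desc) is anc

    def separated(self, a: TreeNode, b: TreeNode) -> bool:
        """Neither node is an ancestor of the other."""
        lca = self.lca(a, b)
        return lca is not a and lca is not b

    def path_down(self, anc: TreeNode, desc: TreeNode) -> list[TreeNode]:
        """Nodes from ``anc`` to ``desc`` inclusive."""
        path = [desc]
        while path[-1] is not anc:
            p = self.parent[id(path[-1])]
            if p is None:
                raise ValidationError("path_down() on a non-ancestor pair")
            path.append(p)
        path.reverse()
        return path


@dataclass
class LabeledHistory:
    """A synteny tree with per-node synteny content, event and species.

    Node attributes used on ``root``'s nodes:

    * ``synteny`` — tuple of family ids (ordered) or frozenset (unordered);
      the empty tuple/set on ``fLoss`` leaves;
    * ``event`` — an :class:`Event`;
    * ``species`` — a species label of ``species_tree``.
    """

    root: TreeNode
    species_tree: TreeNode
    ordered: bool = True
    meta: dict = field(default_factory=dict)

    def nodes(self) -> Iterator[TreeNode]:
        return self.root.traverse()

    def cost(self) -> int:
        """Number of Dup + pLoss + fLoss events."""
        return sum(1 for n in self.nodes() if n.event.type in COSTED_EVENTS)

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Check every edge against the event model; raise
        :class:`InvalidHistoryError` on the first violation."""
        from .trees import ensure_internal_names

        ensure_internal_names(self.species_tree)
        sidx = _SpeciesIndex(self.species_tree)
        for node in self.root.traverse():
            self._check_node(node, sidx)

    def _content(self, node: TreeNode):
        return node.synteny

    def _equal(self, x, y) -> bool:
        return x == y

    def _check_node(self, v: TreeNode, sidx: _SpeciesIndex) -> None:
        ev: Event = v.event
        X = v.synteny
        sv = sidx.node(v.species)
        where = f"node {v.name!r} ({ev.type})"

        if ev.type in (EventType.EXTANT, EventType.FLOSS):
            if v.children:
                raise InvalidHistoryError(f"{where}: must be a leaf")
            if ev.type is EventType.EXTANT and len(X) == 0:
                raise InvalidHistoryError(f"{where}: extant leaf with empty synteny")
            if ev.type is EventType.FLOSS and len(X) != 0:
                raise InvalidHistoryError(f"{where}: fLoss leaf must carry the empty synteny")
            return

        if ev.type is EventType.PLOSS:
            if len(v.children) != 1:
                raise InvalidHistoryError(f"{where}: pLoss must be unary")
            (c,) = v.children
            if c.species != v.species:
                raise InvalidHistoryError(f"{where}: pLoss changes species")
            if self.ordered:
                i, j = self._segment(ev, len(X), where)
                truncated = X[: i - 1] + X[j:]
                if c.synteny != truncated:
                    raise InvalidHistoryError(
                        f"{where}: child synteny {c.synteny} != truncation {truncated}"
                    )
            else:
                if not (c.synteny < X):
                    raise InvalidHistoryError(
                        f"{where}: pLoss child content must be a proper subset"
                    )
            if len(c.synteny) == 0:
                raise InvalidHistoryError(f"{where}: a loss removing everything is an fLoss")
            return

        if len(v.children) != 2:
            raise InvalidHistoryError(f"{where}: must be binary")
        cl, cr = v.children

        if ev.type is EventType.SPE:
            if self.ordered:
                if self._segment(ev, len(X), where) != (1, len(X)):
                    raise InvalidHistoryError(f"{where}: Spe segment must be [1, l]")
            if len(sv.children) != 2:
                raise InvalidHistoryError(f"{where}: speciation at a terminal species")
            expect = {id(sc) for sc in sv.children}
            got = {id(sidx.node(cl.species)), id(sidx.node(cr.species))}
            if expect != got:
                raise InvalidHistoryError(
                    f"{where}: children species must be the two children of {v.species!r}"
                )
            for c in (cl, cr):
                # a child lineage either carries the synteny onward or is
                # lost entirely (fLoss leaf)
                if c.event.type is EventType.FLOSS:
                    continue
                if not self._equal(c.synteny, X):
                    raise InvalidHistoryError(
                        f"{where}: speciation child must carry the same synteny"
                    )
            return

        if ev.type is EventType.DUP:
            for c in (cl, cr):
                if c.species != v.species:
                    raise InvalidHistoryError(f"{where}: duplication changes species")
            # a child branch on which the synteny was entirely lost is an
            # fLoss leaf and carries the empty synteny
            alive = [c for c in (cl, cr) if c.event.type is not EventType.FLOSS]
            if self.ordered:
                i, j = self._segment(ev, len(X), where)
                copied = X[i - 1 : j]
                got = sorted(c.synteny for c in alive)
                want_pairs = {
                    0: [[]],
                    1: [[X], [copied]],
                    2: [sorted([X, copied])],
                }
                if got not in want_pairs[len(alive)]:
                    raise InvalidHistoryError(
                        f"{where}: children must carry X and X[{i},{j}]"
                    )
            else:
                if len(alive) == 2:
                    ok = (cl.synteny == X and cr.synteny <= X) or (
                        cr.synteny == X and cl.synteny <= X
                    )
                else:
                    ok = all(c.synteny <= X for c in alive)
                if not ok:
                    raise InvalidHistoryError(
                        f"{where}: one duplication child must carry the full "
                        "content, the other a subset"
                    )
            return

        raise InvalidHistoryError(f"{where}: unknown event type")  # pragma: no cover

    @staticmethod
    def _segment(ev: Event, length: int, where: str) -> tuple[int, int]:
        if ev.segment is None:
            raise InvalidHistoryError(f"{where}: missing segment")
        i, j = ev.segment
        if not (1 <= i <= j <= length):
            raise InvalidHistoryError(f"{where}: segment [{i},{j}] out of range 1..{length}")
        return i, j


def history_cost(history: LabeledHistory) -> int:
    """Validate ``history`` and return its cost (Dup + pLoss + fLoss count)."""
    history.validate()
    return history.cost()


def check_species_tree(tree: TreeNode) -> TreeNode:
    """Validate a species tree: rooted, binary, unique leaf labels.
    Unnamed internal nodes get fresh ``anc<i>`` labels."""
    from .trees import check_binary, ensure_internal_names

    check_binary(tree, "species tree")
    names = leaf_names(tree)
    if len(set(names)) != len(names):
        raise ValidationError("species tree has duplicate leaf labels")
    return ensure_internal_names(tree)


def check_gene_tree(tree: TreeNode) -> TreeNode:
    from .trees import check_binary

    check_binary(tree, "gene tree")
    names = leaf_names(tree)
    if len(set(names)) != len(names):
        raise ValidationError("gene tree has duplicate leaf labels")
    return tree


def organize(
    syntenies: Sequence[Synteny],
) -> tuple[dict[str, Gene], dict[str, str], dict[str, str]]:
    """Index a synteny family: maps gene id -> Gene, gene id -> synteny id,
    gene id -> family id.  Raises if a gene id repeats across syntenies."""
    from .errors import DuplicateGeneError

    genes: dict[str, Gene] = {}
    syn_of: dict[str, str] = {}
    fam_of: dict[str, str] = {}
    for syn in syntenies:
        for g in syn.genes:
            if g.id in genes:
                raise DuplicateGeneError(f"gene id {g.id!r} occurs twice")
            genes[g.id] = g
            syn_of[g.id] = syn.id
            fam_of[g.id] = g.family
    return genes, syn_of, fam_of
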