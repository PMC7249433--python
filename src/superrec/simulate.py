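"""Ground-truth history simulator.

Generates a segmental duplication/loss history of a single ancestral
synteny over a balanced species tree, then strips it down to the inputs
an inference run would see: the species tree, one gene tree per
surviving family, and the synteny table of the extant leaves.

Five parameters control the process:

* ``t`` — number of gene families in the ancestral synteny (its size);
* ``depth`` — depth of the balanced species tree (``2**depth`` extant
  species);
* ``p_dupl`` — probability that a lineage at an internal species node
  undergoes a segmental duplication (otherwise it speciates);
* ``p_loss`` — probability that a loss occurs on any given child
  branch (drawn independently per child, at most one per branch);
* ``p_length`` — parameter of the shifted geometric law of a loss's
  length: ``P(K = k) = (1 - p_length)**(k - 1) * p_length`` for
  ``k >= 1``.  A drawn length is truncated at the synteny's end; a
  loss covering the whole synteny becomes a full loss (``fLoss``
  leaf).

Duplications copy a substring whose start is uniform and whose length
follows the same shifted geometric law (truncated likewise).  Each
loss's start position is uniform over the synteny.  The drawn
(pre-truncation) loss lengths are recorded on the pLoss/fLoss nodes as
``drawn_length`` for calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .errors import ResourceLimitError, ValidationError
from .model import Event, EventType, Gene, LabeledHistory, Synteny


@dataclass(frozen=True)
class SimulationParams:
    t: int = 5
    depth: int = 5
    p_dupl: float = 0.5
    p_loss: float = 0.5
    p_length: float = 0.5
    seed: int = 0
    max_nodes: int = 50_000

    def __post_init__(self):
        if self.t < 1 or self.depth < 1:
            raise ValidationError("t and depth must be >= 1")
        for p in (self.p_dupl, self.p_loss, self.p_length):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must be in [0, 1]")
        if self.p_length == 0.0:
            raise ValidationError("p_length must be > 0")


def balanced_species_tree(depth: int) -> TreeNode:
    """Complete binary species tree with ``2**depth`` leaves
    ``s0..s{2**depth - 1}`` and named internal nodes."""

    def build(d: int, offset: int) -> TreeNode:
        if d == 0:
            return TreeNode(name=f"s{offset}")
        node = TreeNode(name=f"a{d}_{offset}")
        node.append(build(d - 1, offset))
        node.append(build(d - 1, offset + 2 ** (d - 1)))
        return node

    return build(depth, 0)


def simulate_history(params: SimulationParams) -> LabeledHistory:
    """A valid labeled history over a balanced species tree; the root
    carries families ``f1..f{t}`` in order.  Deterministic for a fixed
    seed."""
    rng = np.random.default_rng(params.seed)
    S = balanced_species_tree(params.depth)
    root_synteny = tuple(f"f{i}" for i in range(1, params.t + 1))
    counter = {"nodes": 0, "extant": 0, "loss": 0}

    def geom(p: float) -> int:
        return 1 if p >= 1.0 else int(rng.geometric(p))

    def bump() -> None:
        counter["nodes"] += 1
        if counter["nodes"] > params.max_nodes:
            raise ResourceLimitError(
                f"simulated history exceeded {params.max_nodes} nodes; "
                "lower p_dupl or raise p_loss"
            )

    def descend(snode: TreeNode, synteny: tuple[str, ...]) -> TreeNode:
        """The subtree evolving from a lineage carrying ``synteny`` that
        has just arrived at species ``snode``."""
        bump()
        if not snode.children:
            leaf = TreeNode(name=f"X{counter['extant']}")
            counter["extant"] += 1
            leaf.synteny = synteny
            leaf.species = snode.name
            leaf.event = Event(EventType.EXTANT)
            return leaf
        if rng.random() < params.p_dupl:
            # segmental duplication within this genome
            l = len(synteny)
            start = int(rng.integers(1, l + 1))
            seg_len = geom(params.p_length)
            end = min(start + seg_len - 1, l)
            copy = synteny[start - 1 : end]
            node = TreeNode()
            node.synteny = synteny
            node.species = snode.name
            node.event = Event(EventType.DUP, (start, end))
            node.append(branch(snode, synteny))
            node.append(branch(snode, copy))
            return node
        node = TreeNode()
        node.synteny = synteny
        node.species = snode.name
        node.event = Event(EventType.SPE, (1, len(synteny)))
        for child in snode.children:
            node.append(branch(child, synteny))
        return node

    def branch(snode: TreeNode, synteny: tuple[str, ...]) -> TreeNode:
        """A child branch: at most one loss, then the next event."""
        if rng.random() >= params.p_loss:
            return descend(snode, synteny)
        l = len(synteny)
        drawn = geom(params.p_length)
        start = int(rng.integers(1, l + 1))
        end = min(start + drawn - 1, l)
        if start == 1 and end == l:
            bump()
            leaf = TreeNode(name=f"L{counter['loss']}")
            counter["loss"] += 1
            leaf.synteny = ()
            leaf.species = snode.name
            leaf.event = Event(EventType.FLOSS)
            leaf.drawn_length = drawn
            return leaf
        bump()
        node = TreeNode()
        node.synteny = synteny
        node.species = snode.name
        node.event = Event(EventType.PLOSS, (start, end))
        node.drawn_length = drawn
        node.append(descend(snode, synteny[: start - 1] + synteny[end:]))
        return node

    root = descend(S, root_synteny)
    history = LabeledHistory(root, S, ordered=True)
    history.meta.update(params=params, root_synteny=root_synteny)
    _name_internal(root)
    return history


def _name_internal(root: TreeNode) -> None:
    i = 0
    for node in root.traverse():
        if node.name is None:
            node.name = f"v{i}"
            i += 1


@dataclass
class StrippedInput:
    """What inference sees, plus the ground truth for benchmarking."""

    species_tree: TreeNode
    gene_trees: list[TreeNode]
    syntenies: list[Synteny]
    family_of: dict[str, str]
    true_cost: int
    true_backbone: TreeNode  # the history's synteny tree, losses removed
    root_order: tuple[str, ...]
    dropped_families: list[str]


def strip_to_input(history: LabeledHistory) -> StrippedInput:
    """Remove loss nodes and internal synteny information, leaving the
    extant syntenies and one gene tree per surviving family.

    Families with no surviving gene are dropped (reported in
    ``dropped_families``).  The stripped inputs are order- and
    tree-consistent by construction.
    """
    root = history.root
    extant = [n for n in root.traverse() if n.event.type is EventType.EXTANT]
    if not extant:
        raise ValidationError("history has no surviving synteny")

    syntenies = []
    for leaf in extant:
        genes = tuple(
            Gene(id=f"{fam}.{leaf.name}", family=fam, species=leaf.species)
            for fam in leaf.synteny
        )
        syntenies.append(Synteny(leaf.name, leaf.species, genes))

    all_fams = history.meta.get("root_synteny") or sorted(
        {g.family for s in syntenies for g in s.genes}
    )
    surviving = {g.family for s in syntenies for g in s.genes}
    dropped = [f for f in all_fams if f not in surviving]

    def project(node: TreeNode, keep) -> TreeNode | None:
        """Restriction of the history to selected extant leaves, unary
        nodes suppressed; leaf names via ``keep`` (None to drop)."""
        if not node.children:
            name = keep(node)
            return TreeNode(name=name) if name else None
        kids = [k for c in node.children if (k := project(c, keep)) is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        out = TreeNode()
        for k in kids:
            out.append(k)
        return out

    gene_trees = []
    for fam in all_fams:
        if fam in dropped:
            continue
        tree = project(
            root,
            lambda n, fam=fam: (
                f"{fam}.{n.name}"
                if n.event.type is EventType.EXTANT and fam in n.synteny
                else None
            ),
        )
        assert tree is not None
        gene_trees.append(tree)

    backbone = project(
        root, lambda n: n.name if n.event.type is EventType.EXTANT else None
    )
    assert backbone is not None

    family_of = {g.id: g.family for s in syntenies for g in s.genes}
    return StrippedInput(
        species_tree=history.species_tree,
        gene_trees=gene_trees,
        syntenies=syntenies,
        family_of=family_of,
        true_cost=history.cost(),
        true_backbone=backbone,
        root_order=tuple(f for f in all_fams if f in surviving),
        dropped_families=dropped,
    )
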