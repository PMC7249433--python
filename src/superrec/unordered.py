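"""The polynomial DP for Unordered Super-Reconciliation (USR).

When rearrangements are allowed for free, only gene *contents* matter:
a node carries a set of families, speciations transmit the set
unchanged, a duplication copies any subset to one child, and one
``pLoss`` suffices to remove any subset on an edge (so at most one
``pLoss`` separates two binary nodes in a parsimonious history).

The duplication and full-loss counts are fixed by the event-labeled,
fLoss-grafted backbone; only partial losses are minimized.  The key
fact is that the *identity* of extra content assigned above a node is
irrelevant: for a node ``v`` with ``lcaSet(v)`` the union of extant
contents below it, the cost of assigning any strict superset of
``lcaSet(v)`` is one number, ``C*(v)``; the cost of assigning
``lcaSet(v)`` itself is ``C_lca(v)``.  Both follow a constant-time
case analysis per node:

* ``C*(v)`` (``v`` gets extra content ``X``): each child either keeps
  ``X`` (cost ``C*``) or drops to its own lca set (cost ``C_lca`` plus
  one loss); when ``v`` is a duplication one of the drops rides the
  partial copy for free — hence the ``spec(v)`` term (1 for a
  speciation, 0 for a duplication).
* ``C_lca(v)``: a child whose lca set equals ``lcaSet(v)`` must simply
  receive it; a child with a smaller lca set either drops (``C_lca`` +
  one loss) or inherits ``lcaSet(v)`` whole (``C*``, no loss); a
  duplication again absorbs one drop.

Grafted ``fLoss`` leaves absorb any content for free (the full loss is
already counted), so they carry ``C_lca = C* = 0``.

Total USR cost = #Dup + #fLoss + C_lca(root); the root content is the
full family set.  Correctness of the case analysis is established
against a brute-force oracle over all subset assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from skbio import TreeNode

from .errors import ValidationError
from .model import Event, EventType, LabeledHistory
from .reconciliation import Backbone

INF = float("inf")


def compute_lca_sets(
    tree: TreeNode, leaf_sets: Mapping[str, frozenset[str]]
) -> dict[int, frozenset[str]]:
    """Bottom-up union of extant gene contents (``lcaSet``); keyed by
    ``id(node)``.  Leaves missing from ``leaf_sets`` (grafted fLoss
    leaves) get the empty set."""
    out: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if not node.children:
            out[id(node)] = frozenset(leaf_sets.get(node.name, frozenset()))
        else:
            out[id(node)] = frozenset().union(*(out[id(c)] for c in node.children))
    return out


@dataclass
class USRResult:
    cost: int
    ploss: int
    assignment: dict[str, frozenset[str]]  # node name -> content
    history: LabeledHistory


def usr_min_cost(backbone: Backbone, leaf_sets: Mapping[str, frozenset[str]]) -> USRResult:
    """Minimum Dup + fLoss + pLoss cost over all unordered histories
    extending the backbone, with the full family set at the root.

    Ties in the backtracking prefer assigning the smaller (lca) set.
    """
    tree = backbone.tree
    lca_sets = compute_lca_sets(tree, leaf_sets)
    fams = lca_sets[id(tree)]

    c_lca: dict[int, float] = {}
    c_star: dict[int, float] = {}
    # backpointers: per node, the per-child choice ("lca" or "star") and
    # which child's drop is absorbed by a partial duplication (-1: none)
    bp_lca: dict[int, tuple[tuple[str, str], int]] = {}
    bp_star: dict[int, tuple[tuple[str, str], int]] = {}

    for v in tree.postorder():
        if not v.children:
            if backbone.is_floss_leaf(v):
                # the full loss is already counted; it absorbs anything
                c_lca[id(v)] = 0.0
                c_star[id(v)] = 0.0
            else:
                if not lca_sets[id(v)]:
                    raise ValidationError(f"extant leaf {v.name!r} has empty content")
                c_lca[id(v)] = 0.0
                c_star[id(v)] = INF
            continue
        if len(v.children) != 2:
            raise ValidationError("backbone must be binary")
        ev = backbone.event(v)
        if ev not in (EventType.SPE, EventType.DUP):
            raise ValidationError(f"node {v.name!r} is not event-labeled")
        spec = 1 if ev is EventType.SPE else 0
        l, r = v.children
        L = lca_sets[id(v)]

        # C*(v): v carries strict extra content
        star_cases = [
            (c_lca[id(l)] + c_lca[id(r)] + 1 + spec, ("lca", "lca")),
            (c_star[id(l)] + c_lca[id(r)] + spec, ("star", "lca")),
            (c_lca[id(l)] + c_star[id(r)] + spec, ("lca", "star")),
            (c_star[id(l)] + c_star[id(r)], ("star", "star")),
        ]
        best, choice = min(star_cases, key=lambda x: x[0])
        c_star[id(v)] = best
        bp_star[id(v)] = (choice, _absorbed(choice, spec))

        # C_lca(v): v carries exactly L
        options_per_child = []
        for child in (l, r):
            Lc = lca_sets[id(child)]
            opts = []
            if Lc == L:
                opts.append((c_lca[id(child)], "lca", 0))  # receives L = its lca set
            else:
                opts.append((c_lca[id(child)], "lca", 1))  # drop: one loss
                opts.append((c_star[id(child)], "star", 0))  # inherit L whole
            options_per_child.append(opts)
        best = INF
        best_choice = None
        for cl, kl, el in options_per_child[0]:
            for cr, kr, er in options_per_child[1]:
                k = el + er
                losses = max(0, k - 1) if ev is EventType.DUP else k
                tot = cl + cr + losses
                if tot < best:
                    best = tot
                    absorbed = -1
                    if ev is EventType.DUP and k >= 1:
                        absorbed = 0 if el else 1
                    best_choice = ((kl, kr), absorbed)
        c_lca[id(v)] = best
        bp_lca[id(v)] = best_choice

    ploss = c_lca[id(tree)]
    if ploss == INF:  # pragma: no cover - cannot happen on a valid backbone
        raise ValidationError("no valid unordered assignment")
    cost = int(ploss) + backbone.n_dup + backbone.n_floss

    assignment: dict[str, frozenset[str]] = {}
    root_h = _backtrack(
        backbone, tree, fams, "lca", lca_sets, bp_lca, bp_star, leaf_sets, assignment
    )
    history = LabeledHistory(root_h, backbone.species_tree, ordered=False)
    from .ordered import _name_nodes

    _name_nodes(history.root)
    return USRResult(cost=cost, ploss=int(ploss), assignment=assignment, history=history)


def _absorbed(choice: tuple[str, str], spec: int) -> int:
    """Index of the child whose drop rides the partial duplication in a
    C* case (-1 if none)."""
    if spec == 1:
        return -1
    if choice == ("lca", "lca"):
        return 0
    if choice[0] == "lca":
        return 0
    if choice[1] == "lca":
        return 1
    return -1


def _backtrack(
    backbone: Backbone,
    v: TreeNode,
    content: frozenset[str],
    kind: str,
    lca_sets,
    bp_lca,
    bp_star,
    leaf_sets,
    assignment,
) -> TreeNode:
    """Materialize the optimal unordered history below ``v`` given its
    assigned ``content``."""
    species = backbone.species_name(v)
    if not v.children:
        out = TreeNode(name=v.name)
        out.species = species
        if backbone.is_floss_leaf(v):
            out.synteny = frozenset()
            out.event = Event(EventType.FLOSS)
        else:
            out.synteny = frozenset(leaf_sets[v.name])
            out.event = Event(EventType.EXTANT)
        assignment[v.name] = out.synteny
        return out

    (choice, absorbed) = (bp_lca if kind == "lca" else bp_star)[id(v)]
    ev = backbone.event(v)
    out = TreeNode(name=v.name)
    out.species = species
    out.synteny = content
    out.event = Event(EventType.SPE if ev is EventType.SPE else EventType.DUP)
    if v.name:
        assignment[v.name] = content

    for idx, child in enumerate(v.children):
        ckind = choice[idx]
        c_content = content if ckind == "star" else lca_sets[id(child)]
        # fLoss leaves absorb the parent content; their own node carries
        # the empty synteny
        sub = _backtrack(
            backbone, child, c_content, ckind, lca_sets, bp_lca, bp_star,
            leaf_sets, assignment,
        )
        needs_loss = (
            c_content != content
            and not backbone.is_floss_leaf(child)
            and idx != absorbed
        )
        if needs_loss:
            ploss = TreeNode()
            ploss.species = backbone.species_name(child) if ev is EventType.SPE else species
            ploss.synteny = content
            ploss.event = Event(EventType.PLOSS)
            ploss.append(sub)
            out.append(ploss)
        else:
            out.append(sub)
    return out
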