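"""The exact small-phylogeny DP for ordered syntenies.

Given a backbone (an event-labeled, fLoss-grafted supertree) and a
candidate ancestral gene order ``A``, the DP assigns to every node a
subsequence of ``A`` (encoded as a bitmask over the positions of ``A``)
so that the total number of segmental events is minimal:

* a speciation transmits its synteny ``X`` to both children; each child
  assignment ``Y`` costs ``D_T(X, Y)`` partial/full losses — the number
  of maximal runs of ``X`` positions absent from ``Y``;
* a duplication costs 1 and copies a substring of ``X``; on the copied
  side the missing prefix and suffix are free, so the child costs
  ``D_P(X, Y)`` — internal gap runs only — while the other side pays
  ``D_T``.  At most one child can be the copy.

Grafted ``fLoss`` leaves are forced to the empty synteny; the transform
``X -> empty`` costs ``D_T(X, ()) = 1``, which is exactly the one full
loss, so full losses need no separate bookkeeping.  The empty
assignment is forbidden everywhere else.

States are ``O(2^t)`` per node (``t`` = number of families), so the
method is exponential in the ancestral synteny size but linear in the
tree size.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Mapping, Sequence

from skbio import TreeNode

from .errors import OrderInconsistencyError, ResourceLimitError, ValidationError
from .model import Event, EventType, LabeledHistory
from .reconciliation import Backbone

INF = float("inf")

#: default cap on the number of DP table cells (nodes x 2^t)
DEFAULT_MAX_TABLE_ENTRIES = 1 << 24


def is_subsequence(sub: Sequence, seq: Sequence) -> bool:
    """True iff ``sub`` is a subsequence of ``seq``."""
    it = iter(seq)
    return all(x in it for x in sub)


def loss_dist_total(X: Sequence[str], Y: Sequence[str]) -> int:
    """``D_T``: minimum number of segmental losses turning ``X`` into its
    subsequence ``Y``.

    With all characters distinct this is the number of maximal runs of
    ``X`` positions absent from ``Y`` (each run is one loss; kept genes
    between runs prevent merging them).  ``D_T(X, X) = 0``;
    ``D_T(X, ()) = 1`` for non-empty ``X`` (one full loss).
    """
    keep = _kept_flags(X, Y)
    runs = 0
    prev = True
    for k in keep:
        if not k and prev:
            runs += 1
        prev = k
    return runs


def loss_dist_partial(X: Sequence[str], Y: Sequence[str]) -> int:
    """``D_P``: minimum number of segmental losses turning some substring
    of ``X`` into ``Y``.

    Choosing the substring spanning the first to the last kept position
    makes prefix and suffix gap runs free, so only internal gap runs
    count.  ``D_P(X, ()) = 0`` (the empty substring).
    """
    keep = _kept_flags(X, Y)
    if not any(keep):
        return 0
    first = keep.index(True)
    last = len(keep) - 1 - keep[::-1].index(True)
    runs = 0
    prev = True
    for k in keep[first : last + 1]:
        if not k and prev:
            runs += 1
        prev = k
    return runs


def _kept_flags(X: Sequence[str], Y: Sequence[str]) -> list[bool]:
    """Per-position flags of ``X``: kept in ``Y`` or lost.  Raises if
    ``Y`` is not a subsequence of ``X``."""
    if len(set(X)) != len(X):
        raise ValidationError("synteny characters must be unique")
    pos = {c: i for i, c in enumerate(X)}
    flags = [False] * len(X)
    prev = -1
    for c in Y:
        i = pos.get(c)
        if i is None or i <= prev:
            raise ValidationError(f"{Y!r} is not a subsequence of {X!r}")
        flags[i] = True
        prev = i
    return flags


# -- bitmask variants over the positions of the root order A -----------


@lru_cache(maxsize=1 << 20)
def _mask_runs_total(X: int, Y: int, nbits: int) -> int:
    runs = 0
    prev = True
    for i in range(nbits):
        if not X >> i & 1:
            continue
        k = bool(Y >> i & 1)
        if not k and prev:
            runs += 1
        prev = k
    return runs


@lru_cache(maxsize=1 << 20)
def _mask_runs_partial(X: int, Y: int, nbits: int) -> int:
    if Y == 0:
        return 0
    sup = [i for i in range(nbits) if X >> i & 1]
    keep = [bool(Y >> i & 1) for i in sup]
    first = keep.index(True)
    last = len(keep) - 1 - keep[::-1].index(True)
    runs = 0
    prev = True
    for k in keep[first : last + 1]:
        if not k and prev:
            runs += 1
        prev = k
    return runs


def _seq_of_mask(mask: int, A: Sequence[str]) -> tuple[str, ...]:
    return tuple(A[i] for i in range(len(A)) if mask >> i & 1)


def _mask_of_leaf(seq: Sequence[str], pos: Mapping[str, int], leaf: str) -> int:
    """Bitmask of a leaf synteny; raises if it is not a subsequence of A."""
    mask = 0
    prev = -1
    for fam in seq:
        i = pos.get(fam)
        if i is None or i <= prev:
            raise OrderInconsistencyError(
                f"extant synteny {leaf!r} ({'-'.join(seq)}) is not a "
                "subsequence of the ancestral order"
            )
        mask |= 1 << i
        prev = i
    return mask


def small_phylogeny_ordered(
    backbone: Backbone,
    ancestral_order: Sequence[str],
    leaf_syntenies: Mapping[str, Sequence[str]],
    max_table_entries: int = DEFAULT_MAX_TABLE_ENTRIES,
) -> tuple[int, LabeledHistory]:
    """Minimum-cost ordered synteny assignment with root ``A``.

    Returns the optimal cost (Dup + pLoss + fLoss) and a labeled history
    extending the backbone that achieves it.  Ties are broken toward the
    smallest bitmask (and toward the left child carrying the duplication
    copy), so the result is deterministic.
    """
    A = tuple(ancestral_order)
    if len(set(A)) != len(A):
        raise ValidationError("ancestral order has repeated families")
    t = len(A)
    pos = {fam: i for i, fam in enumerate(A)}
    tree = backbone.tree

    if not tree.children:
        # single extant synteny: the root is the leaf, which must carry A
        seq = tuple(leaf_syntenies[tree.name])
        _mask_of_leaf(seq, pos, tree.name)
        if seq != A:
            raise OrderInconsistencyError(
                "single extant synteny differs from the ancestral order"
            )
        history = _build_history(backbone, A, leaf_syntenies, {}, {}, 0)
        history.meta.update(ancestral_order=A, dp_cells=0, n_nodes=1, t=t)
        return 0, history

    nodes = list(tree.postorder())
    n_states = 1 << t
    if len(nodes) * n_states > max_table_entries:
        raise ResourceLimitError(
            f"DP table would need {len(nodes)} x 2^{t} entries "
            f"(> {max_table_entries}); t is too large"
        )

    full = n_states - 1
    d: dict[int, list[float]] = {}
    back: dict[int, dict[int, tuple[int, int, int]]] = {}  # v -> X -> (Yl, Yr, copy)
    dp_cells = 0

    for v in nodes:
        if not v.children:
            tab = [INF] * n_states
            if backbone.is_floss_leaf(v):
                tab[0] = 0.0
            else:
                seq = leaf_syntenies[v.name]
                if len(seq) == 0:
                    raise ValidationError(f"extant leaf {v.name!r} has an empty synteny")
                tab[_mask_of_leaf(seq, pos, v.name)] = 0.0
            d[id(v)] = tab
            dp_cells += n_states
            continue

        l, r = v.children
        ev = backbone.event(v)
        tab = [INF] * n_states
        bptr: dict[int, tuple[int, int, int]] = {}
        dl, dr = d[id(l)], d[id(r)]
        for X in range(1, n_states):
            # best total-loss / partial-loss transitions per child
            bestTl = bestTr = bestPl = bestPr = INF
            argTl = argTr = argPl = argPr = -1
            sub = X
            while True:
                cl = dl[sub]
                if cl < INF:
                    c = _mask_runs_total(X, sub, t) + cl
                    if c < bestTl or (c == bestTl and sub < argTl):
                        bestTl, argTl = c, sub
                    c = _mask_runs_partial(X, sub, t) + cl
                    if c < bestPl or (c == bestPl and sub < argPl):
                        bestPl, argPl = c, sub
                cr = dr[sub]
                if cr < INF:
                    c = _mask_runs_total(X, sub, t) + cr
                    if c < bestTr or (c == bestTr and sub < argTr):
                        bestTr, argTr = c, sub
                    c = _mask_runs_partial(X, sub, t) + cr
                    if c < bestPr or (c == bestPr and sub < argPr):
                        bestPr, argPr = c, sub
                if sub == 0:
                    break
                sub = (sub - 1) & X
            if ev is EventType.SPE:
                cost = bestTl + bestTr
                if cost < INF:
                    tab[X] = cost
                    bptr[X] = (argTl, argTr, -1)
            else:  # duplication
                left_copy = bestPl + bestTr
                right_copy = bestTl + bestPr
                if min(left_copy, right_copy) < INF:
                    if left_copy <= right_copy:
                        tab[X] = 1 + left_copy
                        bptr[X] = (argPl, argTr, 0)
                    else:
                        tab[X] = 1 + right_copy
                        bptr[X] = (argTl, argPr, 1)
        d[id(v)] = tab
        back[id(v)] = bptr
        dp_cells += n_states

    cost = d[id(tree)][full]
    if cost == INF:
        raise OrderInconsistencyError(
            "no valid synteny assignment with this ancestral order"
        )

    history = _build_history(backbone, A, leaf_syntenies, d, back, full)
    history.meta.update(
        ancestral_order=A,
        dp_cells=dp_cells,
        n_nodes=len(nodes),
        t=t,
    )
    return int(cost), history


# -- history construction ---------------------------------------------


def _removed_runs(X: Sequence[str], Y: Sequence[str]) -> list[tuple[int, int]]:
    """Maximal runs of positions of ``X`` absent from ``Y``, as 1-based
    closed intervals in ``X`` coordinates."""
    keep = _kept_flags(X, Y)
    runs = []
    start = None
    for i, k in enumerate(keep):
        if not k and start is None:
            start = i
        elif k and start is not None:
            runs.append((start + 1, i))
            start = None
    if start is not None:
        runs.append((start + 1, len(keep)))
    return runs


def _loss_chain(
    X: tuple[str, ...],
    Y: tuple[str, ...],
    species: str,
    bottom: TreeNode,
) -> TreeNode:
    """Chain of pLoss nodes transforming ``X`` into ``Y`` above
    ``bottom`` (which must carry ``Y``); leftmost run removed first.
    Returns the top node (``bottom`` itself if no loss is needed)."""
    runs = _removed_runs(X, Y)
    top = bottom
    # build bottom-up: apply runs right-to-left so each node's synteny is
    # the state before its own loss
    shift = 0
    states = []
    cur = list(X)
    for i, j in runs:
        i0, j0 = i - shift, j - shift
        states.append((tuple(cur), (i0, j0)))
        del cur[i0 - 1 : j0]
        shift += j - i + 1
    assert tuple(cur) == tuple(Y)
    for synteny, seg in reversed(states):
        node = TreeNode()
        node.synteny = synteny
        node.event = Event(EventType.PLOSS, seg)
        node.species = species
        node.append(top)
        top = node
    return top


def _build_history(
    backbone: Backbone,
    A: tuple[str, ...],
    leaf_syntenies: Mapping[str, Sequence[str]],
    d: dict[int, list[float]],
    back: dict[int, dict[int, tuple[int, int, int]]],
    full_mask: int,
) -> LabeledHistory:
    tree = backbone.tree

    def node_for(v: TreeNode, mask: int) -> TreeNode:
        species = backbone.species_name(v)
        if not v.children:
            out = TreeNode(name=v.name)
            out.species = species
            if backbone.is_floss_leaf(v):
                out.synteny = ()
                out.event = Event(EventType.FLOSS)
            else:
                out.synteny = tuple(leaf_syntenies[v.name])
                out.event = Event(EventType.EXTANT)
            return out
        X = _seq_of_mask(mask, A)
        Yl_mask, Yr_mask, copy_side = back[id(v)][mask]
        l, r = v.children
        ev = backbone.event(v)
        out = TreeNode(name=v.name)
        out.species = species
        out.synteny = X
        if ev is EventType.SPE:
            out.event = Event(EventType.SPE, (1, len(X)))
            for child, Yc in ((l, Yl_mask), (r, Yr_mask)):
                sub = node_for(child, Yc)
                csp = backbone.species_name(child)
                if backbone.is_floss_leaf(child):
                    out.append(sub)  # the fLoss leaf itself is the loss
                else:
                    out.append(_loss_chain(X, _seq_of_mask(Yc, A), csp, sub))
            return out
        # duplication
        copy_mask = Yl_mask if copy_side == 0 else Yr_mask
        copy_seq = _seq_of_mask(copy_mask, A)
        pos_in_X = {fam: i + 1 for i, fam in enumerate(X)}
        i, j = pos_in_X[copy_seq[0]], pos_in_X[copy_seq[-1]]
        segment_seq = X[i - 1 : j]
        out.event = Event(EventType.DUP, (i, j))
        for side, (child, Yc) in enumerate(((l, Yl_mask), (r, Yr_mask))):
            sub = node_for(child, Yc)
            start = segment_seq if side == copy_side else X
            out.append(_loss_chain(start, _seq_of_mask(Yc, A), species, sub))
        return out

    if not tree.children:
        root_h = node_for(tree, 0)
    else:
        root_h = node_for(tree, full_mask)
    history = LabeledHistory(root_h, backbone.species_tree, ordered=True)
    _name_nodes(history.root)
    return history


def _name_nodes(root: TreeNode) -> None:
    taken = {n.name for n in root.traverse() if n.name is not None}
    i = 0
    for node in root.traverse():
        if node.name is None:
            while f"n{i}" in taken:
                i += 1
            node.name = f"n{i}"
            taken.add(node.name)
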