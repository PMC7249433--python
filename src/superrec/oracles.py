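"""Brute-force oracles.

Ground truth for the dynamic programs, by exhaustive enumeration at
desk scale.  Everything here is deliberately independent of the DP
code paths: loss distances are shortest paths in the graph of interval
deletions (not the gap-run formula), and the minimum costs are direct
minima over *all* valid per-node assignments with per-edge event
counting.  Size guards refuse instances where enumeration would blow
up.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from typing import Mapping, Sequence

from skbio import TreeNode

from .errors import OracleGuardError
from .model import EventType
from .reconciliation import Backbone

MAX_FAMILIES = 5
MAX_INTERNAL = 25  # counted after fLoss grafting


@lru_cache(maxsize=None)
def brute_loss_dist(X: tuple[str, ...], Y: tuple[str, ...]) -> int:
    """Minimum number of interval deletions transforming ``X`` into
    ``Y``, by breadth-first search over all deletion sequences."""
    if len(X) > 8:
        raise OracleGuardError("brute_loss_dist guard: |X| > 8")
    if X == Y:
        return 0
    frontier = {X}
    seen = {X}
    steps = 0
    while frontier:
        steps += 1
        nxt = set()
        for cur in frontier:
            n = len(cur)
            for i in range(n):
                for j in range(i, n):
                    red = cur[:i] + cur[j + 1 :]
                    if red == Y:
                        return steps
                    if red not in seen and len(red) > len(Y):
                        seen.add(red)
                        nxt.add(red)
        frontier = nxt
    raise ValueError(f"{Y!r} unreachable from {X!r} by deletions")


@lru_cache(maxsize=None)
def brute_loss_dist_partial(X: tuple[str, ...], Y: tuple[str, ...]) -> int:
    """Minimum deletions transforming some substring of ``X`` into
    ``Y`` (brute force over all substrings, including the empty one)."""
    best = None
    n = len(X)
    subs = [()] + [X[i:j] for i in range(n) for j in range(i + 1, n + 1)]
    for W in subs:
        if not _is_subseq(Y, W):
            continue
        d = brute_loss_dist(W, Y)
        if best is None or d < best:
            best = d
    if best is None:
        raise ValueError(f"{Y!r} is not a subsequence of any substring of {X!r}")
    return best


def _is_subseq(sub: Sequence, seq: Sequence) -> bool:
    it = iter(seq)
    return all(x in it for x in sub)


def _subsequences(seq: tuple[str, ...]):
    out = []
    for k in range(len(seq) + 1):
        out.extend(combinations(seq, k))
    return out


def _guard(backbone: Backbone, n_fams: int) -> None:
    internal = sum(1 for n in backbone.tree.traverse() if n.children)
    if n_fams > MAX_FAMILIES or internal > MAX_INTERNAL:
        raise OracleGuardError(
            f"oracle guard exceeded: {n_fams} families, {internal} internal nodes"
        )


def oracle_ordered(
    backbone: Backbone,
    ancestral_order: Sequence[str],
    leaf_syntenies: Mapping[str, Sequence[str]],
) -> int:
    """Exact minimum ordered cost by enumerating every valid synteny
    assignment (subsequences of ``A`` at internal nodes, root = ``A``,
    leaves fixed) and counting events edge by edge."""
    A = tuple(ancestral_order)
    _guard(backbone, len(A))
    tree = backbone.tree

    content: dict[int, tuple[str, ...]] = {}
    required: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if not node.children:
            if backbone.is_floss_leaf(node):
                content[id(node)] = ()
            else:
                content[id(node)] = tuple(leaf_syntenies[node.name])
            required[id(node)] = frozenset(content[id(node)])
        else:
            required[id(node)] = frozenset().union(
                *(required[id(c)] for c in node.children)
            )

    cache: dict[tuple[int, tuple[str, ...]], float] = {}

    def best(v: TreeNode, X: tuple[str, ...]) -> float:
        """Minimum events in the subtree of v when v's parent sends X
        down the edge into v (before v's own event)."""
        key = (id(v), X)
        if key in cache:
            return cache[key]
        out = _best(v, X)
        cache[key] = out
        return out

    def _best(v: TreeNode, X: tuple[str, ...]) -> float:
        if not v.children:
            target = content[id(v)]
            if not _is_subseq(target, X):
                return float("inf")
            return brute_loss_dist(X, target)
        ev = backbone.event(v)
        # v's assignment Y: any subsequence of X covering the extant
        # content below v
        need = required[id(v)]
        total_best = float("inf")
        for Y in _subsequences(X):
            if not need <= set(Y):
                continue
            edge_cost = brute_loss_dist(X, Y)
            l, r = v.children
            if ev is EventType.SPE:
                down = best_from(l, Y) + best_from(r, Y)
                sub_cost = down
            else:
                # duplication: one child receives Y, the copy receives a
                # substring of Y obtained with partial-loss freedom
                sub_cost = 1 + min(
                    best_copy(l, Y) + best_from(r, Y),
                    best_from(l, Y) + best_copy(r, Y),
                )
            total_best = min(total_best, edge_cost + sub_cost)
        return total_best

    def best_from(v: TreeNode, X: tuple[str, ...]) -> float:
        """As best() but the edge into v transmits X exactly (losses on
        the edge are charged inside best())."""
        return best(v, X)

    def best_copy(v: TreeNode, X: tuple[str, ...]) -> float:
        """Copy side of a duplication: the child receives any substring
        of X; internal losses below are charged normally."""
        if not v.children:
            target = content[id(v)]
            if not _is_subseq(target, X):
                return float("inf")
            return brute_loss_dist_partial(X, target)
        # the copy takes a substring W of X, then the subtree hangs off W
        out = float("inf")
        n = len(X)
        subs = [X[i:j] for i in range(n) for j in range(i + 1, n + 1)]
        for W in subs:
            out = min(out, best(v, W))
        return out

    # the root node carries A itself: no edge above it
    root = tree
    if not root.children:
        return 0 if content[id(root)] == A else float("inf")
    ev = backbone.event(root)
    l, r = root.children
    if ev is EventType.SPE:
        return int(best(l, A) + best(r, A))
    return int(1 + min(best_copy(l, A) + best(r, A), best(l, A) + best_copy(r, A)))


def oracle_unordered(
    backbone: Backbone, leaf_sets: Mapping[str, frozenset[str]]
) -> int:
    """Exact minimum unordered cost by enumerating all per-node subset
    assignments between ``lcaSet(v)`` and the full family set."""
    return _oracle_unordered_impl(backbone, leaf_sets, forced=None)


def oracle_unordered_forced(
    backbone: Backbone,
    leaf_sets: Mapping[str, frozenset[str]],
    node_name: str,
    forced_set: frozenset[str],
) -> float:
    """As :func:`oracle_unordered` but with one internal node's content
    pinned; used to probe that the identity of extra content is
    irrelevant."""
    return _oracle_unordered_impl(backbone, leaf_sets, forced=(node_name, forced_set))


def _oracle_unordered_impl(backbone, leaf_sets, forced):
    from .unordered import compute_lca_sets

    tree = backbone.tree
    lca_sets = compute_lca_sets(tree, leaf_sets)
    fams = sorted(lca_sets[id(tree)])
    _guard(backbone, len(fams))
    base = backbone.n_dup + backbone.n_floss

    def supersets(low: frozenset[str]):
        extra = [f for f in fams if f not in low]
        for k in range(len(extra) + 1):
            for combo in combinations(extra, k):
                yield low | frozenset(combo)

    cache: dict[tuple[int, frozenset], float] = {}

    def rec(v: TreeNode, sent: frozenset[str]) -> float:
        """Min pLoss count below v when v's parent sends `sent` into v
        (Spe edge or duplication-original edge semantics are handled by
        the caller; here `sent` is what v may keep or reduce from)."""
        key = (id(v), sent)
        if key in cache:
            return cache[key]
        out = _rec(v, sent)
        cache[key] = out
        return out

    def _rec(v: TreeNode, sent: frozenset[str]) -> float:
        if not v.children:
            if backbone.is_floss_leaf(v):
                return 0.0  # absorbs anything
            target = frozenset(leaf_sets[v.name])
            if target == sent:
                return 0.0
            if target < sent:
                return 1.0  # one pLoss on the edge into the leaf
            return float("inf")
        ev = backbone.event(v)
        best = float("inf")
        for Y in supersets(lca_sets[id(v)]):
            if not Y <= sent:
                continue
            if forced is not None and v.name == forced[0] and Y != forced[1]:
                continue
            edge = 0 if Y == sent else 1  # one pLoss reduces any subset
            l, r = v.children
            if ev is EventType.SPE:
                down = rec(l, Y) + rec(r, Y)
            else:
                # one child is the original (receives Y, may reduce with a
                # pLoss), the other the copy (receives any subset free)
                down = min(
                    copy_side(l, Y) + rec(r, Y),
                    rec(l, Y) + copy_side(r, Y),
                )
            best = min(best, edge + down)
        return best

    def copy_side(v: TreeNode, Y: frozenset[str]) -> float:
        if not v.children:
            if backbone.is_floss_leaf(v):
                return 0.0
            target = frozenset(leaf_sets[v.name])
            return 0.0 if target <= Y else float("inf")
        out = float("inf")
        for Z in supersets(lca_sets[id(v)]):
            if Z <= Y:
                out = min(out, rec_at(v, Z))
        return out

    def rec_at(v: TreeNode, Y: frozenset[str]) -> float:
        """Min pLoss below v when v is assigned exactly Y."""
        if forced is not None and v.name == forced[0] and Y != forced[1]:
            return float("inf")
        ev = backbone.event(v)
        l, r = v.children
        if ev is EventType.SPE:
            return rec(l, Y) + rec(r, Y)
        return min(copy_side(l, Y) + rec(r, Y), rec(l, Y) + copy_side(r, Y))

    root = tree
    F = frozenset(fams)
    if not root.children:
        return base + (0 if frozenset(leaf_sets[root.name]) == F else float("inf"))
    return base + rec_at(root, F)


def oracle_classic_dl(
    gene_tree: TreeNode,
    species_of_leaf: Mapping[str, str],
    species_tree: TreeNode,
) -> int:
    """Independent duplication-loss cost: LCA-map, then count events by
    explicitly walking species paths edge by edge (textbook identity:
    losses(v -> c) = dist(s(v), s(c)) - [v is Spe])."""
    from .model import _SpeciesIndex
    from .reconciliation import lca_mapping

    sidx = _SpeciesIndex(species_tree)
    smap = lca_mapping(gene_tree, species_of_leaf, sidx)
    if not gene_tree.children:
        return 0
    dups = losses = 0
    for node in gene_tree.traverse():
        if not node.children:
            continue
        l, r = node.children
        spe = sidx.separated(smap[id(l)], smap[id(r)])
        if not spe:
            dups += 1
        for c in node.children:
            path = sidx.path_down(smap[id(node)], smap[id(c)])
            skipped = len(path) - 1 - (1 if spe else 0)
            losses += skipped
    return dups + losses
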