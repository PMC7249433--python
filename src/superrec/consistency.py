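"""Existence conditions: gene-order consistency and tree consistency.

A set of syntenies can descend from a single ancestral gene order only
if the *precedence graph* — one vertex per gene family, an edge
``(i, j)`` whenever some synteny places a family-``i`` gene before a
family-``j`` gene — is acyclic; every topological sort of the graph is
then a candidate ancestral order, and every input synteny is a
subsequence of every such sort.

A Super-Reconciliation must display every input synteny tree, so the
trees must be jointly compatible.  :func:`build_supertree` is the
classical BUILD (Aho) algorithm on the trees' rooted triplets;
:func:`enumerate_binary_supertrees` enumerates all binary trees
displaying every input, by recursively bipartitioning the triplet-graph
components (each binary supertree's root split must keep every
component whole, and conversely every bipartition of components
extends, so each supertree is produced exactly once).

Note that the pairwise shared-triplet probe :func:`triplet_consistent`
is a necessary condition only: three trees with pairwise-disjoint
triple overlaps can still be jointly incompatible.  BUILD is the
decision procedure.
"""

from __future__ import annotations

import warnings
from itertools import islice
from typing import Iterable, Sequence

import networkx as nx
from skbio import TreeNode

from .errors import OrderInconsistencyError, TreeInconsistencyError
from .model import Synteny
from .trees import canonical_newick, leaf_names, rooted_triplets

DEFAULT_LIMIT = 10_000


def build_precedence_graph(syntenies: Sequence[Synteny]) -> nx.DiGraph:
    """Directed graph over gene families with an edge ``(i, j)`` for
    every ordered pair of families in a common synteny (all pairs, not
    only adjacencies)."""
    g = nx.DiGraph()
    fams = sorted({gene.family for syn in syntenies for gene in syn.genes})
    g.add_nodes_from(fams)
    for syn in syntenies:
        seq = syn.families
        for a in range(len(seq)):
            for b in range(a + 1, len(seq)):
                g.add_edge(seq[a], seq[b])
    return g


def is_order_consistent(graph: nx.DiGraph) -> bool:
    """True iff the precedence graph is acyclic (an ancestral gene
    order exists)."""
    return nx.is_directed_acyclic_graph(graph)


def enumerate_ancestral_orders(
    graph: nx.DiGraph, limit: int = DEFAULT_LIMIT
) -> list[tuple[str, ...]]:
    """All topological sorts of the precedence graph, i.e. all candidate
    ancestral syntenies, in lexicographic order.

    Emits every sort when their count is at most ``limit``; otherwise
    the first ``limit`` found are returned (sorted) and a warning is
    issued.
    """
    if not is_order_consistent(graph):
        raise OrderInconsistencyError(
            "precedence graph is cyclic: no ordered ancestral synteny exists"
        )
    sorts = [tuple(s) for s in islice(nx.all_topological_sorts(graph), limit + 1)]
    if len(sorts) > limit:
        warnings.warn(
            f"more than {limit} ancestral orders; enumeration truncated",
            stacklevel=2,
        )
        sorts = sorts[:limit]
    return sorted(sorts)


def _triplet_topology(tree: TreeNode, triple: tuple[str, str, str]):
    """Which pair of ``triple`` forms the cherry in ``tree`` (None if
    unresolved)."""
    from .trees import restrict

    r = restrict(tree, triple)
    if len(r.children) != 2:
        return None
    for child in r.children:
        names = leaf_names(child)
        if len(names) == 2:
            return frozenset(names)
    return None


def triplet_consistent(trees: Sequence[TreeNode]) -> bool:
    """Pairwise shared-triplet check: for every 3-subset of leaves
    shared by two or more trees, all restrictions agree.

    Necessary (not sufficient) for a common supertree to exist.
    """
    leafsets = [frozenset(leaf_names(t)) for t in trees]
    seen: dict[frozenset, object] = {}
    for t, ls in zip(trees, leafsets):
        if len(ls) < 3:
            continue
        for a, b, c in rooted_triplets(t):
            key = frozenset((a, b, c))
            topo = frozenset((a, b))
            if key in seen and seen[key] != topo:
                return False
            seen.setdefault(key, topo)
    return True


def _collect_triples(trees: Iterable[TreeNode]) -> set[tuple[str, str, str]]:
    triples: set[tuple[str, str, str]] = set()
    for t in trees:
        for a, b, c in rooted_triplets(t):
            triples.add((a, b, c) if a < b else (b, a, c))
    return triples


def _aho_components(leaves: list[str], triples) -> list[list[str]]:
    g = nx.Graph()
    g.add_nodes_from(leaves)
    here = set(leaves)
    for a, b, c in triples:
        if a in here and b in here and c in here:
            g.add_edge(a, b)
    return [sorted(comp) for comp in nx.connected_components(g)]


def build_supertree(trees: Sequence[TreeNode]) -> TreeNode:
    """BUILD: a (possibly non-binary) supertree displaying every input
    tree, or :class:`TreeInconsistencyError` if none exists."""
    trees = list(trees)
    if not trees:
        raise TreeInconsistencyError("no input trees")
    leaves = sorted({name for t in trees for name in leaf_names(t)})
    triples = _collect_triples(trees)

    def rec(names: list[str]) -> TreeNode:
        if len(names) == 1:
            return TreeNode(name=names[0])
        comps = sorted(_aho_components(names, triples), key=lambda c: c[0])
        if len(comps) == 1:
            raise TreeInconsistencyError(
                "synteny trees are incompatible: no supertree displays them all"
            )
        node = TreeNode()
        for comp in comps:
            node.append(rec(comp))
        return node

    return rec(leaves)


def enumerate_binary_supertrees(
    trees: Sequence[TreeNode], limit: int = DEFAULT_LIMIT
) -> list[TreeNode]:
    """All rooted binary trees on the union of the inputs' leaves that
    display every input, sorted by canonical Newick.

    When their number exceeds ``limit`` the list is truncated (after
    deterministic generation order) and a warning is issued.
    """
    trees = list(trees)
    leaves = sorted({name for t in trees for name in leaf_names(t)})
    if not leaves:
        raise TreeInconsistencyError("no leaves")
    triples = _collect_triples(trees)

    out: list[TreeNode] = []
    truncated = False

    def rec(names: list[str]):
        # yields binary trees on `names` consistent with the triples
        if len(names) == 1:
            yield TreeNode(name=names[0])
            return
        comps = sorted(_aho_components(names, triples), key=lambda c: c[0])
        if len(comps) == 1:
            return  # incompatible below this point
        k = len(comps)
        # unordered bipartitions of the components: fix component 0 on
        # the left side
        for mask in range(2 ** (k - 1)):
            left = [comps[0]]
            right = []
            for i in range(1, k):
                (left if mask >> (i - 1) & 1 else right).append(comps[i])
            if not right:
                continue
            lnames = sorted(n for comp in left for n in comp)
            rnames = sorted(n for comp in right for n in comp)
            for lt in rec(lnames):
                for rt in rec(rnames):
                    node = TreeNode()
                    node.append(lt.copy())
                    node.append(rt.copy())
                    yield node

    gen = rec(leaves)
    for tree in gen:
        out.append(tree)
        if len(out) > limit:
            truncated = True
            out.pop()
            break
    if not out:
        raise TreeInconsistencyError(
            "synteny trees are incompatible: no supertree displays them all"
        )
    if truncated:
        warnings.warn(f"more than {limit} binary supertrees; enumeration truncated",
                      stacklevel=2)
    dedup = {canonical_newick(t): t for t in out}
    return [dedup[k] for k in sorted(dedup)]
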