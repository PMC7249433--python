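"""The end-to-end Super-Reconciliation search.

The framework: (1) enumerate the order-consistent ancestral syntenies
(topological sorts of the precedence graph); (2) enumerate the binary
supertrees of the input synteny trees; (3) for each (order, supertree)
pair run the small-phylogeny DP; (4) keep the pairs achieving the
minimum cost.  Both enumeration spaces can be exponential, so each is
capped; truncation is reported in the result rather than silently
changing the optimum's meaning.

The unordered variant skips step (1): gene orders are ignored and the
per-supertree optimum is polynomial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from skbio import TreeNode

from .consistency import (
    build_precedence_graph,
    enumerate_ancestral_orders,
    enumerate_binary_supertrees,
    is_order_consistent,
)
from .errors import OrderInconsistencyError, TreeInconsistencyError
from .io import history_to_newick
from .model import (
    LabeledHistory,
    Synteny,
    check_gene_tree,
    check_species_tree,
    organize,
    synteny_tree_of,
)
from .ordered import small_phylogeny_ordered
from .reconciliation import Backbone
from .trees import canonical_newick, leaf_names
from .unordered import usr_min_cost

DEFAULT_MAX_ORDERS = 10_000
DEFAULT_MAX_SUPERTREES = 10_000
DEFAULT_MAX_OPTIMA = 100


@dataclass
class Optimum:
    """One optimal (ancestral order, supertree) pair and its history."""

    ancestral_order: tuple[str, ...] | None
    supertree: TreeNode
    history: LabeledHistory


@dataclass
class SearchResult:
    cost: int
    optima: list[Optimum]
    mode: str
    n_orders: int = 0
    n_supertrees: int = 0
    orders_truncated: bool = False
    supertrees_truncated: bool = False
    optima_truncated: bool = False

    @property
    def histories(self) -> list[LabeledHistory]:
        return [o.history for o in self.optima]

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "cost": self.cost,
            "n_optima": len(self.optima),
            "n_orders": self.n_orders,
            "n_supertrees": self.n_supertrees,
            "orders_truncated": self.orders_truncated,
            "supertrees_truncated": self.supertrees_truncated,
            "optima_truncated": self.optima_truncated,
        }


def check_consistency(
    species_tree: TreeNode,
    gene_trees: Sequence[TreeNode],
    syntenies: Sequence[Synteny],
) -> dict:
    """Report order and tree consistency, with (possibly truncated)
    counts of candidate ancestral orders and binary supertrees."""
    synteny_trees, _, _ = _prepare(species_tree, gene_trees, syntenies)
    graph = build_precedence_graph(syntenies)
    order_ok = is_order_consistent(graph)
    out = {
        "order_consistent": order_ok,
        "n_ancestral_orders": None,
        "tree_consistent": None,
        "n_binary_supertrees": None,
    }
    if order_ok:
        out["n_ancestral_orders"] = len(enumerate_ancestral_orders(graph))
    try:
        sts = enumerate_binary_supertrees(synteny_trees)
        out["tree_consistent"] = True
        out["n_binary_supertrees"] = len(sts)
    except TreeInconsistencyError:
        out["tree_consistent"] = False
    return out


def _prepare(species_tree, gene_trees, syntenies):
    check_species_tree(species_tree)
    for t in gene_trees:
        check_gene_tree(t)
    genes, syn_of, fam_of = organize(syntenies)
    for t in gene_trees:
        for name in leaf_names(t):
            if name not in syn_of:
                from .errors import UnknownGeneError

                raise UnknownGeneError(f"gene {name!r} is not in the synteny table")
    synteny_trees = [synteny_tree_of(t, syn_of) for t in gene_trees]
    species_of_synteny = {s.id: s.species for s in syntenies}
    return synteny_trees, species_of_synteny, fam_of


def super_reconcile(
    species_tree: TreeNode,
    gene_trees: Sequence[TreeNode],
    syntenies: Sequence[Synteny],
    mode: str = "ordered",
    max_orders: int = DEFAULT_MAX_ORDERS,
    max_supertrees: int = DEFAULT_MAX_SUPERTREES,
    max_optima: int = DEFAULT_MAX_OPTIMA,
) -> SearchResult:
    """Minimum-cost Super-Reconciliation over all explored (ancestral
    order, supertree) pairs.

    Raises :class:`OrderInconsistencyError` if gene orders conflict
    (``mode="ordered"`` only; the unordered model remains applicable)
    and :class:`TreeInconsistencyError` if the synteny trees admit no
    supertree (fatal for both modes).
    """
    if mode not in ("ordered", "unordered"):
        raise ValueError(f"unknown mode {mode!r}")
    synteny_trees, species_of_synteny, fam_of = _prepare(
        species_tree, gene_trees, syntenies
    )
    leaf_orders = {s.id: s.families for s in syntenies}
    leaf_sets = {s.id: s.family_set for s in syntenies}

    orders: list[tuple[str, ...] | None]
    orders_truncated = False
    if mode == "ordered":
        graph = build_precedence_graph(syntenies)
        if not is_order_consistent(graph):
            raise OrderInconsistencyError(
                "gene orders are inconsistent: no ordered Super-Reconciliation "
                "exists (the unordered model may still apply)"
            )
        import warnings as _w

        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            orders = list(enumerate_ancestral_orders(graph, limit=max_orders))
        orders_truncated = any("truncated" in str(c.message) for c in caught)
    else:
        orders = [None]

    import warnings as _w

    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        supertrees = enumerate_binary_supertrees(synteny_trees, limit=max_supertrees)
    supertrees_truncated = any("truncated" in str(c.message) for c in caught)

    best_cost: int | None = None
    optima: list[Optimum] = []
    seen: set[str] = set()
    optima_truncated = False

    for st in supertrees:
        backbone = Backbone(st, species_of_synteny, species_tree)
        for A in orders:
            if mode == "ordered":
                cost, history = small_phylogeny_ordered(backbone, A, leaf_orders)
            else:
                res = usr_min_cost(backbone, leaf_sets)
                cost, history = res.cost, res.history
            if best_cost is None or cost < best_cost:
                best_cost = cost
                optima = []
                seen = set()
                optima_truncated = False
            if cost == best_cost:
                key = canonical_newick(st) + "//" + history_to_newick(history)
                if key in seen:
                    continue
                if len(optima) >= max_optima:
                    optima_truncated = True
                    continue
                seen.add(key)
                optima.append(Optimum(A, st, history))

    assert best_cost is not None
    return SearchResult(
        cost=best_cost,
        optima=optima,
        mode=mode,
        n_orders=len(orders) if mode == "ordered" else 0,
        n_supertrees=len(supertrees),
        orders_truncated=orders_truncated,
        supertrees_truncated=supertrees_truncated,
        optima_truncated=optima_truncated,
    )
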