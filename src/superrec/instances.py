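"""Desk-scale instance generators for oracle cross-checks.

The dynamic programs are certified against brute force on two sweeps:

* an exhaustive sweep over every backbone topology with up to a few
  leaves, every assignment of non-empty subsequences of the ancestral
  order to the leaves, and a fixed two-species tree with alternating
  leaf species;
* random instances with a random species tree, topology, leaf species
  and leaf contents.

Each instance bundles a ready :class:`~superrec.reconciliation.Backbone`
with the leaf syntenies, so a caller can run the DP and the oracle side
by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator

import numpy as np
from skbio import TreeNode

from .reconciliation import Backbone
from .trees import all_binary_topologies, parse_newick


@dataclass
class Instance:
    """One small-phylogeny instance: a prepared backbone, the ancestral
    order, and the extant leaf syntenies (ordered tuples)."""

    backbone: Backbone
    ancestral_order: tuple[str, ...]
    leaf_syntenies: dict[str, tuple[str, ...]]

    @property
    def leaf_sets(self) -> dict[str, frozenset[str]]:
        return {k: frozenset(v) for k, v in self.leaf_syntenies.items()}


def _nonempty_subsequences(A: tuple[str, ...]) -> list[tuple[str, ...]]:
    out = []
    for k in range(1, len(A) + 1):
        out.extend(combinations(A, k))
    return out


def exhaustive_ordered_instances(t: int = 3, max_leaves: int = 4) -> Iterator[Instance]:
    """Every backbone topology on up to ``max_leaves`` leaves, with every
    assignment of non-empty subsequences of ``A = (f1..ft)`` to the
    leaves; two species, leaves assigned alternately."""
    A = tuple(f"f{i}" for i in range(1, t + 1))
    subseqs = _nonempty_subsequences(A)
    species_tree = parse_newick("(spA,spB);")
    for n in range(1, max_leaves + 1):
        leaves = [f"X{i}" for i in range(n)]
        species_of = {leaf: ("spA" if i % 2 == 0 else "spB") for i, leaf in enumerate(leaves)}
        for topo in all_binary_topologies(leaves):
            if n == 1:
                # a single extant synteny must be the ancestral order itself
                backbone = Backbone(topo, species_of, species_tree.copy())
                yield Instance(backbone, A, {leaves[0]: A})
                continue
            for combo in _product_indices(len(subseqs), n):
                leaf_syn = {leaves[i]: subseqs[c] for i, c in enumerate(combo)}
                backbone = Backbone(topo, species_of, species_tree.copy())
                yield Instance(backbone, A, leaf_syn)


def _product_indices(base: int, length: int):
    idx = [0] * length
    while True:
        yield tuple(idx)
        for i in range(length - 1, -1, -1):
            idx[i] += 1
            if idx[i] < base:
                break
            idx[i] = 0
        else:
            return


def _random_species_tree(rng: np.random.Generator, n_species: int) -> TreeNode:
    names = [f"sp{i}" for i in range(n_species)]
    nodes = [TreeNode(name=nm) for nm in names]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        p = TreeNode()
        p.append(a)
        p.append(b)
        nodes.append(p)
    return nodes[0]


def _random_topology(rng: np.random.Generator, leaves: list[str]) -> TreeNode:
    nodes = [TreeNode(name=nm) for nm in leaves]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        p = TreeNode()
        p.append(a)
        p.append(b)
        nodes.append(p)
    return nodes[0]


def random_instance(
    rng: np.random.Generator,
    t: int = 4,
    max_leaves: int = 5,
    max_species: int = 4,
) -> Instance:
    """A random small-phylogeny instance: random species tree, random
    backbone topology, random non-empty subsequence of a shuffled
    ancestral order at each leaf."""
    A = tuple(f"f{i}" for i in rng.permutation(np.arange(1, t + 1)))
    n_species = int(rng.integers(2, max_species + 1))
    species_tree = _random_species_tree(rng, n_species)
    n_leaves = int(rng.integers(1, max_leaves + 1))
    leaves = [f"X{i}" for i in range(n_leaves)]
    topo = _random_topology(rng, leaves)
    subseqs = _nonempty_subsequences(A)
    leaf_syn = {}
    species_of = {}
    for leaf in leaves:
        leaf_syn[leaf] = A if n_leaves == 1 else subseqs[int(rng.integers(len(subseqs)))]
        species_of[leaf] = f"sp{int(rng.integers(n_species))}"
    backbone = Backbone(topo, species_of, species_tree)
    return Instance(backbone, A, leaf_syn)
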