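"""Existence conditions: when can a set of syntenies share one history?

Two checks must pass before any Super-Reconciliation exists: the gene
orders must admit a common ancestral order (the precedence graph over
families must be acyclic), and the per-family trees must be compatible
(a supertree of the synteny trees must exist).
"""

from superrec import (
    Gene,
    Synteny,
    build_precedence_graph,
    enumerate_ancestral_orders,
    is_order_consistent,
    parse_newick,
    check_consistency,
)


def syn(sid, species, fams):
    return Synteny(sid, species, tuple(Gene(f"{f}.{sid}", f, species) for f in fams))


# two genomes; three families a, b, c arranged in four syntenies
species_tree = parse_newick("(A,B);")
syntenies = [
    syn("A1", "A", "abc"),
    syn("A2", "A", "bc"),
    syn("B1", "B", "abc"),
    syn("B2", "B", "c"),
]
gene_trees = [
    parse_newick("(a.A1,a.B1);"),
    parse_newick("((b.A1,b.B1),b.A2);"),
    parse_newick("((c.A1,c.B1),(c.A2,c.B2));"),
]

graph = build_precedence_graph(syntenies)
print("precedence edges:", sorted(graph.edges))
print("order consistent:", is_order_consistent(graph))
print("candidate ancestral orders:", enumerate_ancestral_orders(graph))

report = check_consistency(species_tree, gene_trees, syntenies)
print("tree consistent:", report["tree_consistent"])
print("binary supertrees:", report["n_binary_supertrees"])

# Every synteny places a before b before c, so the only possible
# ancestral gene order is a-b-c; the three gene trees are compatible
# and admit exactly one binary supertree: the search space is tiny.

# A conflicting pair of orders (a before b in one genome, b before a in
# the other) makes the precedence graph cyclic: no ordered history can
# produce both by losses alone.
bad = [syn("y1", "A", "ab"), syn("y2", "B", "ba")]
print("conflicting orders consistent:",
      is_order_consistent(build_precedence_graph(bad)))
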