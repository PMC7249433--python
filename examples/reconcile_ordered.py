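"""Minimum-cost ordered Super-Reconciliation of a small instance.

The search enumerates ancestral gene orders and binary supertrees, runs
the small-phylogeny DP on each pair, and reports the optimum: a single
history of segmental duplications and losses explaining all four
syntenies from one ancestral synteny.
"""

from superrec import Gene, Synteny, history_to_newick, parse_newick, super_reconcile
from superrec.io import history_event_table


def syn(sid, species, fams):
    return Synteny(sid, species, tuple(Gene(f"{f}.{sid}", f, species) for f in fams))


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

result = super_reconcile(species_tree, gene_trees, syntenies, mode="ordered")
print("minimum cost:", result.cost)           # duplications + losses
print("optimal histories:", len(result.optima))
best = result.optima[0]
print("ancestral order:", "-".join(best.ancestral_order))
print()
print("event log of the optimal history:")
for node, event, species, synteny, segment in history_event_table(best.history):
    print(f"  {node:>6}  {event:<7} species={species:<5} synteny={synteny:<6} {segment}")
print()
print(history_to_newick(best.history))

# The cost counts Dup, pLoss and fLoss events (speciations are free).
# Each internal node of the printed history carries the gene order
# assigned to the ancestral synteny at that point and the segment the
# event copied or removed.
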