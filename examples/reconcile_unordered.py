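"""Unordered Super-Reconciliation: rearrangements for free.

When genomes are distant, conserved gene order is too much to ask: the
unordered model keeps segmental duplications and losses but ignores
gene order (any rearrangement is free), which makes the problem
polynomial.  It applies even when the ordered model has no solution.
"""

from superrec import Gene, Synteny, parse_newick, super_reconcile
from superrec.errors import OrderInconsistencyError


def syn(sid, species, fams):
    return Synteny(sid, species, tuple(Gene(f"{f}.{sid}", f, species) for f in fams))


species_tree = parse_newick("(A,B);")
# conflicting orders: a-b in genome A, b-a in genome B
syntenies = [syn("X1", "A", "ab"), syn("X2", "B", "ba")]
gene_trees = [parse_newick("(a.X1,a.X2);"), parse_newick("(b.X1,b.X2);")]

try:
    super_reconcile(species_tree, gene_trees, syntenies, mode="ordered")
except OrderInconsistencyError as exc:
    print("ordered model:", exc)

result = super_reconcile(species_tree, gene_trees, syntenies, mode="unordered")
print("unordered minimum cost:", result.cost)
best = result.optima[0]
for node in best.history.nodes():
    fams = ",".join(sorted(node.synteny)) or "-"
    print(f"  {node.name:>4} {node.event.type:<7} {{{fams}}} in {node.species}")

# Cost 0: both syntenies carry the same gene content {a, b}, so a
# single speciation explains them; the order flip is attributed to a
# rearrangement, which this model does not charge for.
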