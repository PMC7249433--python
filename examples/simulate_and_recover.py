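"""Simulate a ground-truth history, strip it, and infer a history back.

The simulator evolves an ancestral synteny of t families down a
balanced species tree of the given depth, with segmental duplications
(probability p_dupl per lineage at an internal species), at most one
segmental loss per child branch (probability p_loss, shifted-geometric
length), then strips the result to what an inference run would see.
Parsimony can only undershoot: the inferred cost is at most the number
of simulated events.
"""

from superrec import SimulationParams, simulate_history, strip_to_input
from superrec.ordered import small_phylogeny_ordered
from superrec.reconciliation import Backbone
from superrec.unordered import usr_min_cost

params = SimulationParams(t=5, depth=5, p_dupl=0.5, p_loss=0.5, p_length=0.5, seed=7)
history = simulate_history(params)
history.validate()
print("simulated events (Dup + pLoss + fLoss):", history.cost())

stripped = strip_to_input(history)
print("extant syntenies:", len(stripped.syntenies),
      "| surviving families:", len(stripped.gene_trees),
      "| extinct families:", stripped.dropped_families)

backbone = Backbone(
    stripped.true_backbone,
    {s.id: s.species for s in stripped.syntenies},
    stripped.species_tree,
)
cost, inferred = small_phylogeny_ordered(
    backbone, stripped.root_order, {s.id: s.families for s in stripped.syntenies}
)
inferred.validate()
print("inferred ordered cost:", cost, "<= true cost:", stripped.true_cost)

unordered = usr_min_cost(backbone, {s.id: s.family_set for s in stripped.syntenies})
print("inferred unordered cost:", unordered.cost, "<= ordered cost:", cost)

# The gap between inferred and true cost is expected: dense histories
# are rarely the most parsimonious explanation of their own leaves.
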