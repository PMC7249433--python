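"""Supertree machinery: BUILD and the enumeration of binary supertrees.

Synteny trees from different families overlap on shared syntenies;
a Super-Reconciliation must extend a supertree displaying them all.
"""

from superrec import build_supertree, enumerate_binary_supertrees, parse_newick, to_newick
from superrec.errors import TreeInconsistencyError

inputs = [parse_newick("((X1,X2),X3);"), parse_newick("(X2,(X3,X4));")]
print("BUILD supertree:", to_newick(build_supertree(inputs)))
for t in enumerate_binary_supertrees(inputs):
    print("  binary supertree:", to_newick(t))

# Each printed tree displays both inputs: restricting it to {X1,X2,X3}
# or to {X2,X3,X4} gives back the corresponding input topology.

conflict = [parse_newick("((X1,X2),X3);"), parse_newick("((X1,X3),X2);")]
try:
    build_supertree(conflict)
except TreeInconsistencyError as exc:
    print("conflicting triplets:", exc)
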