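# Methods

## The evolutionary model

A synteny is an ordered sequence of genes from pairwise-distinct
families in one genome. All extant syntenies descend from a single
ancestral synteny `A` through speciations, segmental duplications and
segmental losses:

- `Spe(X, [1, l])` at a node mapped to species `s`: `X` is reproduced in
  both children of `s` in the species tree;
- `Dup(X, [i, j])`: the substring `X[i..j]` is copied within the same
  genome, creating a new synteny; the copy is *partial* when
  `[i, j] != [1, l]`;
- `Loss(X, [i, j])`: the substring is removed; a loss that empties the
  synteny is a full loss (`fLoss`, a leaf of the history), otherwise a
  partial loss (`pLoss`, a unary node).

A labeled history is a partially binary tree whose nodes carry
(synteny, event, species) and whose edges satisfy these constraints;
`LabeledHistory.validate()` checks them node by node, including the two
degenerate forms that arise in practice: an `fLoss` leaf directly under
a `Spe` (the lineage entering one child species died) or under a `Dup`
(one of the two products was lost entirely). The cost of a history is
the number of `Dup + pLoss + fLoss` events. Unordered histories carry
gene-content sets instead of sequences; a `Dup` then gives one child the
full content and the other any subset, and one `pLoss` suffices for any
reduction, so at most one `pLoss` separates two binary nodes in a
parsimonious history.

Segment intervals are 1-based and closed throughout (`Dup(X, [2, 3])`
copies the second and third genes). Grafted `fLoss` leaves carry the
empty synteny.

## Existence conditions

Losses can only delete: every synteny of a valid history is a
subsequence of each of its ancestors' syntenies. Hence an ordered
history exists iff the precedence graph — one vertex per family, an
edge `(i, j)` for every ordered pair of families co-occurring in a
synteny (all pairs, not only adjacencies, matching the definition
literally; acyclicity is the same either way) — is acyclic, and the
candidate ancestral orders are exactly its topological sorts
(enumerated via networkx, capped at a configurable limit with a
warning; counting them exactly is #P-complete, so the count reported on
truncation is a lower bound).

Tree consistency is decided by BUILD on the rooted triplets of the
synteny trees. The package also exposes `triplet_consistent`, the
pairwise shared-triplet probe: it is a *necessary* condition only.
Three trees whose pairwise leaf overlaps are too small to share a
triplet can still be jointly incompatible (e.g. the triples `12|3`,
`34|1`, `14|2`), so the search relies on BUILD, and the two failure
modes raise distinct errors: `OrderInconsistencyError` (curable by the
unordered model) vs `TreeInconsistencyError` (fatal).

All binary supertrees are enumerated by recursive bipartition of the
Aho-graph components: a binary supertree's root split cannot separate
two leaves joined by a triplet constraint, so each split is a union of
components, and conversely every union extends — each supertree is
produced exactly once. For small leaf sets this was cross-checked
against the exhaustive filter (all binary topologies, kept when they
display every input).

## The ordered dynamic program

Given a backbone — a supertree whose nodes are LCA-mapped to species,
labeled `Spe`/`Dup` (children separated in the species tree or not) and
extended with `fLoss` leaves on every skipped species edge — and an
ancestral order `A`, the DP assigns each node a subsequence of `A`,
encoded as a bitmask over `A`'s positions, with the root fixed at `A`.
Edge costs use two loss distances (all characters are distinct, so both
are `O(t)`):

- `D_T(X, Y)`: minimal segmental losses transforming `X` into its
  subsequence `Y` = the number of maximal runs of `X`-positions absent
  from `Y` (kept genes between runs prevent merging deletions);
- `D_P(X, Y)`: the same when a substring of `X` may be chosen first =
  internal gap runs only (the substring spanning the first to last kept
  position makes prefix/suffix runs free). Consequently
  `D_P <= D_T <= D_P + 2`.

A speciation charges `D_T` on both child edges; a duplication charges
`1` plus `D_T` on one side and `D_P` on the other (the copied side), the
cheaper orientation winning, with ties broken toward the left child.
`fLoss` leaves are pinned to the empty synteny; since
`D_T(X, empty) = 1`, the single full-loss event falls out of the same
recurrence with no separate bookkeeping. The empty assignment is
forbidden everywhere else (brute-force enumeration on small instances
confirms this never changes the optimum). States per node: `2^t`;
transitions enumerate submasks (`3^t` per child), with the run counts
memoized; total work is linear in the number of nodes at fixed `t`. A
configurable cell budget (default `2^24`) guards the exponential growth
in `t` with a clear error rather than an out-of-memory failure.

Backtracking prefers the smallest bitmask on ties, making results
reproducible; it materializes `pLoss` chains (leftmost run removed
first), reports each duplication's segment as the minimal substring
covering the copied child's content, and returns a `LabeledHistory`
whose validated cost equals the DP optimum by construction (asserted in
tests, not assumed).

## The unordered dynamic program

With rearrangements free, only gene contents matter and only partial
losses remain to be minimized (duplication and full-loss counts are
fixed by the labeled backbone). For a node `v`, let `lcaSet(v)` be the
union of extant contents below it. The identity of any *extra* content
assigned above `lcaSet(v)` is irrelevant — losing `{x}` costs the same
as losing `{x, y}` — so two numbers per node suffice: `C_lca(v)`
(content exactly `lcaSet(v)`) and `C*(v)` (any strict superset). For a
speciation (`spec(v) = 1`) or duplication (`spec(v) = 0`):

```
C*(v) = min( C_lca(v1) + C_lca(v2) + 1 + spec(v),
             C*(v1)    + C_lca(v2) +     spec(v),
             C_lca(v1) + C*(v2)    +     spec(v),
             C*(v1)    + C*(v2) )
```

and `C_lca(v)` follows the same case analysis restricted to content
`lcaSet(v)`: a child with the same lca set simply receives it; a child
with a smaller one either drops to it (`C_lca` + one `pLoss`) or
inherits the parent content whole (`C*`, no loss); a duplication
absorbs one drop in its partial copy. Grafted `fLoss` leaves take
`C_lca = C* = 0`: the full loss is already counted and swallows
whatever arrives. Extant leaves take `C_lca = 0`, `C* = infinity`. The
total is `#Dup + #fLoss + C_lca(root)` with the root content the full
family set. Because the `C_lca` case analysis is a re-derivation (the
source of the recurrences gives `C*` in closed form only), its
correctness is established empirically: a brute-force oracle minimizing
over *all* per-node subset assignments agrees on 100% of 1000 random
instances with up to 5 families, including pinned-extra-content probes
of the irrelevance property. Backtracking prefers the smaller (lca)
set on ties.

## The search

`super_reconcile` chains the steps: validate, build synteny trees,
check order consistency (ordered mode), enumerate ancestral orders and
binary supertrees (defaults: 10,000 each, truncation flagged in the
result), run the DP per pair, and keep all optima up to `max_optima`
(default 100), deduplicated by canonical serialization. No pruning
beyond the caps: the ordered problem is NP-hard in general, and at the
scales where exhaustive exploration is feasible, exactness is worth
more than an incomplete heuristic. The reported optimum does not depend
on enumeration order (a plain minimum over the explored set).

## Brute-force oracles

The oracles never share code paths with the DPs: loss distances are
breadth-first shortest paths in the graph of interval deletions;
`oracle_ordered` enumerates every valid assignment of subsequences
(with memoization and subsequence-coverage pruning, both exact);
`oracle_unordered` enumerates every per-node set between `lcaSet(v)`
and the family universe. Guards refuse instances above 5 families or
25 internal nodes (counted after loss grafting) — beyond that,
enumeration stops being desk-scale.

## The simulator

`simulate_history` evolves `f1..ft` down a balanced species tree of
depth `d` (so `2^d` extant species). A lineage reaching an internal
species node duplicates with probability `p_dupl` (segment start
uniform, length shifted-geometric, truncated to the synteny) or
speciates; on each child branch, independently with probability
`p_loss`, at most one loss occurs: length `K` with
`P(K = k) = (1 - p_length)^(k-1) * p_length` (`k >= 1`), start uniform,
truncated at the synteny boundary; a loss covering everything becomes
an `fLoss` leaf. Defaults are `t = 5`, `d = 5`, all probabilities 0.5.
Two conventions the model statement leaves open were fixed once and are
configurable in principle: the loss position is uniform, and losses are
drawn per child branch (not per node). Each loss records its *drawn*
length; calibration tests chi-square the drawn lengths because boundary
truncation censors the realized ones. A node-count cap (default 50,000)
guards the near-critical branching regime (at `p_dupl = 0.5`,
`p_loss = 0`, the expected lineage count diverges).

`strip_to_input` removes loss nodes and internal synteny information,
emits one gene tree per surviving family (families with no surviving
gene are dropped and reported), the extant synteny table, and — for
benchmarking only — the true backbone, root order and event count.
Stripped inputs are order- and tree-consistent by construction, which
the tests verify rather than assume.

### What the simulator does and does not emulate

It produces exactly the data regime the inference assumes: one ancestral
synteny, no tandem duplications, no rearrangements, no gene conversion,
a known balanced species tree, and correct gene trees. Passing tests on
simulated data therefore certify the *algorithms* (optimality, bounds,
calibration), not robustness to real-data violations of those
assumptions — gene-tree estimation error, order conflicts from
rearrangements (only the unordered mode addresses these, by fiat), or
paralogy within a synteny.

## Numerical and design choices

- Parsimony bound benchmarks run the DP on the *true* backbone with the
  true root order: that is itself a valid Super-Reconciliation of the
  stripped input and an upper bound on the search optimum, so the
  asserted inequality (inferred <= simulated events) is the stronger
  one, and it avoids enumeration caps silently excluding the true
  supertree. Problem sizes used by the test suite and acceptance
  script: the exhaustive DP sweep uses 3 families and up to 4 leaves
  (~37,000 instances); random sweeps use up to 5 families and 5 leaves;
  simulation benchmarks use `t = 5`, `d = 5` over 100 histories plus a
  depth sweep `d = 3..8`.
- Determinism: every stochastic component takes an explicit seed; tie
  breaks (bitmask order, left-copy preference, lca-set preference,
  canonical Newick sorting) are fixed, so repeated runs are
  bit-identical.
- Degenerate inputs: a single extant synteny is its own history (the
  root must carry the ancestral order, which then equals the synteny);
  empty syntenies are only legal on `fLoss` leaves; single-leaf gene
  trees are accepted (they constrain the supertree's leaf set but not
  its topology).
- A 2-leaf synteny tree is displayed by every supertree containing its
  leaves, so such trees constrain the search space only through their
  leaf sets; uniqueness claims about supertrees require triplets.

## Known limitations

- The ordered search is exponential in the number of families (state
  space `2^t` per node) and in the sizes of the order/supertree
  enumeration spaces; the caps keep runs bounded but may truncate, and
  truncation is reported rather than resolved.
- No mul-trees: a synteny with two genes of one family is rejected at
  parsing.
- The unordered mode prices rearrangements at zero; it bounds the
  ordered optimum from below but can hide arbitrarily many order
  violations.
- The simulator's balanced species tree and per-branch single-loss
  convention are conventions, not claims about real clades.
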