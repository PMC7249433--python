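# superrec

Inference of **segmental duplication and loss histories for syntenies**:
given a species tree, one gene tree per family, and a table grouping the
genes into syntenies (ordered blocks of neighboring genes, at most one
per family), `superrec` reconstructs a minimum-cost evolutionary history
that explains *all* the syntenies from a single ancestral one — the
Super-Reconciliation problem. It generalizes classical duplication-loss
reconciliation from one gene tree to a set of trees whose genes co-evolve
in syntenic blocks (paralogons), as in the Hox clusters, the FGFR
receptors or the opioid receptor regions.

It is a library first (with a thin `superrec` command-line tool) aimed at
people studying the evolution of gene clusters and paralogons.

## The model

Syntenies evolve from one ancestral synteny `A` by three events:

- `Spe(X, [1, l])` — speciation: `X` is transmitted to both child genomes;
- `Dup(X, [i, j])` — segmental duplication: the substring `X[i..j]` is
  copied elsewhere in the same genome;
- `Loss(X, [i, j])` — segmental loss: `X[i..j]` is removed; a loss is
  *partial* (`pLoss`) if something remains, *full* (`fLoss`) otherwise.

A Super-Reconciliation is a labeled synteny tree extending every input
synteny tree and representing a valid history; its cost is the number of
`Dup + pLoss + fLoss` events (speciations are free). Existence requires

1. **order consistency** — the precedence graph over families (edge
   `i -> j` when some synteny places a family-`i` gene before a
   family-`j` gene) is acyclic; its topological sorts are exactly the
   candidate ancestral orders; and
2. **tree consistency** — the synteny trees admit a common supertree
   (decided by the BUILD algorithm on rooted triplets).

The optimizer explores (ancestral order, binary supertree) pairs and, on
each, solves a small-phylogeny problem by dynamic programming over
subsequences of `A` (bitmask states, so `O(2^t)` per node for `t`
families — exponential in the ancestral synteny size, linear in tree
size). Two loss distances drive the recurrence: `D_T(X, Y)`, the minimum
segmental losses turning `X` into a subsequence `Y` (= number of maximal
gap runs), and `D_P(X, Y)`, the same for a substring of `X` (internal gap
runs only — the form a partial duplication pays on the copied side).

Because distant genomes rarely conserve gene order, the package also
implements the **unordered** variant: rearrangements are free and only
gene *contents* matter. That problem is polynomial — two quantities per
node (content = exactly the union of what is below, or anything larger)
computed in a single post-order pass.

A five-parameter simulator (ancestral size `t`, species-tree depth `d`,
duplication probability `p_dupl`, loss probability `p_loss`, shifted
geometric loss-length parameter `p_length`) generates ground-truth
histories for benchmarking, and brute-force oracles certify both dynamic
programs by exhaustive enumeration at desk scale.

## Worked example

Two genomes `A` and `B`; three families `a`, `b`, `c` in four syntenies
(`A1 = a-b-c`, `A2 = b-c`, `B1 = a-b-c`, `B2 = c`), with gene trees
pairing `A1` with `B1` and `A2` with `B2`. Running
`python examples/reconcile_ordered.py` prints:

```
minimum cost: 2
optimal histories: 1
ancestral order: a-b-c

event log of the optimal history:
      n0  Dup     species=anc0  synteny=a|b|c  2-3
      n1  Spe     species=anc0  synteny=a|b|c  1-3
      A1  extant  species=A     synteny=a|b|c
      B1  extant  species=B     synteny=a|b|c
      n2  Spe     species=anc0  synteny=b|c    1-2
      A2  extant  species=A     synteny=b|c
      n3  pLoss   species=B     synteny=b|c    1-1
      B2  extant  species=B     synteny=c
```

Read: in the ancestral genome the segment `b-c` of `a-b-c` was
duplicated (`Dup`, segment 2–3), both copies speciated into `A` and `B`,
and genome `B` later lost gene `b` from the copied block (`pLoss`). Total
cost 2 — one duplication plus one loss — against 3 if the three families
were reconciled independently; the segmental history is both cheaper to
state and biologically more plausible than three identical independent
duplications.

The same instance from the shell:

```sh
superrec simulate -t 5 -d 5 --seed 7 -o sim/      # or bring your own files
superrec check     --species sim/S.nwk --trees sim/trees.nwk --syntenies sim/syntenies.tsv
superrec reconcile --species sim/S.nwk --trees sim/trees.nwk --syntenies sim/syntenies.tsv -o out/
```

Other entry points are shown in `examples/` (consistency checks,
unordered reconciliation, supertree enumeration, simulation and
recovery).

## Input formats

- Trees: Newick, rooted, binary; one tree per line in gene-tree files;
  branch lengths tolerated and ignored.
- Synteny table: TSV with header `gene family species synteny position`,
  positions 1-based and contiguous within each synteny.
- Histories are written as annotated Newick
  (`[&event=Dup,segment=2-3,synteny=a|b|c,species=spX]`) plus a flat TSV
  event log.

## Scope

Tandem duplications (several same-family genes in one synteny),
multifurcating input trees, unrooted trees, and rearrangement-aware
distances are out of scope; the unordered mode is the supported way to
handle rearranged gene orders. See `docs/methods.md` for the model
details, parameter semantics and known limitations.
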