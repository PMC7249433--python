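"""Readers and writers for the formats superrec touches.

* Trees are Newick (one tree per line for gene-tree files); unquoted
  labels, branch lengths tolerated and ignored.
* The synteny table is a TSV with header ``gene family species synteny
  position``; positions are 1-based and contiguous within a synteny.
* Histories are written as annotated Newick with per-node comment blocks
  ``[&event=Dup,segment=2-3,synteny=a|b|c,species=spX]`` plus a flat TSV
  event log.  (No reader: the annotated form is an output convention.)
"""

from __future__ import annotations

import csv
import os
from typing import Iterable

from skbio import TreeNode

from .errors import SyntenyTableError, UnknownGeneError
from .model import Gene, LabeledHistory, Synteny, check_gene_tree, check_species_tree, organize
from .trees import leaf_names, parse_newick, parse_newick_lines, to_newick

TABLE_COLUMNS = ("gene", "family", "species", "synteny", "position")


def read_species_tree(path: str | os.PathLike) -> TreeNode:
    with open(path) as fh:
        return check_species_tree(parse_newick(fh.read()))


def read_gene_trees(path: str | os.PathLike) -> list[TreeNode]:
    with open(path) as fh:
        trees = parse_newick_lines(fh.read())
    for t in trees:
        check_gene_tree(t)
    return trees


def write_trees(trees: Iterable[TreeNode], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(to_newick(t) + "\n")


def read_synteny_table(path: str | os.PathLike) -> tuple[list[Synteny], dict[str, str]]:
    """Read the TSV synteny table.

    Returns the list of syntenies (genes ordered by position) and the
    gene -> family map.
    """
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = tuple(next(reader))
        except StopIteration:
            raise SyntenyTableError("empty synteny table") from None
        if header != TABLE_COLUMNS:
            raise SyntenyTableError(
                f"bad header {header!r}; expected {TABLE_COLUMNS!r}"
            )
        rows = [row for row in reader if row and any(cell.strip() for cell in row)]

    by_synteny: dict[str, list[tuple[int, Gene]]] = {}
    species_of: dict[str, str] = {}
    for row in rows:
        if len(row) != 5:
            raise SyntenyTableError(f"bad row {row!r}")
        gene, family, species, synteny, pos_s = row
        try:
            pos = int(pos_s)
        except ValueError:
            raise SyntenyTableError(f"non-integer position in row {row!r}") from None
        sp = species_of.setdefault(synteny, species)
        if sp != species:
            raise SyntenyTableError(
                f"synteny {synteny!r} spans species {sp!r} and {species!r}"
            )
        by_synteny.setdefault(synteny, []).append((pos, Gene(gene, family, species)))

    syntenies = []
    for syn_id in sorted(by_synteny):
        entries = sorted(by_synteny[syn_id], key=lambda e: e[0])
        positions = [p for p, _ in entries]
        if positions != list(range(1, len(entries) + 1)):
            raise SyntenyTableError(
                f"positions in synteny {syn_id!r} are not contiguous from 1: {positions}"
            )
        syntenies.append(
            Synteny(syn_id, species_of[syn_id], tuple(g for _, g in entries))
        )
    _, _, fam_of = organize(syntenies)
    return syntenies, fam_of


def write_synteny_table(syntenies: Iterable[Synteny], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(TABLE_COLUMNS)
        for syn in syntenies:
            for pos, g in enumerate(syn.genes, start=1):
                w.writerow([g.id, g.family, g.species, syn.id, pos])


def check_genes_covered(gene_trees: Iterable[TreeNode], fam_of: dict[str, str]) -> None:
    """Every leaf of every gene tree must appear in the synteny table."""
    for t in gene_trees:
        for name in leaf_names(t):
            if name not in fam_of:
                raise UnknownGeneError(f"gene {name!r} is not in the synteny table")


# -- history output ----------------------------------------------------


def _synteny_text(content) -> str:
    if isinstance(content, frozenset):
        return "|".join(sorted(content))
    return "|".join(content)


def _annotation(node: TreeNode) -> str:
    ev = node.event
    parts = [f"event={ev.type}"]
    if ev.segment is not None:
        parts.append(f"segment={ev.segment[0]}-{ev.segment[1]}")
    parts.append(f"synteny={_synteny_text(node.synteny)}")
    parts.append(f"species={node.species}")
    return "[&" + ",".join(parts) + "]"


def history_to_newick(history: LabeledHistory) -> str:
    """Annotated Newick: each node label is followed by a comment block
    carrying its event, segment, synteny and species."""

    def rec(node: TreeNode) -> str:
        label = (node.name or "") + _annotation(node)
        if not node.children:
            return label
        return "(" + ",".join(rec(c) for c in node.children) + ")" + label

    return rec(history.root) + ";"


def history_event_table(history: LabeledHistory) -> list[tuple[str, str, str, str, str]]:
    """Flat event log rows: (node_id, event, species, synteny, segment)."""
    rows = []
    for node in history.root.traverse():
        ev = node.event
        seg = "" if ev.segment is None else f"{ev.segment[0]}-{ev.segment[1]}"
        rows.append(
            (node.name or "", str(ev.type), node.species, _synteny_text(node.synteny), seg)
        )
    return rows


def write_history(history: LabeledHistory, newick_path, table_path) -> None:
    with open(newick_path, "w") as fh:
        fh.write(history_to_newick(history) + "\n")
    with open(table_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["node_id", "event", "species", "synteny", "segment"])
        w.writerows(history_event_table(history))
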