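"""Small utilities on rooted trees.

All trees in superrec are :class:`skbio.TreeNode` objects.  Leaf names are
the labels that matter (species, gene or synteny identifiers); internal
names are optional and preserved when present.  These helpers add the
operations the reconciliation algorithms need: parsing, canonical forms,
restriction to a leaf subset, the display relation, and rooted-triplet
extraction.
"""

from __future__ import annotations

import io
from itertools import combinations
from typing import Iterable, Iterator

from skbio import TreeNode

from .errors import NonBinaryTreeError, ValidationError

__all__ = [
    "parse_newick",
    "parse_newick_lines",
    "to_newick",
    "leaf_names",
    "is_binary",
    "check_binary",
    "canonical_form",
    "canonical_newick",
    "label_isomorphic",
    "restrict",
    "displays",
    "rooted_triplets",
    "all_binary_topologies",
]


def parse_newick(text: str) -> TreeNode:
    """Parse one Newick string into a rooted tree.

    Labels are taken verbatim (no underscore-to-space conversion); branch
    lengths, if present, are parsed and ignored.
    """
    tree = TreeNode.read(io.StringIO(text), convert_underscores=False)
    for node in tree.traverse():
        node.length = None
    return tree


def parse_newick_lines(text: str) -> list[TreeNode]:
    """Parse a sequence of Newick strings, one tree per non-blank line."""
    return [parse_newick(line) for line in text.splitlines() if line.strip()]


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def leaf_names(tree: TreeNode) -> list[str]:
    return [tip.name for tip in tree.tips()] if tree.children else [tree.name]


def is_binary(tree: TreeNode) -> bool:
    return all(len(n.children) in (0, 2) for n in tree.traverse())


def check_binary(tree: TreeNode, what: str = "tree") -> TreeNode:
    if not is_binary(tree):
        raise NonBinaryTreeError(f"{what} is not binary")
    return tree


def canonical_form(tree: TreeNode):
    """A hashable canonical form of the leaf-labeled topology.

    Children are ordered by the minimum leaf label below them, so two
    trees get the same form iff they are label-isomorphic.
    """

    def rec(node: TreeNode):
        if not node.children:
            return node.name
        forms = sorted((rec(c) for c in node.children), key=repr)
        return tuple(forms)

    return rec(tree)


def _form_to_newick(form) -> str:
    if isinstance(form, str):
        return form
    return "(" + ",".join(_form_to_newick(f) for f in form) + ")"


def canonical_newick(tree: TreeNode) -> str:
    """Newick text of the canonical form (no internal labels)."""
    return _form_to_newick(canonical_form(tree)) + ";"


def label_isomorphic(t1: TreeNode, t2: TreeNode) -> bool:
    return canonical_form(t1) == canonical_form(t2)


def restrict(tree: TreeNode, leaves: Iterable[str]) -> TreeNode:
    """Restriction of ``tree`` to a leaf subset.

    The subtree rooted at the LCA of ``leaves``, with all other leaves
    removed and unary nodes suppressed.
    """
    keep = set(leaves)
    have = set(leaf_names(tree))
    missing = keep - have
    if missing:
        raise ValidationError(f"leaves not in tree: {sorted(missing)}")

    def rec(node: TreeNode) -> TreeNode | None:
        if not node.children:
            if node.name in keep:
                return TreeNode(name=node.name)
            return None
        kids = [sub for c in node.children if (sub := rec(c)) is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = TreeNode(name=node.name)
        for k in kids:
            new.append(k)
        return new

    out = rec(tree)
    assert out is not None
    return out


def displays(tree: TreeNode, other: TreeNode) -> bool:
    """True iff ``tree`` displays ``other``: the restriction of ``tree``
    to the leaves of ``other`` is label-isomorphic to ``other``."""
    return canonical_form(restrict(tree, leaf_names(other))) == canonical_form(other)


def rooted_triplets(tree: TreeNode) -> Iterator[tuple[str, str, str]]:
    """All resolved rooted triplets ``(a, b, c)`` meaning ``ab|c``
    (``lca(a,b)`` is a strict descendant of ``lca(a,b,c)``), with
    ``a < b`` lexicographically.

    Each resolved triplet is yielded exactly once, at its three leaves'
    LCA: any pair inside one child subtree forms ``ab|c`` against every
    leaf below a sibling child.  Triplets whose three leaves fall into
    three distinct children of a multifurcation are unresolved and are
    not yielded.
    """
    if len(leaf_names(tree)) < 3:
        return
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if not node.children:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    for node in tree.non_tips(include_self=True):
        for child in node.children:
            inside = below[id(child)]
            siblings = below[id(node)] - inside
            if len(inside) < 2 or not siblings:
                continue
            for a, b in combinations(sorted(inside), 2):
                for c in siblings:
                    yield (a, b, c)


def ensure_internal_names(tree: TreeNode, prefix: str = "anc") -> TreeNode:
    """Give every unnamed node a fresh ``prefix<i>`` name (in place)."""
    taken = {n.name for n in tree.traverse() if n.name is not None}
    i = 0
    for node in tree.traverse():
        if node.name is None:
            while f"{prefix}{i}" in taken:
                i += 1
            node.name = f"{prefix}{i}"
            taken.add(node.name)
    return tree


def all_binary_topologies(leaves: list[str]) -> Iterator[TreeNode]:
    """Yield every rooted binary topology on ``leaves`` exactly once.

    (2n-3)!! trees; intended for oracle-grade exhaustive checks with
    small n.
    """
    leaves = sorted(leaves)
    if not leaves:
        return
    if len(leaves) == 1:
        yield TreeNode(name=leaves[0])
        return

    def build(names: list[str]) -> Iterator[TreeNode]:
        if len(names) == 1:
            yield TreeNode(name=names[0])
            return
        first, rest = names[0], names[1:]
        # split rest into the side containing `first` vs the other side
        for mask in range(1, 2 ** len(rest)):
            right = [rest[i] for i in range(len(rest)) if mask >> i & 1]
            left = [first] + [rest[i] for i in range(len(rest)) if not mask >> i & 1]
            for lt in build(left):
                for rt in build(right):
                    root = TreeNode()
                    root.append(lt.copy())
                    root.append(rt.copy())
                    yield root

    yield from build(leaves)
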