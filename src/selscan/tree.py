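"""Rooted phylogenies with branch lengths and foreground branch marks.

A :class:`PhyloTree` is a thin array-backed wrapper around a rooted tree:
every node has a parent link, a branch length (expected substitutions per
codon on the edge to its parent) and a boolean *foreground* flag used by
the branch-wise selection models.  Foreground branches can be marked in
the newick source with a configurable label suffix (``#1`` by default,
the convention of PAML/HyPhy branch labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

from Bio import Phylo

__all__ = ["TreeNode", "PhyloTree", "parse_newick", "read_newick"]

DEFAULT_FOREGROUND_TAG = "#1"


@dataclass
class TreeNode:
    index: int
    name: str | None
    parent: int | None
    length: float
    foreground: bool = False
    children: list[int] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree stored as a postorder node array."""

    def __init__(self, nodes: Sequence[TreeNode]):
        self.nodes = list(nodes)
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {len(roots)}")
        self.root = roots[0].index
        labels = [n.name for n in self.nodes if n.is_leaf]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        if any(n.length < 0 for n in self.nodes):
            raise ValueError("negative branch length")

    # -- queries ---------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes if n.is_leaf)

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]

    def postorder(self) -> Iterable[TreeNode]:
        order: list[TreeNode] = []

        def walk(i: int) -> None:
            for c in self.nodes[i].children:
                walk(c)
            order.append(self.nodes[i])

        walk(self.root)
        return order

    def foreground_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.foreground]

    def total_length(self) -> float:
        return sum(n.length for n in self.nodes if n.parent is not None)

    # -- edits -----------------------------------------------------------
    def set_foreground(self, labels: Iterable[str]) -> None:
        """Mark the terminal branches leading to *labels* as foreground."""
        wanted = set(labels)
        found = set()
        for n in self.nodes:
            if n.name in wanted:
                n.foreground = True
                found.add(n.name)
        missing = wanted - found
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")

    def clear_foreground(self) -> None:
        for n in self.nodes:
            n.foreground = False

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            [
                TreeNode(n.index, n.name, n.parent, n.length, n.foreground,
                         list(n.children))
                for n in self.nodes
            ]
        )

    # -- serialization ---------------------------------------------------
    def to_newick(self, foreground_tag: str = DEFAULT_FOREGROUND_TAG) -> str:
        def fmt(i: int) -> str:
            n = self.nodes[i]
            tag = foreground_tag if n.foreground else ""
            if n.is_leaf:
                core = f"{n.name}{tag}"
            else:
                core = "(" + ",".join(fmt(c) for c in n.children) + ")"
                core += (n.name or "") + tag
            if n.parent is None:
                return core
            return f"{core}:{n.length:g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_leaves} leaves, {len(self.nodes)} nodes)"


def _from_biopython(tree, foreground_tag: str) -> PhyloTree:
    nodes: list[TreeNode] = []

    def walk(clade, parent: int | None) -> int:
        idx = len(nodes)
        name = clade.name
        fg = False
        if name and name.endswith(foreground_tag):
            fg = True
            name = name[: -len(foreground_tag)] or None
        length = clade.branch_length if clade.branch_length is not None else 0.0
        nodes.append(TreeNode(idx, name, parent, float(length), fg))
        for child in clade.clades:
            nodes[idx].children.append(walk(child, idx))
        return idx

    walk(tree.root, None)
    return PhyloTree(nodes)


def parse_newick(text: str, foreground_tag: str = DEFAULT_FOREGROUND_TAG) -> PhyloTree:
    """Parse a single newick tree from a string.

    Branch lengths default to 0 when absent.  Node labels ending in
    *foreground_tag* mark the branch above that node as foreground.
    """
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in newick string")
    tree = Phylo.read(StringIO(text), "newick")
    # Bio.Phylo may coerce pure-numeric internal labels to confidences;
    # restore the ones that carry a foreground tag (those stay strings).
    return _from_biopython(tree, foreground_tag)


def read_newick(path, foreground_tag: str = DEFAULT_FOREGROUND_TAG) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read(), foreground_tag)
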