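"""Rooted species trees.

The species tree is the coordinate system for every node-level inference in
the package: ancestral-state marginals, recruitment-node assignment, gene
family origins (phylostrata) and the permutation null are all reported
against its labelled nodes.  Trees are read from Newick; internal nodes
without a label receive a deterministic name built from their sorted
descendant tip names (``A|B|C``), so node identities are stable across runs
and across tools regardless of Newick rotation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

log = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "SpeciesTree",
    "NewickParseError",
    "read_newick_tree",
    "parse_newick",
    "write_newick",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


@dataclass(eq=False)
class TreeNode:
    """One node of a rooted tree; ``branch_length`` is the edge to the parent."""

    label: str | None = None
    branch_length: float = 0.0
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind} bl={self.branch_length}>"


class SpeciesTree:
    """A rooted, labelled species tree.

    Invariants enforced on construction:

    * every non-root node has exactly one parent (tree, no cycles);
    * tip names unique and non-empty;
    * internal labels unique (auto-generated from sorted descendant tips
      when absent);
    * branch lengths ``>= 0``; a missing length on a non-root edge is
      replaced by 1.0 (and logged at parse time).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._index()

    # -- construction -----------------------------------------------------

    def _index(self) -> None:
        postorder: list[TreeNode] = []
        stack = [(self.root, False)]
        seen: set[int] = set()
        while stack:
            node, expanded = stack.pop()
            if expanded:
                postorder.append(node)
                continue
            if id(node) in seen:
                raise ValueError("cycle detected in tree")
            seen.add(id(node))
            stack.append((node, True))
            for child in reversed(node.children):
                if child.parent is not node:
                    raise ValueError(
                        f"node {child.label!r} does not point back to its parent"
                    )
                stack.append((child, False))
        self.postorder: list[TreeNode] = postorder

        clade: dict[int, frozenset[str]] = {}
        for node in postorder:
            if node.is_tip:
                if not node.label:
                    raise ValueError("tip with empty name")
                clade[id(node)] = frozenset([node.label])
            else:
                tips: set[str] = set()
                for child in node.children:
                    tips |= clade[id(child)]
                clade[id(node)] = frozenset(tips)
                if not node.label:
                    node.label = "|".join(sorted(tips))
        self._clade = {node.label: clade[id(node)] for node in postorder}

        labels = [n.label for n in postorder]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate node labels: {dupes}")

        self.nodes_by_label: dict[str, TreeNode] = {n.label: n for n in postorder}
        for node in postorder:
            if node.branch_length < 0:
                raise ValueError(f"negative branch length at {node.label!r}")

        # preorder & depths (edges from root)
        self.depth: dict[str, int] = {}
        preorder: list[TreeNode] = []
        stack = [self.root]
        self.depth[self.root.label] = 0
        while stack:
            node = stack.pop()
            preorder.append(node)
            for child in reversed(node.children):
                self.depth[child.label] = self.depth[node.label] + 1
                stack.append(child)
        self.preorder: list[TreeNode] = preorder
        self.tip_names: list[str] = [n.label for n in preorder if n.is_tip]

    # -- queries ----------------------------------------------------------

    @property
    def tips(self) -> list[TreeNode]:
        return [self.nodes_by_label[name] for name in self.tip_names]

    @property
    def internal_labels(self) -> list[str]:
        return [n.label for n in self.preorder if not n.is_tip]

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.preorder]

    def clade_tips(self, label: str) -> frozenset[str]:
        """Descendant tip names of the node (a tip yields itself)."""
        return self._clade[label]

    def n_descendant_tips(self, label: str) -> int:
        return len(self._clade[label])

    def mrca(self, tip_names) -> TreeNode:
        """Most recent common ancestor of a non-empty set of tips."""
        query = frozenset(tip_names)
        if not query:
            raise ValueError("mrca of an empty tip set")
        unknown = query - set(self.tip_names)
        if unknown:
            raise KeyError(f"tips not in tree: {sorted(unknown)}")
        best = None
        for node in self.postorder:
            if query <= self._clade[node.label]:
                if best is None or len(self._clade[node.label]) < len(
                    self._clade[best.label]
                ):
                    best = node
        assert best is not None
        return best

    def is_ancestor_or_equal(self, anc: str, desc: str) -> bool:
        return self._clade[desc] <= self._clade[anc]

    # -- serialisation ----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_tip:
                s = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                s = f"({inner}){node.label}"
            if node.parent is not None:
                s += f":{node.branch_length:.17g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SpeciesTree {len(self.tip_names)} tips>"


def _check_balanced(text: str) -> None:
    """Report unbalanced parentheses with the byte offset of the offence."""
    opens: list[int] = []
    for offset, ch in enumerate(text):
        if ch == "(":
            opens.append(offset)
        elif ch == ")":
            if not opens:
                raise NewickParseError(f"unmatched ')' at byte offset {offset}")
            opens.pop()
    if opens:
        raise NewickParseError(
            f"unclosed '(' opened at byte offset {opens[-1]}"
        )


def _convert(dnode, parent: TreeNode | None) -> TreeNode:
    if dnode.taxon is not None:
        label = dnode.taxon.label
    else:
        label = dnode.label or None
    length = dnode.edge.length
    if length is None:
        if parent is None:
            length = 0.0
        else:
            length = 1.0
            log.warning(
                "missing branch length at node %r replaced by 1.0", label
            )
    node = TreeNode(label=label, branch_length=float(length), parent=parent)
    for dchild in dnode.child_nodes():
        node.children.append(_convert(dchild, node))
    return node


def parse_newick(text: str) -> SpeciesTree:
    """Parse one rooted Newick string into a :class:`SpeciesTree`."""
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick input")
    _check_balanced(stripped)
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"Newick parse failed: {exc}") from None
    return SpeciesTree(_convert(dtree.seed_node, None))


def read_newick_tree(path) -> SpeciesTree:
    """Read a rooted Newick tree from a file."""
    text = Path(path).read_text()
    if not text.strip():
        raise NewickParseError(f"empty Newick file: {path}")
    return parse_newick(text)


def write_newick(tree: SpeciesTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
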