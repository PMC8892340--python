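"""Rooted, time-calibrated trees: parsing, validation, indexing.

Trees are stored as a flat postorder index so that likelihood code can run
over plain numpy arrays.  Newick reading and writing is delegated to
dendropy; this module only adds the validation the downstream models demand
(unique tip labels, finite nonnegative branch lengths, a single root, and a
strict-bifurcation check that must pass before any model fitting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import dendropy

__all__ = ["Node", "Tree", "parse_newick", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed or invalid trees."""


@dataclass
class Node:
    """One node of a rooted tree.

    ``length`` is the duration of the branch above the node, in the tree's
    time unit (millions of years for empirical trees).  The root's length is 0.
    """

    label: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """A rooted phylogeny with named tips and nonnegative branch lengths.

    Parameters
    ----------
    root : Node
        Root of the node hierarchy.  The tree takes ownership of the nodes.

    Notes
    -----
    Validation enforces: unique tip labels, finite branch lengths >= 0, and
    every tip labelled.  ``is_bifurcating`` must be True before the pruning
    likelihood will accept the tree; polytomies are resolved upstream by
    :func:`coevotrait.gene_status.thin_tree`.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        labels: list[str] = []
        for node in self.postorder():
            if not math.isfinite(node.length):
                raise TreeError(f"non-finite branch length on node {node.label!r}")
            if node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} on node {node.label!r}"
                )
            if node.is_leaf:
                if not node.label:
                    raise TreeError("unlabelled tip")
                labels.append(node.label)
            elif len(node.children) == 1 and node is not self.root:
                raise TreeError("internal node with a single child (unifurcation)")
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        self._tip_labels = labels

    # -- traversal ------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        """Yield nodes children-first; tip order is the Newick order."""
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    # -- properties -----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def is_bifurcating(self) -> bool:
        """True iff every internal node has exactly two children."""
        return all(
            len(n.children) == 2 for n in self.postorder() if not n.is_leaf
        )

    def depths(self) -> dict[str, float]:
        """Root-to-tip distance per tip label."""
        out: dict[str, float] = {}

        def walk(node: Node, d: float) -> None:
            d += node.length
            if node.is_leaf:
                out[node.label] = d
            for child in node.children:
                walk(child, d)

        walk(self.root, -self.root.length)
        return out

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    # -- editing --------------------------------------------------------

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            return Node(node.label, node.length, [clone(c) for c in node.children])

        return Tree(clone(self.root))

    def prune_to(self, keep: set[str]) -> "Tree":
        """Restrict the tree to the tips in ``keep``.

        Unifurcations created by the removal are suppressed, merging branch
        lengths, exactly as dropping taxa from a chronogram should.
        """
        missing = keep - set(self._tip_labels)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")

        def rebuild(node: Node) -> Node | None:
            if node.is_leaf:
                return Node(node.label, node.length) if node.label in keep else None
            kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            return Node(node.label, node.length, kids)

        new_root = rebuild(self.root)
        if new_root is None:
            raise TreeError("pruning removed every tip")
        new_root.length = 0.0
        return Tree(new_root)

    # -- I/O -------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.12g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.12g}"

        if self.root.is_leaf:
            return f"{self.root.label}:{self.root.length:.12g};"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Tree with {self.n_tips} tips>"


def _from_dendropy(dnode: dendropy.Node) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    length = 0.0 if dnode.edge.length is None else float(dnode.edge.length)
    node = Node(label=label, length=length)
    node.children = [_from_dendropy(c) for c in dnode.child_nodes()]
    return node


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a validated :class:`Tree`.

    Branch lengths are kept as written (the models interpret them as millions
    of years).  A missing root branch length is treated as 0.

    Raises
    ------
    TreeError
        If the string is malformed (the dendropy error message, which names
        the offending position, is preserved) or the tree violates an
        invariant such as duplicate tip labels.
    """
    if not text or not text.strip():
        raise TreeError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"Newick parse error: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = 0.0 if dtree.seed_node.edge.length is None else float(
        dtree.seed_node.edge.length
    )
    return Tree(root)


class TreeIndex:
    """Flat postorder arrays for fast pruning over a bifurcating tree.

    Attributes
    ----------
    n_tips, n_nodes : int
    parent, left, right : per-node child/parent indices (-1 where absent);
        nodes 0..n_tips-1 are tips in the tree's tip order, internal nodes
        follow in postorder, the root is last.
    lengths : branch length above each node (root gets 0).
    tip_index : label -> tip row.
    """

    def __init__(self, tree: Tree):
        if not tree.is_bifurcating:
            raise TreeError(
                "tree contains polytomies; resolve (thin_tree) before fitting"
            )
        tips = tree.tips()
        self.n_tips = len(tips)
        order = list(tree.postorder())
        self.n_nodes = len(order)
        idx: dict[int, int] = {}
        next_tip = 0
        next_internal = self.n_tips
        for node in order:
            if node.is_leaf:
                idx[id(node)] = next_tip
                next_tip += 1
            else:
                idx[id(node)] = next_internal
                next_internal += 1
        self.postorder_internal = []
        self.left = [-1] * self.n_nodes
        self.right = [-1] * self.n_nodes
        self.lengths = [0.0] * self.n_nodes
        self.labels = [None] * self.n_nodes
        for node in order:
            i = idx[id(node)]
            self.lengths[i] = node.length
            self.labels[i] = node.label
            if not node.is_leaf:
                self.left[i] = idx[id(node.children[0])]
                self.right[i] = idx[id(node.children[1])]
                self.postorder_internal.append(i)
        self.root = idx[id(tree.root)]
        self.lengths[self.root] = 0.0
        self.tip_index = {tips[i].label: i for i in range(self.n_tips)}
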