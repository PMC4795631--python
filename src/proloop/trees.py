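"""Tree container and Newick I/O.

Newick parsing/writing is delegated to dendropy; trees are then converted to
a light parent/child-linked structure, which is what the reconciliation and
re-rooting code operates on.  A rooted tree has a bifurcating top node; an
unrooted tree is represented with a nominal trifurcating top node.

Edges are identified by *bipartitions*: the frozenset of leaf labels on the
side of the edge that does not contain the lexicographically smallest leaf.
This makes edge identity stable across different internal representations of
the same unrooted topology.
"""

from __future__ import annotations

from typing import Iterator

import dendropy

from .errors import ContractError, NewickParseError


class TreeNode:
    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, {len(self.children)} children)"


class Tree:
    def __init__(self, root: TreeNode, rooted: bool):
        self.root = root
        self.rooted = rooted
        labels = [n.label for n in root.leaves()]
        if len(labels) != len(set(labels)):
            raise NewickParseError("duplicate leaf labels in tree")
        if any(lbl is None for lbl in labels):
            raise NewickParseError("all leaves must be labeled")

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def is_binary(self) -> bool:
        """Internal nodes bifurcate (the top of an unrooted tree may trifurcate)."""
        for node in self.postorder():
            if node.is_leaf:
                continue
            expected = 3 if (node is self.root and not self.rooted) else 2
            if len(node.children) != expected:
                return False
        return True

    def __len__(self) -> int:
        return len(self.leaves())


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = TreeNode(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str) -> Tree:
    """Parse one Newick tree.

    ``"(A,B,C);"`` yields an unrooted tree (trifurcating top node);
    ``"((A,B),C);"`` yields a rooted tree.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickParseError("Newick string must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    if not root.children:
        raise NewickParseError("tree must have at least two leaves")
    rooted = len(root.children) == 2
    return Tree(root, rooted=rooted)


def _to_newick(node: TreeNode, with_lengths: bool) -> str:
    if node.is_leaf:
        out = node.label or ""
    else:
        out = "(" + ",".join(_to_newick(c, with_lengths) for c in node.children) + ")"
        if node.label:
            out += node.label
    if with_lengths and node.length is not None:
        out += f":{node.length:g}"
    return out


def write_newick(tree: Tree, with_lengths: bool = True) -> str:
    return _to_newick(tree.root, with_lengths) + ";"


# ---------------------------------------------------------------------------
# Bipartitions and re-rooting


def bipartition(node: TreeNode, all_labels: frozenset[str]) -> frozenset[str]:
    """Canonical edge key for the edge above ``node``.

    The side not containing min(all_labels) is returned; the root has no edge.
    """
    side = node.leaf_labels()
    anchor = min(all_labels)
    if anchor in side:
        side = all_labels - side
    return frozenset(side)


def edges(tree: Tree) -> list[TreeNode]:
    """All edges of the tree, each identified by its child node."""
    return [n for n in tree.postorder() if n.parent is not None]


def _copy_subtree(node: TreeNode) -> TreeNode:
    new = TreeNode(node.label, node.length)
    for child in node.children:
        new.add_child(_copy_subtree(child))
    return new


def _adjacency(tree: Tree) -> tuple[dict[int, list[TreeNode]], dict[int, TreeNode]]:
    adj: dict[int, list[TreeNode]] = {}
    nodes: dict[int, TreeNode] = {}
    for node in tree.postorder():
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        if node.parent is not None:
            adj[id(node)].append(node.parent)
            adj.setdefault(id(node.parent), []).append(node)
    return adj, nodes


def root_at_edge(tree: Tree, edge_child: TreeNode) -> Tree:
    """Return a new *rooted* tree with the root placed on the edge above
    ``edge_child``; the input tree is not modified.

    Degree-2 nodes created by removing the old top node are suppressed, so
    the result is binary whenever the input was (unrooted-)binary.
    """
    if edge_child.parent is None:
        raise ContractError("cannot root at the top node: it has no parent edge")
    adj, _ = _adjacency(tree)

    def build(node: TreeNode, come_from: TreeNode | None) -> TreeNode:
        new = TreeNode(node.label, node.length)
        for nbr in adj[id(node)]:
            if nbr is come_from:
                continue
            new.add_child(build(nbr, node))
        return new

    root = TreeNode()
    root.add_child(build(edge_child, edge_child.parent))
    root.add_child(build(edge_child.parent, edge_child))

    # suppress any degree-2 pass-through nodes left by the old top node
    def suppress(node: TreeNode) -> None:
        for child in list(node.children):
            suppress(child)
        if len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent

    suppress(root)
    return Tree(root, rooted=True)


def unroot(tree: Tree) -> Tree:
    """Suppress the root of a rooted binary tree, yielding a trifurcating top."""
    if not tree.rooted:
        return tree
    root = _copy_subtree(tree.root)
    if len(root.children) != 2:
        raise ContractError("unroot expects a bifurcating root")
    left, right = root.children
    # absorb the shallower side into the top node
    donor, keeper = (left, right) if not left.is_leaf else (right, left)
    if donor.is_leaf:
        raise ContractError("cannot unroot a 2-leaf tree")
    new_top = TreeNode()
    for child in donor.children:
        new_top.add_child(child)
    keeper.parent = None
    new_top.add_child(keeper)
    return Tree(new_top, rooted=False)
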