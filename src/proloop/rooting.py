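"""Duplication-loss reconciliation rooting of gene trees.

An unrooted gene tree is rooted by trying every edge as the root, LCA-
reconciling each rooted candidate against a rooted binary species tree, and
keeping the edge(s) that minimise the weighted duplication + loss count.
Ties are preserved: with divergent families many edges can receive the best
root score, and the full argmin set is part of the result.

Events are counted with the classic LCA reconciliation: a gene node is a
duplication iff its species image equals the image of at least one child;
losses are summed per gene edge from species-tree depth differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractError, ProloopError
from .trees import Tree, TreeNode, bipartition, edges, root_at_edge

LeafMap = dict[str, str]

DEFAULT_WEIGHTS = (1.0, 1.0)


@dataclass
class DLRootingResult:
    """Per-edge duplication/loss costs over all rootings of a gene tree."""

    #: edge bipartition -> (duplications, losses, cost)
    per_edge: dict[frozenset[str], tuple[int, int, float]]
    weights: tuple[float, float]
    min_cost: float = field(init=False)
    best_edges: set[frozenset[str]] = field(init=False)

    def __post_init__(self) -> None:
        if not self.per_edge:
            raise ContractError("no candidate root edges")
        self.min_cost = min(c for _, _, c in self.per_edge.values())
        self.best_edges = {
            e for e, (_, _, c) in self.per_edge.items()
            if c <= self.min_cost + 1e-9
        }


def _check_binary_rooted(tree: Tree, what: str) -> None:
    if not tree.rooted:
        raise ProloopError(f"{what} tree must be rooted")
    for node in tree.postorder():
        if node.children and len(node.children) != 2:
            raise ProloopError(
                f"{what} tree has a multifurcation "
                f"({len(node.children)} children); resolve it upstream"
            )


def lca_map(gene: Tree, species: Tree, leafmap: LeafMap) -> dict[TreeNode, TreeNode]:
    """Map each gene-tree node to its species-tree image.

    Leaves map through ``leafmap``; an internal node maps to the lowest
    common ancestor of its children's images.
    """
    _check_binary_rooted(gene, "gene")
    _check_binary_rooted(species, "species")
    species_leaf = {n.label: n for n in species.leaves()}
    depth: dict[int, int] = {}
    for node in species.root.preorder():
        depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1

    def lca(a: TreeNode, b: TreeNode) -> TreeNode:
        while a is not b:
            if depth[id(a)] < depth[id(b)]:
                b = b.parent
            elif depth[id(a)] > depth[id(b)]:
                a = a.parent
            else:
                a, b = a.parent, b.parent
        return a

    mapping: dict[TreeNode, TreeNode] = {}
    for node in gene.postorder():
        if node.is_leaf:
            if node.label not in leafmap:
                raise ProloopError(f"gene leaf {node.label!r} missing from leaf map")
            sp = leafmap[node.label]
            if sp not in species_leaf:
                raise ProloopError(f"species {sp!r} not in species tree")
            mapping[node] = species_leaf[sp]
        else:
            left, right = node.children
            mapping[node] = lca(mapping[left], mapping[right])
    return mapping


def count_dl(gene: Tree, species: Tree, leafmap: LeafMap) -> tuple[int, int]:
    """Duplication and loss counts implied by LCA reconciliation.

    Loss contribution of gene edge (u -> c), with d = depth(M(c)) -
    depth(M(u)) in the species tree: d - 1 if u is a speciation, d if u is
    a duplication.
    """
    mapping = lca_map(gene, species, leafmap)
    depth: dict[int, int] = {}
    for node in species.root.preorder():
        depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1

    duplications = 0
    losses = 0
    for node in gene.postorder():
        if node.is_leaf:
            continue
        is_dup = any(mapping[child] is mapping[node] for child in node.children)
        if is_dup:
            duplications += 1
        for child in node.children:
            d = depth[id(mapping[child])] - depth[id(mapping[node])]
            losses += d if is_dup else max(0, d - 1)
    return duplications, losses


def scan_roots(
    gene: Tree,
    species: Tree,
    leafmap: LeafMap,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
) -> DLRootingResult:
    """Try every edge of an unrooted gene tree as the root and score it.

    Returns all per-edge (dup, loss, cost) triples keyed by edge
    bipartition, with the full set of minimum-cost edges.
    """
    if gene.rooted:
        raise ContractError("scan_roots expects an unrooted gene tree")
    if len(gene) < 3:
        raise ContractError("gene tree must have at least 3 leaves")
    w_dup, w_loss = weights
    all_labels = gene.leaf_labels()
    per_edge: dict[frozenset[str], tuple[int, int, float]] = {}
    for edge_child in edges(gene):
        key = bipartition(edge_child, all_labels)
        if key in per_edge:
            continue
        rooted = root_at_edge(gene, edge_child)
        dups, losses = count_dl(rooted, species, leafmap)
        per_edge[key] = (dups, losses, w_dup * dups + w_loss * losses)
    return DLRootingResult(per_edge=per_edge, weights=(w_dup, w_loss))


def best_rooted_trees(
    gene: Tree, result: DLRootingResult
) -> list[Tree]:
    """Materialise the rooted tree for each minimum-cost edge."""
    all_labels = gene.leaf_labels()
    out = []
    seen: set[frozenset[str]] = set()
    for edge_child in edges(gene):
        key = bipartition(edge_child, all_labels)
        if key in result.best_edges and key not in seen:
            seen.add(key)
            out.append(root_at_edge(gene, edge_child))
    return out
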