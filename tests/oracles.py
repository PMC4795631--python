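"""Independent naive oracles used only by the tests.

Deliberately written in a different style from the package (ancestor-set
intersections instead of depth walks; explicit path enumeration for losses;
a from-scratch Gotoh dynamic program for affine-gap global alignment) so
that agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

from proloop.trees import Tree, TreeNode


# --- reconciliation ---------------------------------------------------------

def _ancestors(node: TreeNode) -> list[TreeNode]:
    out = [node]
    while node.parent is not None:
        node = node.parent
        out.append(node)
    return out


def naive_lca_map(gene: Tree, species: Tree, leafmap: dict[str, str]):
    """LCA mapping by full ancestor-set intersection."""
    species_leaf = {n.label: n for n in species.leaves()}
    mapping = {}
    for node in gene.postorder():
        if node.is_leaf:
            mapping[node] = species_leaf[leafmap[node.label]]
        else:
            paths = [_ancestors(mapping[c]) for c in node.children]
            common = set(id(n) for n in paths[0])
            for p in paths[1:]:
                common &= set(id(n) for n in p)
            # deepest common ancestor = first common node on any root path
            mapping[node] = next(n for n in paths[0] if id(n) in common)
    return mapping


def naive_count_dl(gene: Tree, species: Tree, leafmap: dict[str, str]):
    """Duplication/loss counts via explicit species-path enumeration."""
    mapping = naive_lca_map(gene, species, leafmap)
    dups = 0
    losses = 0
    for node in gene.postorder():
        if node.is_leaf:
            continue
        is_dup = any(mapping[c] is mapping[node] for c in node.children)
        dups += int(is_dup)
        for child in node.children:
            # species nodes strictly between M(node) and M(child)
            path = []
            cur = mapping[child]
            while cur is not mapping[node]:
                path.append(cur)
                cur = cur.parent
            n_between = max(0, len(path) - 1)
            losses += n_between + (1 if is_dup and path else 0)
    return dups, losses


def random_gene_species_pair(n_species: int, n_genes: int, rng: np.random.Generator):
    """A random rooted binary species tree + rooted binary gene tree whose
    leaves are assigned to random species."""

    def random_binary(labels):
        nodes = [TreeNode(lbl) for lbl in labels]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False).tolist())
            p = TreeNode()
            p.add_child(nodes[i])
            p.add_child(nodes[j])
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [p]
        return Tree(nodes[0], rooted=True)

    species = random_binary([f"S{i}" for i in range(n_species)])
    gene = random_binary([f"G{i}" for i in range(n_genes)])
    leafmap = {
        f"G{i}": f"S{int(rng.integers(n_species))}" for i in range(n_genes)
    }
    return gene, species, leafmap


# --- affine-gap global alignment (Gotoh) ------------------------------------

_B62 = substitution_matrices.load("BLOSUM62")
NEG = -1e9


def gotoh_global(a: str, b: str, open_: float = -11.0, extend: float = -1.0):
    """Optimal global alignment score + one traceback, affine gaps.

    A gap of length L scores open_ + (L - 1) * extend, matching the package
    aligner's convention.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to '-') ... vertical
    Y = np.full((n + 1, m + 1), NEG)  # gap in a ... horizontal
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend,
                          X[i][j - 1] + open_)
    score = max(M[n][m], X[n][m], Y[n][m])

    # traceback (one optimal path)
    out_a, out_b = [], []
    i, j = n, m
    state = int(np.argmax([M[n][m], X[n][m], Y[n][m]]))
    while i > 0 or j > 0:
        if state == 0:
            s = _B62[a[i - 1], b[j - 1]]
            prev = [M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]]
            state = int(np.argmax(prev))
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            prev = [M[i - 1][j] + open_, X[i - 1][j] + extend, Y[i - 1][j] + open_]
            state = int(np.argmax(prev))
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            prev = [M[i][j - 1] + open_, X[i][j - 1] + extend, Y[i][j - 1] + open_]
            state = int(np.argmax(prev))
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    row_a = "".join(reversed(out_a))
    row_b = "".join(reversed(out_b))
    ident = sum(x == y and x != "-" for x, y in zip(row_a, row_b)) / len(row_a)
    return float(score), ident
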