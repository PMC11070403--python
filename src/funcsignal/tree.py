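"""Functional trees: UPGMA dendrograms, Newick round-trips, patristic
distances.

The dendrogram built from a trait dissimilarity matrix is treated as a
pseudo-phylogenetic ("functional") tree: an ultrametric rooted tree whose
cophenetic distances equal the dissimilarity at which two clusters merge.
Node heights are half the merge dissimilarity, so the leaf-to-leaf path
length through a node reproduces the merge value exactly.
"""

from __future__ import annotations

import io as _io
from typing import Union

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = ["upgma", "patristic_distances", "to_newick", "from_newick",
           "tree_height", "is_ultrametric"]


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) clustering of a dissimilarity matrix.

    Ties between minimal-distance pairs are broken by the lexicographically
    smallest pair of cluster labels (a cluster is labelled by its smallest
    leaf), which makes the topology deterministic across platforms.

    The returned tree is strictly ultrametric; every node carries a branch
    length (the root's children included) and internal nodes are unnamed.
    """
    data = np.asarray(dm.data, dtype=float)
    if np.isnan(data).any():
        raise ValueError("dissimilarity matrix contains NaN")
    ids = [str(i) for i in dm.ids]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 species to build a tree")

    # active clusters: label -> (node, size, height)
    nodes = {i: TreeNode(name=ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    labels = {i: ids[i] for i in range(n)}  # smallest leaf label per cluster
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = data[i, j]
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        # minimal distance, ties broken on sorted label pair
        best = None
        for (i, j), dist in d.items():
            li, lj = sorted((labels[i], labels[j]))
            key = (dist, li, lj)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dist = d[(i, j)]
        h = dist / 2.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = h - heights[i]
        child_j.length = h - heights[j]
        parent = TreeNode(children=[child_i, child_j])
        nodes[next_id] = parent
        sizes[next_id] = sizes[i] + sizes[j]
        heights[next_id] = h
        labels[next_id] = min(labels[i], labels[j])
        active -= {i, j}
        for k in active:
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(next_id, k), max(next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        del d[(i, j)]
        for key in (i, j):
            del nodes[key], sizes[key], heights[key], labels[key]
        active.add(next_id)
        next_id += 1
    root = nodes[next_id - 1]
    root.length = None
    return root


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (cophenetic distances for UPGMA trees)."""
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < -1e-12:
            raise ValueError(f"negative branch length on {node.name!r}")
    return tree.tip_tip_distances()


def tree_height(tree: TreeNode) -> float:
    """Maximum root-to-leaf path length."""
    def depth(node, acc):
        if node.is_tip():
            return [acc]
        out = []
        for ch in node.children:
            out.extend(depth(ch, acc + (ch.length or 0.0)))
        return out
    return max(depth(tree, 0.0)) if not tree.is_tip() else 0.0


def is_ultrametric(tree: TreeNode, rtol: float = 1e-9) -> bool:
    """All leaves equidistant from the root, within rtol x height."""
    depths = []

    def walk(node, acc):
        if node.is_tip():
            depths.append(acc)
        else:
            for ch in node.children:
                walk(ch, acc + (ch.length or 0.0))

    walk(tree, 0.0)
    h = max(depths) if depths else 0.0
    tol = max(rtol * h, 1e-12)
    return (max(depths) - min(depths)) <= tol


def to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue()


def from_newick(text: Union[str, bytes]) -> TreeNode:
    if isinstance(text, bytes):
        text = text.decode()
    return TreeNode.read(_io.StringIO(text))
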