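"""Unweighted UniFrac between species' partner sets on the partner side's
functional tree.

For a pair of leaf sets A and B the tree is restricted to A ∪ B (branches
above the most recent common ancestor of the union are ignored, so the
measure depends only on observed partners); the dissimilarity is the
fraction of the restricted tree's branch length that leads exclusively to
leaves unique to A or unique to B.  The measure is a semimetric in [0, 1],
0 iff A == B, and on a star tree with equal branch lengths it reduces to
1 - Jaccard(A, B).

The pairwise computation is expressed through a branch x leaf incidence
matrix so that partner matrices for thousands of permuted networks reduce
to a handful of small matrix products.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .datatypes import BipartiteNetwork

__all__ = ["TreeEdgeIndex", "unweighted_unifrac", "partner_matrix"]


class TreeEdgeIndex:
    """Branch/leaf incidence decomposition of a rooted tree.

    ``incidence[e, l]`` is True when leaf ``l`` descends through branch
    ``e`` (every non-root node contributes the branch to its parent);
    ``lengths[e]`` is that branch's length (None treated as 0).
    """

    def __init__(self, tree: TreeNode):
        tips = list(tree.tips())
        self.tip_names: list[str] = [str(t.name) for t in tips]
        if len(set(self.tip_names)) != len(self.tip_names):
            raise ValueError("tree has duplicate tip names")
        pos = {id(t): k for k, t in enumerate(tips)}
        edges = [n for n in tree.traverse(include_self=False)]
        L, E = len(tips), len(edges)
        inc = np.zeros((E, L), dtype=bool)
        lengths = np.zeros(E)
        for e, node in enumerate(edges):
            lengths[e] = node.length or 0.0
            if node.is_tip():
                inc[e, pos[id(node)]] = True
            else:
                for t in node.tips():
                    inc[e, pos[id(t)]] = True
        self.incidence = inc
        self.lengths = lengths

    def membership(self, leaf_sets: Sequence[Iterable[str]]) -> np.ndarray:
        """Binary (n_sets x n_tips) membership matrix for leaf-name sets."""
        index = {name: k for k, name in enumerate(self.tip_names)}
        P = np.zeros((len(leaf_sets), len(self.tip_names)), dtype=bool)
        for s, leaves in enumerate(leaf_sets):
            for name in leaves:
                if name not in index:
                    raise ValueError(f"leaf {name!r} not in tree")
                P[s, index[name]] = True
        if not P.any(axis=1).all():
            empty = int(np.flatnonzero(~P.any(axis=1))[0])
            raise ValueError(f"leaf set #{empty} is empty")
        return P

    def pairwise_unifrac(self, P: np.ndarray) -> np.ndarray:
        """All pairwise unweighted UniFrac values between rows of ``P``.

        For each pair (A, B): branches with descendants in exactly one of
        the two sets are unique; branches whose descendants cover both sets
        entirely lie above the MRCA of the union and are excluded; the rest
        of the union's branches are shared.
        """
        P = P.astype(np.float64)
        sizes = P.sum(axis=1)
        N = self.incidence.astype(np.float64).T  # (L, E)
        counts = P @ N                           # (S, E) leaves under branch
        pos = counts > 0
        full = counts >= sizes[:, None] - 1e-9   # branch covers whole set
        l = self.lengths
        h = pos @ l                              # total length per set
        shared = (pos * l) @ pos.T               # sum l over pos_i & pos_j
        above = (full * l) @ full.T              # sum l over full_i & full_j
        unique = h[:, None] + h[None, :] - 2.0 * shared
        total = h[:, None] + h[None, :] - shared - above
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(total > 0, unique / np.where(total > 0, total, 1.0),
                         0.0)
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
        # identical sets are exactly 0 (cancellation can leave ~1e-16)
        Pb = P > 0.5
        same = (Pb[:, None, :] == Pb[None, :, :]).all(axis=2)
        d[same] = 0.0
        return d


def unweighted_unifrac(tree: TreeNode, set_a: Iterable[str],
                       set_b: Iterable[str]) -> float:
    """Unweighted UniFrac between two non-empty leaf sets of ``tree``."""
    idx = TreeEdgeIndex(tree)
    P = idx.membership([set(set_a), set(set_b)])
    return float(idx.pairwise_unifrac(P)[0, 1])


def partner_matrix(network: BipartiteNetwork, partner_tree: TreeNode,
                   side: str = "rows") -> DistanceMatrix:
    """Pairwise UniFrac dissimilarity of partner sets for one network side.

    ``side='rows'`` compares the parasites' host spectra on the host tree;
    ``side='cols'`` compares the hosts' parasite assemblages on the
    parasite tree.  Labels are matched by name, so the result is invariant
    to row/column permutations of the incidence matrix.
    """
    net = network.oriented(side)
    idx = TreeEdgeIndex(partner_tree)
    missing = set(net.col_ids) - set(idx.tip_names)
    if missing:
        raise ValueError(
            f"partners absent from the partner tree: {sorted(missing)}")
    sets = [set(net.incidence.columns[net.incidence.loc[r] == 1])
            for r in net.incidence.index]
    P = idx.membership(sets)
    d = idx.pairwise_unifrac(P)
    return DistanceMatrix(d, ids=net.row_ids)
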