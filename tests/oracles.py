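"""Independent reference implementations used only by the test suite.

Each oracle takes a different computational route from the library code it
checks: scipy's linkage/cophenet for UPGMA, explicit tree shearing and
edge classification for UniFrac, exhaustive recursion for fixed-margin
binary matrices, and plain nested loops for Gower.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform


def upgma_cophenetic(data: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix from scipy's average-linkage clustering."""
    Z = linkage(squareform(data, checks=False), method="average")
    return squareform(cophenet(Z))


def unifrac_bruteforce(tree, set_a, set_b) -> float:
    """Unweighted UniFrac by shearing the tree to the union of the two
    leaf sets and classifying every remaining branch explicitly."""
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    sheared = tree.copy().shear(list(union))
    unique = total = 0.0
    for node in sheared.traverse(include_self=False):
        length = node.length or 0.0
        tips = ({str(node.name)} if node.is_tip()
                else {str(t.name) for t in node.tips()})
        total += length
        if tips <= (set_a - set_b) or tips <= (set_b - set_a):
            unique += length
    if total == 0:
        return 0.0
    return unique / total


def gower_continuous_bruteforce(X: np.ndarray) -> np.ndarray:
    """Uniform-weight Gower for complete continuous data: mean of
    range-normalised Manhattan components, by nested loops."""
    n, k = X.shape
    ranges = X.max(axis=0) - X.min(axis=0)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            comps = []
            for t in range(k):
                d = abs(X[i, t] - X[j, t])
                comps.append(d / ranges[t] if ranges[t] > 0 else 0.0)
            out[i, j] = sum(comps) / k
    return out


def enumerate_fixed_margin_matrices(row_sums, col_sums) -> list[np.ndarray]:
    """All binary matrices with the given margins, by row-wise recursion."""
    row_sums = list(row_sums)
    col_sums = list(col_sums)
    n_cols = len(col_sums)
    out: list[np.ndarray] = []
    rows: list[tuple[int, ...]] = []

    def recurse(i: int, remaining: list[int]) -> None:
        if i == len(row_sums):
            if all(r == 0 for r in remaining):
                out.append(np.array(rows, dtype=np.int8))
            return
        # feasibility prune: remaining capacity must cover remaining rows
        if sum(remaining) != sum(row_sums[i:]):
            return
        candidates = [c for c in range(n_cols) if remaining[c] > 0]
        for combo in itertools.combinations(candidates, row_sums[i]):
            row = [0] * n_cols
            for c in combo:
                row[c] = 1
                remaining[c] -= 1
            rows.append(tuple(row))
            recurse(i + 1, remaining)
            rows.pop()
            for c in combo:
                remaining[c] += 1

    recurse(0, col_sums)
    return out


def pearson_lower_triangle(a: np.ndarray, b: np.ndarray) -> float:
    """Direct Pearson formula over strict lower triangles."""
    tri = np.tril_indices(a.shape[0], k=-1)
    x, y = a[tri], b[tri]
    n = x.size
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x ** 2).sum() - sx ** 2) * \
        np.sqrt(n * (y ** 2).sum() - sy ** 2)
    return float(num / den)
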