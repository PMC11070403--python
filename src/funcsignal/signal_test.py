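"""Functional-signal tests: Mantel correlation between functional
distances and partner-composition dissimilarities, against a null of
degree-preserving network permutations.

The null hypothesis is that a species' partners are assigned independently
of its traits, given how many partners every species has.  It is sampled
with the curveball Markov chain: repeated random "trades" of partners
between two rows of the incidence matrix, which preserve both the row and
the column sums exactly and converge to the uniform distribution over all
binary matrices with those margins.  The observed Mantel correlation is
compared one-sidedly (positive association only — the hypothesis is that
functionally similar species share partners) against the permuted
correlations using the add-one estimator
``p = (1 + #{r_null >= r_obs}) / (1 + n_perm)``, whose smallest attainable
value is ``1 / (n_perm + 1)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .datatypes import BipartiteNetwork, SignalResult
from .tree import patristic_distances
from .unifrac import TreeEdgeIndex

__all__ = [
    "mantel_r",
    "permutation_p",
    "NullEnsemble",
    "degree_preserving_nulls",
    "functional_signal_test",
    "clade_signal_scan",
    "CurveballSampler",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------- mantel
def mantel_r(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Pearson correlation over the strict lower triangles of two
    distance matrices with identical ids in identical order.

    Returns NaN when either triangle has zero variance (the correlation is
    undefined; downstream tests report p = 1 in that case).
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share ids in the same order")
    n = len(d1.ids)
    if n < 3:
        raise ValueError("Mantel correlation needs at least 3 species")
    tri = np.tril_indices(n, k=-1)
    x = np.asarray(d1.data)[tri]
    y = np.asarray(d2.data)[tri]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def permutation_p(n_greater_equal: int, n_perm: int) -> float:
    """One-sided add-one permutation p-value; never 0, floor 1/(n_perm+1)."""
    return (1.0 + n_greater_equal) / (1.0 + n_perm)


# ----------------------------------------------------- curveball sampler
class CurveballSampler:
    """Curveball Markov chain over binary matrices with fixed margins.

    State is kept as one set of partner columns per row.  A trade picks two
    distinct rows, pools the columns exclusive to either, and deals them
    back at random while keeping each row's count — a move that is
    symmetric and therefore samples the fixed-margin matrices uniformly at
    stationarity.  ``run_swaps`` counts the number of matrix entries
    actually exchanged, so burn-in and thinning can be expressed in
    swapped-cell units regardless of how many trades they take.
    """

    def __init__(self, matrix: np.ndarray, rng: np.random.Generator):
        matrix = np.asarray(matrix)
        self.n_rows, self.n_cols = matrix.shape
        self.rows = [set(np.flatnonzero(matrix[i]).tolist())
                     for i in range(self.n_rows)]
        self.rng = rng
        # stdlib shuffle is much faster on the tiny pools traded here;
        # seeded from the numpy generator to stay reproducible
        import random as _random
        self._shuffle = _random.Random(int(rng.integers(2 ** 63))).shuffle
        self._pair_buf: list[tuple[int, int]] = []

    def _next_pair(self) -> tuple[int, int]:
        if not self._pair_buf:
            a = self.rng.integers(0, self.n_rows, size=2048)
            b = self.rng.integers(0, self.n_rows - 1, size=2048)
            b = np.where(b >= a, b + 1, b)  # uniform over distinct pairs
            self._pair_buf = list(zip(a.tolist(), b.tolist()))
        return self._pair_buf.pop()

    def trade(self) -> int:
        """One curveball trade; returns the number of cells exchanged."""
        i, j = self._next_pair()
        ri, rj = self.rows[i], self.rows[j]
        set_i = ri - rj
        set_j = rj - ri
        if not set_i or not set_j:
            return 0
        pool = list(set_i) + list(set_j)
        self._shuffle(pool)
        k = len(set_i)
        new_i = set(pool[:k])
        moved = len(new_i - set_i)
        if moved == 0:
            return 0
        self.rows[i] = (ri - set_i) | new_i
        self.rows[j] = (rj - set_j) | ((set_i | set_j) - new_i)
        return 2 * moved  # k columns traded touch k cells in each row

    def run_swaps(self, n_swaps: int, max_trades: Optional[int] = None) -> int:
        """Trade until ``n_swaps`` cells have been exchanged."""
        if max_trades is None:
            max_trades = 200 * max(n_swaps, 1) + 1000
        done = trades = 0
        while done < n_swaps and trades < max_trades:
            done += self.trade()
            trades += 1
        return done

    def membership(self) -> np.ndarray:
        out = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        for i, cols in enumerate(self.rows):
            out[i, list(cols)] = True
        return out


def _has_trade(matrix: np.ndarray) -> bool:
    """True iff some curveball trade can change the matrix, i.e. the
    matrix is not the unique one with its margins."""
    rows = [set(np.flatnonzero(matrix[i]).tolist())
            for i in range(matrix.shape[0])]
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            if (rows[i] - rows[j]) and (rows[j] - rows[i]):
                return True
    return False


@dataclass
class NullEnsemble:
    """A sample of degree-preserving permutations of one network."""

    matrices: list[np.ndarray]
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    settings: dict = field(default_factory=dict)
    degenerate: bool = False


def _chain_settings(fill: int, burn_in: Optional[int],
                    thinning: Optional[int]) -> tuple[int, int]:
    if burn_in is None:
        burn_in = 10 * fill
    if thinning is None:
        thinning = fill
    return burn_in, thinning


def degree_preserving_nulls(network: BipartiteNetwork, n_perm: int,
                            seed: Optional[int] = None,
                            burn_in: Optional[int] = None,
                            thinning: Optional[int] = None) -> NullEnsemble:
    """Sample ``n_perm`` binary matrices with the observed margins.

    Burn-in defaults to 10x(number of 1s) exchanged cells and thinning to
    (number of 1s) exchanged cells between samples.  A degenerate network
    (no swappable 2x2 submatrix: the margins admit a single matrix) yields
    an ensemble of identical copies with a warning; the signal test then
    returns p = 1.
    """
    m = network.matrix()
    fill = int(m.sum())
    if not _has_trade(m):
        logger.warning("network margins admit a single matrix; "
                       "null ensemble is degenerate")
        return NullEnsemble([m.copy() for _ in range(n_perm)],
                            tuple(network.row_ids), tuple(network.col_ids),
                            settings={"n_perm": n_perm, "seed": seed,
                                      "burn_in": 0, "thinning": 0},
                            degenerate=True)
    burn, thin = _chain_settings(fill, burn_in, thinning)
    rng = np.random.default_rng(seed)
    sampler = CurveballSampler(m, rng)
    sampler.run_swaps(burn)
    out = []
    for _ in range(n_perm):
        sampler.run_swaps(thin)
        out.append(sampler.membership().astype(np.int8))
    return NullEnsemble(out, tuple(network.row_ids), tuple(network.col_ids),
                        settings={"n_perm": n_perm, "seed": seed,
                                  "burn_in": burn, "thinning": thin})


# ----------------------------------------------------------- signal test
def _focal_distances(focal: Union[DistanceMatrix, TreeNode],
                     ids: Sequence[str]) -> np.ndarray:
    """Distance matrix among ``ids`` from a tree (patristic) or matrix."""
    if isinstance(focal, TreeNode):
        focal = patristic_distances(focal)
    missing = set(ids) - set(focal.ids)
    if missing:
        raise ValueError(f"species missing from focal distances: "
                         f"{sorted(missing)}")
    return np.asarray(focal.filter(ids).data)


def _triangle_corr_factory(x: np.ndarray):
    """Closure computing Pearson r of ``x`` against later vectors."""
    xc = x - x.mean()
    nx = np.linalg.norm(xc)
    if nx == 0:
        return None
    xn = xc / nx

    def corr(y: np.ndarray) -> float:
        yc = y - y.mean()
        ny = np.linalg.norm(yc)
        if ny == 0:
            return float("nan")
        return float(xn @ yc / ny)

    return corr


def functional_signal_test(network: BipartiteNetwork,
                           focal: Union[DistanceMatrix, TreeNode],
                           partner_tree: TreeNode,
                           side: str = "rows",
                           n_perm: int = 10_000,
                           seed: Optional[int] = None,
                           burn_in: Optional[int] = None,
                           thinning: Optional[int] = None,
                           clade_id: Optional[str] = None) -> SignalResult:
    """Test whether functionally similar species interact with similar
    partner sets.

    ``focal`` supplies the functional distances among the focal side's
    species (a functional tree, from which patristic distances are taken,
    or a precomputed distance matrix); ``partner_tree`` is the opposite
    side's functional tree on which partner sets are compared with
    unweighted UniFrac.  The permutation null preserves every species'
    number of partners on both sides.
    """
    net = network.oriented(side)
    ids = net.row_ids
    n = len(ids)
    if n < 3:
        raise ValueError("signal test needs at least 3 focal species")
    fd = _focal_distances(focal, ids)
    idx = TreeEdgeIndex(partner_tree)
    missing = set(net.col_ids) - set(idx.tip_names)
    if missing:
        raise ValueError(f"partners absent from partner tree: "
                         f"{sorted(missing)}")
    col_pos = [idx.tip_names.index(c) for c in net.col_ids]
    m = net.matrix()
    L = len(idx.tip_names)
    P_obs = np.zeros((n, L), dtype=bool)
    P_obs[:, col_pos] = m.astype(bool)

    tri = np.tril_indices(n, k=-1)
    x = fd[tri]
    corr = _triangle_corr_factory(x)
    pd_obs = idx.pairwise_unifrac(P_obs)
    y_obs = pd_obs[tri]
    if corr is None or np.ptp(y_obs) == 0:
        note = ("zero variance in functional distances" if corr is None
                else "all focal species share one partner set")
        return SignalResult(side=side, mantel_r=float("nan"), n_perm=n_perm,
                            p_value=1.0, n_species=n, clade_id=clade_id,
                            note=note)
    r_obs = corr(y_obs)

    fill = int(m.sum())
    if not _has_trade(m):
        logger.warning("degenerate network: margins admit a single matrix; "
                       "p = 1 by construction")
        return SignalResult(side=side, mantel_r=r_obs, n_perm=n_perm,
                            p_value=1.0, n_species=n, clade_id=clade_id,
                            note="degenerate margins (single matrix)")
    burn, thin = _chain_settings(fill, burn_in, thinning)
    rng = np.random.default_rng(seed)
    sampler = CurveballSampler(m, rng)
    sampler.run_swaps(burn)
    count = 0
    P_null = np.zeros((n, L), dtype=bool)
    for _ in range(n_perm):
        sampler.run_swaps(thin)
        P_null[:, :] = False
        P_null[:, col_pos] = sampler.membership()
        r_null = corr(idx.pairwise_unifrac(P_null)[tri])
        # an undefined null correlation is counted against the signal
        if math.isnan(r_null) or r_null >= r_obs:
            count += 1
    return SignalResult(side=side, mantel_r=r_obs, n_perm=n_perm,
                        p_value=permutation_p(count, n_perm), n_species=n,
                        clade_id=clade_id)


# ------------------------------------------------------------ clade scan
def _label_nodes(tree: TreeNode) -> None:
    """Give unnamed internal nodes stable preorder ids (node0, node1...)."""
    for k, node in enumerate(tree.traverse(include_self=True)):
        if not node.is_tip() and not node.name:
            node.name = f"node{k}"


def clade_signal_scan(network: BipartiteNetwork,
                      focal_tree: TreeNode,
                      partner_tree: TreeNode,
                      side: str = "rows",
                      min_clade_size: int = 15,
                      n_perm: int = 10_000,
                      seed: Optional[int] = None,
                      count_in_network: bool = True,
                      burn_in: Optional[int] = None,
                      thinning: Optional[int] = None) -> list[SignalResult]:
    """Run the signal test within every large clade of the focal tree.

    Every internal node with at least ``min_clade_size`` descendant species
    (counted among species present in the network by default, or among all
    tree tips with ``count_in_network=False``) defines a sub-network: the
    focal side restricted to the clade, opposite-side species left without
    interactions dropped.  Raw p-values get a Bonferroni adjustment whose
    multiplier is the number of clades actually tested.  Degenerate clades
    (fewer than 3 focal species, or fewer than 2 distinct partner sets)
    are skipped with a logged reason.
    """
    net = network.oriented(side)
    in_net = set(net.row_ids)
    tips = {str(t.name) for t in focal_tree.tips()}
    if not in_net <= tips:
        raise ValueError(f"species missing from focal tree: "
                         f"{sorted(in_net - tips)}")
    _label_nodes(focal_tree)
    focal_full = patristic_distances(focal_tree)

    candidates = []
    for node in focal_tree.traverse(include_self=True):
        if node.is_tip():
            continue
        clade_tips = [str(t.name) for t in node.tips()]
        present = [t for t in clade_tips if t in in_net]
        size = len(present) if count_in_network else len(clade_tips)
        if size < min_clade_size:
            continue
        candidates.append((str(node.name), present))

    results: list[SignalResult] = []
    seeds = np.random.SeedSequence(seed).spawn(len(candidates))
    for (clade_id, present), ss in zip(candidates, seeds):
        if len(present) < 3:
            logger.info("clade %s skipped: %d focal species in network",
                        clade_id, len(present))
            continue
        sub_inc = net.incidence.loc[present]
        keep_cols = sub_inc.columns[(sub_inc.sum(axis=0) > 0)]
        sub_inc = sub_inc[keep_cols]
        partner_sets = {tuple(row) for row in sub_inc.to_numpy()}
        if len(partner_sets) < 2:
            logger.info("clade %s skipped: all species share one partner set",
                        clade_id)
            continue
        sub_net = BipartiteNetwork(sub_inc)
        res = functional_signal_test(
            sub_net, focal_full.filter(present), partner_tree,
            side="rows", n_perm=n_perm,
            seed=int(ss.generate_state(1)[0] % (2 ** 31)),
            burn_in=burn_in, thinning=thinning, clade_id=clade_id)
        res.side = side
        results.append(res)
    m = len(results)
    for r in results:
        r.p_adjusted = min(1.0, r.p_value * m)
    return results
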