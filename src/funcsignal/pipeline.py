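"""High-level workflow: traits -> balanced Gower -> functional tree ->
signal tests on both network sides."""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .datatypes import BipartiteNetwork, SignalResult, TraitTable
from .gower import balance_contributions, gower_pairwise, standardize_traits
from .signal_test import clade_signal_scan, functional_signal_test
from .tree import patristic_distances, upgma

__all__ = [
    "functional_dissimilarity",
    "functional_tree",
    "analyze_network",
    "scan_clades",
]


def functional_dissimilarity(table: TraitTable, balance: bool = True,
                             seed: Optional[int] = None) -> DistanceMatrix:
    """Balanced (or plain uniform-weight) Gower dissimilarity from a raw
    trait table; continuous traits are standardized first."""
    std = standardize_traits(table) if not table.standardized else table
    weights = balance_contributions(std, seed=seed) if balance else None
    return gower_pairwise(std, weights)


def functional_tree(source: Union[TraitTable, DistanceMatrix],
                    balance: bool = True,
                    seed: Optional[int] = None) -> TreeNode:
    """UPGMA functional tree from a trait table or a dissimilarity matrix."""
    if isinstance(source, TraitTable):
        source = functional_dissimilarity(source, balance=balance, seed=seed)
    return upgma(source)


def _spawn(seed: Optional[int], n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def analyze_network(network: BipartiteNetwork,
                    flea_traits: TraitTable, host_traits: TraitTable,
                    n_perm: int = 10_000, seed: Optional[int] = None,
                    balance: bool = True,
                    focal_distances: str = "tree"
                    ) -> dict[str, SignalResult]:
    """Whole-network functional-signal tests for both sides.

    ``focal_distances`` selects whether the Mantel test uses patristic
    distances on the focal side's functional tree (``"tree"``, default) or
    its raw Gower dissimilarities (``"gower"``).
    """
    if focal_distances not in ("tree", "gower"):
        raise ValueError("focal_distances must be 'tree' or 'gower'")
    s1, s2, s3, s4 = _spawn(seed, 4)
    flea_D = functional_dissimilarity(flea_traits, balance=balance, seed=s1)
    host_D = functional_dissimilarity(host_traits, balance=balance, seed=s2)
    flea_tree = upgma(flea_D)
    host_tree = upgma(host_D)
    flea_focal = patristic_distances(flea_tree) if focal_distances == "tree" \
        else flea_D
    host_focal = patristic_distances(host_tree) if focal_distances == "tree" \
        else host_D
    return {
        "fleas": functional_signal_test(network, flea_focal, host_tree,
                                        side="rows", n_perm=n_perm, seed=s3),
        "hosts": functional_signal_test(network, host_focal, flea_tree,
                                        side="cols", n_perm=n_perm, seed=s4),
    }


def scan_clades(network: BipartiteNetwork,
                flea_traits: TraitTable, host_traits: TraitTable,
                side: str = "rows", min_clade_size: int = 15,
                n_perm: int = 10_000, seed: Optional[int] = None,
                balance: bool = True,
                count_in_network: bool = True) -> list[SignalResult]:
    """Clade-restricted signal scan on one side, built from raw traits."""
    s1, s2, s3 = _spawn(seed, 3)
    flea_tree = functional_tree(flea_traits, balance=balance, seed=s1)
    host_tree = functional_tree(host_traits, balance=balance, seed=s2)
    focal_tree, partner_tree = (flea_tree, host_tree) if side == "rows" \
        else (host_tree, flea_tree)
    return clade_signal_scan(network, focal_tree, partner_tree, side=side,
                             min_clade_size=min_clade_size, n_perm=n_perm,
                             seed=s3, count_in_network=count_in_network)
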