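"""Simulation experiments that calibrate and validate the signal test:
type-I error under trait-independent networks, power as a function of the
planted signal strength, and clade-scan specificity with a planted clade.

These are the package's own quality-control experiments; they run entirely
on synthetic data from :mod:`funcsignal.synthetic_data`.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .datatypes import SignalResult
from .pipeline import functional_dissimilarity, functional_tree
from .signal_test import clade_signal_scan, functional_signal_test
from .synthetic_data import (generate_clustered_traits, generate_network,
                             generate_traits)
from .tree import patristic_distances, upgma

__all__ = [
    "single_network_test",
    "estimate_type_i_error",
    "power_curve",
    "planted_clade_experiment",
]

#: Trait mix used by the simulation experiments: three correlated
#: continuous traits, one ranked and one nominal trait, 5% missing cells.
TRAIT_CONFIG = dict(n_continuous=3, n_ordinal=1, n_nominal=1,
                    missing_rate=0.05)


def _child_seeds(seed: Optional[int], n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def single_network_test(seed: int, n_fleas: int = 25, n_hosts: int = 20,
                        signal_strength: float = 0.0,
                        connectance: float = 0.1,
                        n_perm: int = 200) -> SignalResult:
    """Generate one synthetic system and run the flea-side signal test."""
    s1, s2, s3, s4, s5, s6 = _child_seeds(seed, 6)
    fleas = generate_traits(n_fleas, seed=s1, prefix="f", **TRAIT_CONFIG)
    hosts = generate_traits(n_hosts, seed=s2, prefix="h", **TRAIT_CONFIG)
    net = generate_network(fleas, hosts, signal_strength=signal_strength,
                           target_connectance=connectance, seed=s3)
    flea_D = functional_dissimilarity(fleas, seed=s4)
    host_tree = functional_tree(hosts, seed=s5)
    focal = patristic_distances(upgma(flea_D))
    return functional_signal_test(net, focal, host_tree, side="rows",
                                  n_perm=n_perm, seed=s6)


def estimate_type_i_error(n_networks: int = 500, n_fleas: int = 25,
                          n_hosts: int = 20, connectance: float = 0.1,
                          n_perm: int = 200, alpha: float = 0.05,
                          seed: Optional[int] = None) -> dict:
    """Empirical false-positive rate of the signal test at ``alpha``.

    Networks are generated with zero trait-matching signal, so every
    rejection is a false positive.  Returns the rate, its binomial 95%
    confidence half-width, and the simulation size.
    """
    seeds = _child_seeds(seed, n_networks)
    rejections = 0
    for s in seeds:
        res = single_network_test(s, n_fleas=n_fleas, n_hosts=n_hosts,
                                  signal_strength=0.0,
                                  connectance=connectance, n_perm=n_perm)
        if res.p_value < alpha:
            rejections += 1
    rate = rejections / n_networks
    half = 1.96 * math.sqrt(max(rate * (1 - rate), 1e-12) / n_networks)
    return {"rate": rate, "rejections": rejections, "n": n_networks,
            "alpha": alpha, "ci_halfwidth": half,
            "nominal_ci_halfwidth": 1.96 * math.sqrt(
                alpha * (1 - alpha) / n_networks)}


def power_curve(signal_levels: Sequence[float] = (0.0, 1.0, 3.0, 10.0),
                n_reps: int = 100, n_fleas: int = 25, n_hosts: int = 20,
                connectance: float = 0.1, n_perm: int = 200,
                alpha: float = 0.05, seed: Optional[int] = None) -> dict:
    """Mean observed Mantel r and rejection rate at each signal strength.

    Replicate seeds are shared across levels, so the comparison between
    levels is paired.
    """
    seeds = _child_seeds(seed, n_reps)
    out = {}
    for s_level in signal_levels:
        rs, rej = [], 0
        for s in seeds:
            res = single_network_test(s, n_fleas=n_fleas, n_hosts=n_hosts,
                                      signal_strength=s_level,
                                      connectance=connectance, n_perm=n_perm)
            if not math.isnan(res.mantel_r):
                rs.append(res.mantel_r)
            if res.p_value < alpha:
                rej += 1
        out[s_level] = {"mean_r": float(np.mean(rs)) if rs else float("nan"),
                        "rejection_rate": rej / n_reps, "n": n_reps}
    return out


def planted_clade_experiment(n_reps: int = 30, n_fleas: int = 44,
                             n_hosts: int = 20, signal_strength: float = 8.0,
                             connectance: float = 0.12,
                             min_clade_size: int = 15, n_perm: int = 200,
                             alpha: float = 0.05,
                             seed: Optional[int] = None) -> dict:
    """Clade-scan specificity with signal planted in one functional clade.

    Flea traits come in two well-separated clusters so the functional
    dendrogram splits at the root; only cluster 0 gets trait-matched
    interactions.  For each replicate the scan's clades are classified by
    their overlap with the planted cluster, and the experiment counts how
    often planted-majority versus other clades are flagged (Bonferroni-
    adjusted p below ``alpha``).
    """
    seeds = _child_seeds(seed, n_reps)
    planted_tested = planted_hits = 0
    other_tested = other_hits = 0
    for s in seeds:
        s1, s2, s3, s4, s5 = _child_seeds(s, 5)
        fleas, clusters = generate_clustered_traits(
            n_fleas, n_clusters=2, separation=4.0, seed=s1, prefix="f",
            **TRAIT_CONFIG)
        hosts = generate_traits(n_hosts, seed=s2, prefix="h", **TRAIT_CONFIG)
        planted = [sid for sid, c in zip(fleas.species_ids, clusters)
                   if c == 0]
        net = generate_network(fleas, hosts, signal_strength=signal_strength,
                               target_connectance=connectance, seed=s3,
                               signal_rows=planted)
        flea_tree = functional_tree(fleas, seed=s4)
        host_tree = functional_tree(hosts, seed=s5)
        results = clade_signal_scan(net, flea_tree, host_tree, side="rows",
                                    min_clade_size=min_clade_size,
                                    n_perm=n_perm, seed=s)
        tip_sets = {r.clade_id: None for r in results}
        for node in flea_tree.traverse(include_self=True):
            if node.name in tip_sets:
                tip_sets[node.name] = {str(t.name) for t in node.tips()}
        planted_set = set(planted)
        for r in results:
            tips = tip_sets[r.clade_id]
            frac = len(tips & planted_set) / len(tips)
            flagged = (r.p_adjusted or 1.0) < alpha
            if frac > 0.8:      # essentially the planted clade
                planted_tested += 1
                planted_hits += flagged
            elif frac < 0.2:    # essentially the sibling clade
                other_tested += 1
                other_hits += flagged
    return {
        "planted_hit_rate": planted_hits / max(planted_tested, 1),
        "other_hit_rate": other_hits / max(other_tested, 1),
        "planted_tested": planted_tested, "other_tested": other_tested,
        "n_reps": n_reps,
    }
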