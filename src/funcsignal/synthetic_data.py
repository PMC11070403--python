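"""Synthetic mixed-type trait tables, bipartite networks with a tunable
trait-matching signal, and multi-region record sets.

The generator mirrors the structure of regional parasite-host survey
data: two species sets with continuous, ordinal and nominal traits
(missing values allowed), and a binary incidence matrix whose links may
depend on trait matching.  Each side gets a one-dimensional latent niche
score — the first principal coordinate of its balanced Gower matrix — and
the probability of a link decays exponentially with the niche mismatch,
``p_ij ∝ exp(-s |u_i - v_j|)``, scaled to a target connectance.  At
``s = 0`` links are independent of traits, which is exactly the null of
the signal test; increasing ``s`` makes trait-similar species share
partners, which is exactly its alternative.  A repair pass adds (never
removes) the highest-probability missing link for any species left
without partners, so generated networks always satisfy the
"at least one partner per species" inclusion rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (BipartiteNetwork, RegionalRecord, TraitColumn,
                        TraitTable)
from .gower import balance_contributions, gower_pairwise, standardize_traits

__all__ = [
    "generate_traits",
    "generate_clustered_traits",
    "generate_network",
    "EffectSpec",
    "generate_regional_records",
    "latent_niche",
]

logger = logging.getLogger(__name__)

_ORDINAL_LEVELS = ("small", "medium", "large", "very_large")
_NOMINAL_LEVELS = ("A", "B", "C")


def _traits_impl(n_species, n_continuous, n_ordinal, n_nominal, missing_rate,
                 rng, n_clusters, cluster_sep, prefix):
    if n_species < 3:
        raise ValueError("need at least 3 species")
    if not 0 <= missing_rate <= 0.3:
        raise ValueError("missing_rate must be in [0, 0.3]")
    if n_continuous + n_ordinal + n_nominal < 1:
        raise ValueError("need at least one trait")
    ids = [f"{prefix}{i:03d}" for i in range(n_species)]
    clusters = rng.integers(0, n_clusters, size=n_species) if n_clusters > 1 \
        else np.zeros(n_species, dtype=int)
    offsets = rng.standard_normal((n_clusters, max(n_continuous, 1)))
    offsets *= cluster_sep

    cols: list[TraitColumn] = []
    data: dict[str, np.ndarray] = {}
    # continuous block: correlated multivariate normal (rho = 0.3)
    if n_continuous:
        rho = 0.3
        cov = np.full((n_continuous, n_continuous), rho)
        np.fill_diagonal(cov, 1.0)
        X = rng.multivariate_normal(np.zeros(n_continuous), cov,
                                    size=n_species)
        X += offsets[clusters][:, :n_continuous]
        for k in range(n_continuous):
            name = f"cont{k}"
            cols.append(TraitColumn(name, "continuous"))
            data[name] = X[:, k]
    for k in range(n_ordinal):
        latent = rng.standard_normal(n_species)
        if n_clusters > 1:
            latent += cluster_sep * (clusters - (n_clusters - 1) / 2.0)
        cuts = np.quantile(latent, [0.25, 0.5, 0.8])
        idx = np.searchsorted(cuts, latent)
        name = f"ord{k}"
        cols.append(TraitColumn(name, "ordinal", levels=_ORDINAL_LEVELS))
        data[name] = np.array([_ORDINAL_LEVELS[i] for i in idx], object)
    for k in range(n_nominal):
        name = f"nom{k}"
        cols.append(TraitColumn(name, "nominal"))
        data[name] = rng.choice(_NOMINAL_LEVELS, size=n_species)
    df = pd.DataFrame(data, index=pd.Index(ids, name="species"),
                      columns=[c.name for c in cols])
    if missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        # never blank out a whole column or a whole species
        for j in range(mask.shape[1]):
            if mask[:, j].all():
                mask[rng.integers(0, n_species), j] = False
        for i in range(mask.shape[0]):
            if mask[i, :].all():
                mask[i, rng.integers(0, mask.shape[1])] = False
        # every species pair must share >= 1 observed trait, otherwise
        # its Gower dissimilarity would be undefined
        present = ~mask
        shared = present.astype(int) @ present.T.astype(int)
        for i, j in zip(*np.where(np.triu(shared == 0, k=1))):
            k = int(rng.integers(0, mask.shape[1]))
            mask[i, k] = mask[j, k] = False
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    return TraitTable(df, tuple(cols)), clusters


def generate_traits(n_species: int, n_continuous: int = 3,
                    n_ordinal: int = 1, n_nominal: int = 1,
                    missing_rate: float = 0.0,
                    seed: Optional[int] = None,
                    prefix: str = "sp") -> TraitTable:
    """Random mixed-type trait table, reproducible by seed.

    Continuous traits are drawn from a correlated multivariate normal,
    ordinal traits from thresholded latent normals (four ranked levels),
    nominal traits from uniform categorical draws; cells are masked at
    ``missing_rate`` without ever emptying a whole row or column.
    """
    rng = np.random.default_rng(seed)
    table, _ = _traits_impl(n_species, n_continuous, n_ordinal, n_nominal,
                            missing_rate, rng, 1, 0.0, prefix)
    return table


def generate_clustered_traits(n_species: int, n_clusters: int = 2,
                              separation: float = 3.0,
                              n_continuous: int = 3, n_ordinal: int = 1,
                              n_nominal: int = 1, missing_rate: float = 0.0,
                              seed: Optional[int] = None,
                              prefix: str = "sp"
                              ) -> tuple[TraitTable, np.ndarray]:
    """Trait table with planted functional clusters.

    Cluster-specific mean shifts of size ``separation`` on the continuous
    (and ordinal latent) traits make each cluster a clade of the
    functional dendrogram; returns the table and the cluster labels.
    """
    rng = np.random.default_rng(seed)
    return _traits_impl(n_species, n_continuous, n_ordinal, n_nominal,
                        missing_rate, rng, n_clusters, separation, prefix)


def latent_niche(table: TraitTable, seed: Optional[int] = None) -> np.ndarray:
    """First principal coordinate of the balanced Gower matrix, scaled to
    unit variance (zeros if the matrix is degenerate)."""
    std = standardize_traits(table)
    w = balance_contributions(std, seed=seed)
    D = np.asarray(gower_pairwise(std, w).data)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    lead = vals[-1]
    if lead <= 1e-12:
        return np.zeros(n)
    u = vecs[:, -1] * math.sqrt(lead)
    sd = u.std()
    u = u / sd if sd > 0 else u
    # deterministic sign convention
    if u[np.argmax(np.abs(u))] < 0:
        u = -u
    return u


def generate_network(flea_traits: TraitTable, host_traits: TraitTable,
                     signal_strength: float = 0.0,
                     target_connectance: float = 0.1,
                     seed: Optional[int] = None,
                     signal_rows: Optional[Sequence[str]] = None
                     ) -> BipartiteNetwork:
    """Binary bipartite network whose links match traits with strength
    ``signal_strength``.

    With ``signal_rows`` given, only those parasite species receive
    trait-matched interaction probabilities; the rest get the flat average
    probability, so a functional clade can carry signal while its siblings
    do not.  ``signal_strength = 0`` yields trait-independent networks.
    """
    if not 0 < target_connectance < 1:
        raise ValueError("target_connectance must be in (0, 1)")
    if signal_strength < 0:
        raise ValueError("signal_strength must be >= 0")
    rng = np.random.default_rng(seed)
    nf, nh = flea_traits.n_species, host_traits.n_species
    if signal_strength == 0:
        w = np.ones((nf, nh))
    else:
        ss = np.random.SeedSequence(seed).spawn(2)
        u = latent_niche(flea_traits,
                         seed=int(ss[0].generate_state(1)[0] % 2**31))
        v = latent_niche(host_traits,
                         seed=int(ss[1].generate_state(1)[0] % 2**31))
        w = np.exp(-signal_strength * np.abs(u[:, None] - v[None, :]))
        if signal_rows is not None:
            rows = [flea_traits.species_ids.index(s) for s in signal_rows]
            flat = np.full(nh, w[rows].mean())
            mask = np.ones(nf, dtype=bool)
            mask[rows] = False
            w[mask] = flat
    p = target_connectance * w / w.mean()
    p = np.clip(p, 0.0, 1.0)
    inc = (rng.random((nf, nh)) < p).astype(np.int8)
    # repair pass: guarantee >= 1 partner per species by ADDING the
    # highest-probability missing link (never removing links); ties --
    # e.g. every candidate at s = 0 -- are broken uniformly at random
    def _argmax_random_tie(v):
        cand = np.flatnonzero(v >= v.max() - 1e-12)
        return int(rng.choice(cand))

    for i in np.flatnonzero(inc.sum(axis=1) == 0):
        inc[i, _argmax_random_tie(p[i])] = 1
    for j in np.flatnonzero(inc.sum(axis=0) == 0):
        inc[_argmax_random_tie(p[:, j]), j] = 1
    df = pd.DataFrame(inc, index=pd.Index(flea_traits.species_ids,
                                          name="species"),
                      columns=host_traits.species_ids)
    return BipartiteNetwork(df)


# -------------------------------------------------- regional record sets
@dataclass
class EffectSpec:
    """Declared true effects for one side of a regional simulation.

    ``detection`` and ``strength`` map predictor names (``n_fleas``,
    ``n_hosts``, ``network_size``, ``connectance``) to slopes on the
    z-scored predictor — logit scale for detection, response scale for
    strength.  Realm random intercepts have the given standard deviations.
    """

    detection: dict = field(default_factory=dict)
    strength: dict = field(default_factory=dict)
    detection_intercept: float = -0.3
    strength_intercept: float = 0.12
    strength_sd: float = 0.04
    realm_sd_detection: float = 0.8
    realm_sd_strength: float = 0.03


def generate_regional_records(n_regions: int,
                              realms: Sequence[str],
                              effect_spec: Optional[dict] = None,
                              seed: Optional[int] = None
                              ) -> list[RegionalRecord]:
    """Simulate per-region outcomes with declared predictor effects.

    ``effect_spec`` maps side ("fleas"/"hosts") to an :class:`EffectSpec`;
    omitted sides get no effects.  Region sizes are lognormal (roughly 5-60
    species per side), connectance uniform in [0.05, 0.3]; realms are
    assigned round-robin so each has records.
    """
    rng = np.random.default_rng(seed)
    effect_spec = effect_spec or {}
    realms = list(realms)
    if not realms:
        raise ValueError("need at least one realm")
    n_fleas = np.maximum(4, np.round(
        np.exp(rng.normal(math.log(18), 0.5, n_regions)))).astype(int)
    n_hosts = np.maximum(4, np.round(
        np.exp(rng.normal(math.log(14), 0.5, n_regions)))).astype(int)
    conn = rng.uniform(0.05, 0.3, n_regions)
    realm_of = [realms[i % len(realms)] for i in range(n_regions)]
    preds = {
        "n_fleas": n_fleas.astype(float),
        "n_hosts": n_hosts.astype(float),
        "network_size": (n_fleas * n_hosts).astype(float),
        "connectance": conn,
    }
    z = {k: (v - v.mean()) / v.std(ddof=1) for k, v in preds.items()}

    records = []
    side_draws = {}
    for side in ("fleas", "hosts"):
        spec = effect_spec.get(side, EffectSpec())
        u_det = {rm: rng.normal(0, spec.realm_sd_detection) for rm in realms}
        u_str = {rm: rng.normal(0, spec.realm_sd_strength) for rm in realms}
        eta = np.full(n_regions, spec.detection_intercept)
        mu = np.full(n_regions, spec.strength_intercept)
        for k, b in spec.detection.items():
            eta += b * z[k]
        for k, g in spec.strength.items():
            mu += g * z[k]
        eta += np.array([u_det[rm] for rm in realm_of])
        mu += np.array([u_str[rm] for rm in realm_of])
        det = rng.random(n_regions) < 1.0 / (1.0 + np.exp(-eta))
        val = mu + rng.normal(0, spec.strength_sd, n_regions)
        side_draws[side] = (det, np.clip(val, 0.001, 0.999))

    for i in range(n_regions):
        det_f, r_f = side_draws["fleas"][0][i], side_draws["fleas"][1][i]
        det_h, r_h = side_draws["hosts"][0][i], side_draws["hosts"][1][i]
        records.append(RegionalRecord(
            region=f"region{i:03d}", realm=realm_of[i],
            n_fleas=int(n_fleas[i]), n_hosts=int(n_hosts[i]),
            connectance=float(conn[i]),
            detected_fleas=bool(det_f), detected_hosts=bool(det_h),
            r_fleas=float(r_f) if det_f else None,
            r_hosts=float(r_h) if det_h else None,
        ))
    return records
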