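"""Core data model for trait-based signal analysis of bipartite networks.

The central objects are a species-by-trait table with a mixed-type schema,
a binary parasite-by-host incidence matrix, and the result record of a
single Mantel-type signal test.  Pairwise dissimilarities are represented
with :class:`skbio.DistanceMatrix` and trees with :class:`skbio.TreeNode`
throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_KINDS",
    "TraitColumn",
    "TraitTable",
    "BipartiteNetwork",
    "SignalResult",
    "RegionalRecord",
]

#: Recognised trait kinds.  ``multilabel`` columns are binary components of a
#: grouped trait (for example a species with a combination of lifestyles);
#: all components sharing a ``group`` are treated as ONE trait downstream.
TRAIT_KINDS = ("continuous", "ordinal", "nominal", "binary", "multilabel")


@dataclass(frozen=True)
class TraitColumn:
    """Descriptor for one column of a trait table.

    Parameters
    ----------
    name
        Column name, matching the CSV header.
    kind
        One of :data:`TRAIT_KINDS`.
    group
        Group identifier; required for ``multilabel`` components, ignored
        otherwise.
    levels
        Ordered category labels for ``ordinal`` columns.  If omitted the
        column must be numeric and its values are used as ranks directly.
    log_transform
        If true, the (continuous) column is log-transformed before
        standardization.  Used for heavy-tailed quantities such as
        geographic range size.
    """

    name: str
    kind: str
    group: Optional[str] = None
    levels: Optional[tuple] = None
    log_transform: bool = False

    def __post_init__(self):
        if self.kind not in TRAIT_KINDS:
            raise ValueError(
                f"unknown trait kind {self.kind!r} for column {self.name!r}; "
                f"expected one of {TRAIT_KINDS}"
            )
        if self.kind == "multilabel" and self.group is None:
            raise ValueError(
                f"multilabel column {self.name!r} requires a group identifier"
            )
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(self.levels))


@dataclass
class TraitTable:
    """A species x traits table with mixed-type columns and missing values.

    ``data`` is indexed by species id; missing cells are ``NaN``/``None`` and
    are never imputed.  ``schema`` declares the kind of every column.
    """

    data: pd.DataFrame
    schema: tuple[TraitColumn, ...]
    standardized: bool = False

    def __post_init__(self):
        self.schema = tuple(self.schema)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species ids: {dups}")
        if len(idx) < 2:
            raise ValueError("a trait table needs at least 2 species")
        names = [c.name for c in self.schema]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names in schema")
        if set(names) != set(self.data.columns):
            missing = set(names) - set(self.data.columns)
            extra = set(self.data.columns) - set(names)
            raise ValueError(
                f"schema/data column mismatch (missing={sorted(missing)}, "
                f"unexpected={sorted(extra)})"
            )
        for col in self.schema:
            if self.data[col.name].isna().all():
                raise ValueError(f"column {col.name!r} is entirely missing")

    # -- conveniences ----------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def n_species(self) -> int:
        return len(self.data.index)

    def column(self, name: str) -> TraitColumn:
        for c in self.schema:
            if c.name == name:
                return c
        raise KeyError(name)

    def subset(self, species: Sequence[str]) -> "TraitTable":
        return TraitTable(self.data.loc[list(species)].copy(), self.schema,
                          standardized=self.standardized)


@dataclass
class BipartiteNetwork:
    """Binary incidence matrix; parasites in rows, hosts in columns.

    Every species on either side must have at least one recorded partner:
    a row or column of zeros means the species was never observed
    interacting and does not belong in the network.
    """

    incidence: pd.DataFrame

    def __post_init__(self):
        self.incidence = self.incidence.astype(np.int8)
        self.validate()

    def validate(self) -> None:
        inc = self.incidence
        if inc.index.has_duplicates or inc.columns.has_duplicates:
            raise ValueError("row/column labels must be unique")
        vals = inc.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = sorted(set(np.unique(vals)) - {0, 1})
            raise ValueError(f"incidence matrix must be binary; found {bad}")
        if (vals.sum(axis=1) == 0).any():
            empty = inc.index[vals.sum(axis=1) == 0].tolist()
            raise ValueError(
                f"rows with no interactions: {empty}; every parasite must "
                "have at least one recorded host"
            )
        if (vals.sum(axis=0) == 0).any():
            empty = inc.columns[vals.sum(axis=0) == 0].tolist()
            raise ValueError(
                f"columns with no interactions: {empty}; only hosts with at "
                "least one recorded parasite belong in the network"
            )

    @property
    def row_ids(self) -> list[str]:
        return [str(s) for s in self.incidence.index]

    @property
    def col_ids(self) -> list[str]:
        return [str(s) for s in self.incidence.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.incidence.shape

    @property
    def n_links(self) -> int:
        return int(self.incidence.to_numpy().sum())

    @property
    def connectance(self) -> float:
        r, c = self.shape
        return self.n_links / (r * c)

    def matrix(self) -> np.ndarray:
        return self.incidence.to_numpy().astype(np.int8)

    def transpose(self) -> "BipartiteNetwork":
        return BipartiteNetwork(self.incidence.T)

    def oriented(self, side: str) -> "BipartiteNetwork":
        """Return the network with the focal ``side`` in rows."""
        if side == "rows":
            return self
        if side == "cols":
            return self.transpose()
        raise ValueError(f"side must be 'rows' or 'cols', got {side!r}")


@dataclass
class SignalResult:
    """Outcome of one Mantel-type functional-signal test.

    ``mantel_r`` is NaN when the partner dissimilarities have zero variance
    (all species share one partner set); the test then reports ``p_value``
    of 1 and a note explaining why.
    """

    side: str
    mantel_r: float
    n_perm: int
    p_value: float
    n_species: int
    clade_id: Optional[str] = None
    p_adjusted: Optional[float] = None
    note: Optional[str] = None

    def __post_init__(self):
        if self.side not in ("rows", "cols"):
            raise ValueError("side must be 'rows' or 'cols'")
        if not math.isnan(self.mantel_r) and not -1 - 1e-12 <= self.mantel_r <= 1 + 1e-12:
            raise ValueError(f"mantel_r out of [-1, 1]: {self.mantel_r}")
        floor = 1.0 / (self.n_perm + 1)
        if self.p_value < floor - 1e-15 or self.p_value > 1:
            raise ValueError(
                f"p_value {self.p_value} outside [{floor}, 1] for "
                f"{self.n_perm} permutations"
            )

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class RegionalRecord:
    """Per-region summary feeding the stage-2 (determinants) models.

    Detection flags and Mantel correlations are stored separately for the
    parasite side ("fleas") and the host side ("hosts"); a correlation is
    only recorded when the corresponding test was significant.
    """

    region: str
    realm: str
    n_fleas: int
    n_hosts: int
    connectance: float
    detected_fleas: bool = False
    detected_hosts: bool = False
    r_fleas: Optional[float] = None
    r_hosts: Optional[float] = None

    def __post_init__(self):
        if not 0 < self.connectance <= 1:
            raise ValueError(f"connectance must be in (0, 1]: {self.connectance}")

    @property
    def network_size(self) -> int:
        return self.n_fleas * self.n_hosts

    def detected(self, side: str) -> bool:
        return self.detected_fleas if side == "fleas" else self.detected_hosts

    def strength(self, side: str) -> Optional[float]:
        return self.r_fleas if side == "fleas" else self.r_hosts
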