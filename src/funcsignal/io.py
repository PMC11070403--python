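"""File I/O: CSV trait tables and incidence matrices, JSON schemas,
Newick trees, TSV/JSON result files.

Conventions: missing trait values are empty cells (or ``NA``) in CSV and
are never imputed; result files use a fixed column order and 6 significant
digits, and p-values are never rounded to zero.  All writers are
deterministic — identical inputs yield byte-identical files.
"""

from __future__ import annotations

import io as _io
import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .datatypes import (BipartiteNetwork, RegionalRecord, SignalResult,
                        TraitColumn, TraitTable)

__all__ = [
    "load_schema",
    "dump_schema",
    "read_trait_table",
    "write_trait_table",
    "read_network",
    "write_network",
    "read_dissimilarity",
    "write_dissimilarity",
    "read_tree",
    "write_tree",
    "write_results",
    "read_records",
    "write_records",
]

_NA_TOKENS = ("", "NA", "NaN", "nan")

RESULT_COLUMNS = ("side", "clade_id", "n_species", "mantel_r",
                  "p_value", "p_adjusted", "n_perm", "note")


# ---------------------------------------------------------------- schemas
def load_schema(schema: Union[str, Path, Sequence, dict]) -> tuple[TraitColumn, ...]:
    """Load a trait schema from a JSON file, a dict, or a sequence.

    The JSON layout is ``{"columns": [{"name": ..., "kind": ...,
    "group": ..., "levels": [...], "log_transform": ...}, ...]}``.
    """
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = json.load(fh)
    if isinstance(schema, dict):
        schema = schema["columns"]
    cols = []
    for c in schema:
        if isinstance(c, TraitColumn):
            cols.append(c)
        else:
            cols.append(TraitColumn(
                name=c["name"],
                kind=c["kind"],
                group=c.get("group"),
                levels=tuple(c["levels"]) if c.get("levels") else None,
                log_transform=bool(c.get("log_transform", False)),
            ))
    return tuple(cols)


def dump_schema(schema: Sequence[TraitColumn], path: Union[str, Path]) -> None:
    obj = {"columns": []}
    for c in schema:
        entry = {"name": c.name, "kind": c.kind}
        if c.group is not None:
            entry["group"] = c.group
        if c.levels is not None:
            entry["levels"] = list(c.levels)
        if c.log_transform:
            entry["log_transform"] = True
        obj["columns"].append(entry)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=False)
        fh.write("\n")


# ----------------------------------------------------------- trait tables
def read_trait_table(path: Union[str, Path],
                     schema: Union[str, Path, Sequence, dict]) -> TraitTable:
    """Read a species x traits CSV (first column = species id).

    Empty cells and ``NA`` tokens become missing values.  Raises on
    duplicate species ids, unknown trait kinds and all-missing columns.
    """
    cols = load_schema(schema)
    df = pd.read_csv(path, index_col=0, dtype=str,
                     keep_default_na=False, na_values=list(_NA_TOKENS))
    df.index = df.index.astype(str)
    for c in cols:
        if c.name not in df.columns:
            raise ValueError(f"column {c.name!r} declared in schema but "
                             f"absent from {path}")
        if c.kind in ("continuous", "multilabel", "binary") or (
                c.kind == "ordinal" and c.levels is None):
            df[c.name] = pd.to_numeric(df[c.name], errors="raise")
    return TraitTable(df[[c.name for c in cols]], cols)


def write_trait_table(table: TraitTable, path: Union[str, Path]) -> None:
    df = table.data.copy()
    df.index.name = df.index.name or "species"
    df.to_csv(path, na_rep="")


# --------------------------------------------------------------- networks
def read_network(path: Union[str, Path]) -> BipartiteNetwork:
    """Read a binary incidence CSV (parasites in rows, hosts in columns)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BipartiteNetwork(df)


def write_network(network: BipartiteNetwork, path: Union[str, Path]) -> None:
    df = network.incidence.copy()
    df.index.name = df.index.name or "species"
    df.to_csv(path)


# --------------------------------------------------- dissimilarity matrices
def read_dissimilarity(path: Union[str, Path]) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float),
                          ids=[str(i) for i in df.index])


def write_dissimilarity(dm: DistanceMatrix, path: Union[str, Path]) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.index.name = "id"
    df.to_csv(path, float_format="%.10g")


# ------------------------------------------------------------------- trees
def read_tree(source: Union[str, Path]) -> TreeNode:
    """Read a Newick tree from a path or a Newick string."""
    text = str(source)
    if "(" in text and ";" in text:  # literal newick
        return TreeNode.read(_io.StringIO(text))
    return TreeNode.read(str(source))


def write_tree(tree: TreeNode, path: Optional[Union[str, Path]] = None) -> str:
    buf = _io.StringIO()
    tree.write(buf)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ----------------------------------------------------------------- results
def _fmt(x, digits: int = 6) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        return f"{x:.{digits}g}"
    return str(x)


def write_results(results: Sequence[SignalResult], directory: Union[str, Path],
                  metadata: Optional[dict] = None) -> tuple[Path, Path]:
    """Write per-test rows as TSV plus a JSON run-metadata file.

    Returns the (tsv, json) paths.  Column order and numeric formatting are
    fixed so repeated runs with the same seed are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tsv = directory / "results.tsv"
    meta = directory / "run.json"
    with open(tsv, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            row = (r.side, r.clade_id if r.clade_id is not None else "NA",
                   r.n_species, _fmt(r.mantel_r), _fmt(r.p_value),
                   _fmt(r.p_adjusted), r.n_perm,
                   r.note if r.note else "NA")
            fh.write("\t".join(str(v) for v in row) + "\n")
    with open(meta, "w") as fh:
        json.dump(metadata or {}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return tsv, meta


# ------------------------------------------------------- regional records
_RECORD_COLUMNS = ("region", "realm", "n_fleas", "n_hosts", "network_size",
                   "connectance", "detected_fleas", "detected_hosts",
                   "r_fleas", "r_hosts")


def write_records(records: Sequence[RegionalRecord],
                  path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_RECORD_COLUMNS) + "\n")
        for r in records:
            row = (r.region, r.realm, r.n_fleas, r.n_hosts, r.network_size,
                   _fmt(r.connectance), int(r.detected_fleas),
                   int(r.detected_hosts), _fmt(r.r_fleas), _fmt(r.r_hosts))
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_records(path: Union[str, Path]) -> list[RegionalRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    records = []
    for _, row in df.iterrows():
        records.append(RegionalRecord(
            region=str(row["region"]), realm=str(row["realm"]),
            n_fleas=int(row["n_fleas"]), n_hosts=int(row["n_hosts"]),
            connectance=float(row["connectance"]),
            detected_fleas=bool(row["detected_fleas"]),
            detected_hosts=bool(row["detected_hosts"]),
            r_fleas=None if pd.isna(row["r_fleas"]) else float(row["r_fleas"]),
            r_hosts=None if pd.isna(row["r_hosts"]) else float(row["r_hosts"]),
        ))
    return records
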