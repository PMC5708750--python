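"""Read and write per-cell tables, pathway definitions, and metric outputs.

The cell table dialect is plain tab-separated text (UTF-8, header row), one
line per segmented cell.  Mandatory content per cell: centroid coordinates
(``x``, ``y``, in µm), a cell area (µm²) and biomarker values.  Biomarker
columns are named ``<marker>@<compartment>`` (e.g. ``GSK3B_pS9@cytosol``);
per-round staining-quality scores live in ``qc:<round>`` columns.  Missing
biomarker values are encoded as empty fields or ``NA`` and are preserved as
missing — this layer never imputes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

INTENSITY_SEP = "@"
QC_PREFIX = "qc:"

#: logical column name -> default physical column name
DEFAULT_SCHEMA: dict[str, str] = {
    "cell_id": "cell_id",
    "sample_id": "sample_id",
    "x": "x",
    "y": "y",
    "cell_area": "cell_area",
    "nuclear_area": "nuclear_area",
    "cytosol_area": "cytosol_area",
    "nuclei_count": "nuclei_count",
    "is_epithelial": "is_epithelial",
}

MANDATORY = ("x", "y", "cell_area")


class SchemaError(ValueError):
    """A mandatory column could not be resolved in the input table."""


@dataclasses.dataclass(frozen=True)
class PathwayNode:
    """One measurable node: a protein read out in one subcellular compartment,
    optionally in a specific phosphorylation state."""

    marker: str
    compartment: str
    phospho: str | None = None

    @property
    def key(self) -> str:
        """Panel key matching the intensity column convention."""
        marker = self.marker if self.phospho is None else f"{self.marker}_{self.phospho}"
        return f"{marker}{INTENSITY_SEP}{self.compartment}"


@dataclasses.dataclass(frozen=True)
class PathwayDefinition:
    """An ordered list of measurable nodes defining the state concatenation
    sequence.  The order is arbitrary but, once chosen, is fixed for a study:
    state keys are only comparable under a constant node order."""

    name: str
    nodes: tuple[PathwayNode, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) == 0:
            raise ValueError(f"pathway {self.name!r} has an empty node list")
        keys = [n.key for n in self.nodes]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise ValueError(f"pathway {self.name!r} has duplicate nodes: {sorted(dupes)}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def keys(self) -> list[str]:
        return [n.key for n in self.nodes]


@dataclasses.dataclass
class CellTable:
    """All segmented cells of one sample.

    ``cells`` holds one row per cell with the canonical columns of
    :data:`DEFAULT_SCHEMA` (those present in the input), plus ``qc:<round>``
    scores and ``<marker>@<compartment>`` intensity columns (NaN = missing).
    """

    sample_id: str
    cells: pd.DataFrame
    field_bounds: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if "cell_id" in self.cells.columns and self.cells["cell_id"].duplicated().any():
            raise ValueError(f"sample {self.sample_id!r}: duplicate cell_ids")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def intensity_columns(self) -> list[str]:
        return [c for c in self.cells.columns if INTENSITY_SEP in c]

    @property
    def qc_columns(self) -> list[str]:
        return [c for c in self.cells.columns if c.startswith(QC_PREFIX)]

    def bounds(self) -> tuple[float, float, float, float]:
        """Field bounds, defaulting to the centroid bounding box."""
        if self.field_bounds is not None:
            return self.field_bounds
        x, y = self.cells["x"], self.cells["y"]
        return (float(x.min()), float(x.max()), float(y.min()), float(y.max()))


def _resolve_schema(columns: Iterable[str], schema: Mapping[str, str] | None) -> dict[str, str]:
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    cols = set(columns)
    for logical in MANDATORY:
        if mapping[logical] not in cols:
            raise SchemaError(
                f"mandatory column {mapping[logical]!r} (for {logical!r}) not found"
            )
    return mapping


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> dict[str, CellTable]:
    """Read a per-cell TSV and split it into one :class:`CellTable` per sample.

    Parameters
    ----------
    path:
        Tab-separated file with a header row.
    schema:
        Optional overrides mapping logical names (``x``, ``cell_area``, ...)
        to physical column names.

    Returns
    -------
    dict mapping sample_id to its CellTable.  A file without a sample-id
    column yields a single table under sample id ``"sample"``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["", "NA"], keep_default_na=False)
    mapping = _resolve_schema(df.columns, schema)
    # rename physical -> logical for the canonical columns present
    rename = {phys: logical for logical, phys in mapping.items() if phys in df.columns}
    df = df.rename(columns=rename)

    numeric = [c for c in df.columns
               if c in DEFAULT_SCHEMA and c not in ("cell_id", "sample_id", "is_epithelial")]
    numeric += [c for c in df.columns if INTENSITY_SEP in c or c.startswith(QC_PREFIX)]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"non-numeric value in column {col!r} at line {row}") from exc
    if "is_epithelial" in df.columns:
        df["is_epithelial"] = df["is_epithelial"].map(
            lambda v: bool(int(v)) if str(v) in ("0", "1") else str(v).lower() == "true"
        )

    for col in ("cell_area", "nuclear_area", "cytosol_area"):
        if col in df.columns and (pd.to_numeric(df[col]) <= 0).any():
            raise ValueError(f"column {col!r} contains non-positive areas")
    if not np.isfinite(df[["x", "y"]].to_numpy(float)).all():
        raise ValueError("non-finite cell coordinates")

    if "sample_id" not in df.columns:
        df["sample_id"] = "sample"
    if "cell_id" not in df.columns:
        df["cell_id"] = np.arange(len(df))

    out: dict[str, CellTable] = {}
    for sid, sub in df.groupby("sample_id", sort=True):
        out[str(sid)] = CellTable(str(sid), sub.reset_index(drop=True))
    return out


def write_cell_table(tables: Iterable[CellTable], path: str | Path) -> None:
    """Write cell tables back to the TSV dialect ``read_cell_table`` accepts."""
    frames = [t.cells for t in tables]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, na_rep="")


def read_pathway_definition(path: str | Path) -> PathwayDefinition:
    """Read an ordered pathway / gene-set definition from JSON or TSV.

    JSON: ``{"name": ..., "nodes": [{"marker":, "compartment":, "phospho":}, ...]}``.
    TSV: columns ``marker``, ``compartment`` and optional ``phospho``; file
    order defines the concatenation order.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        nodes = tuple(
            PathwayNode(n["marker"], n["compartment"], n.get("phospho"))
            for n in payload["nodes"]
        )
        return PathwayDefinition(payload.get("name", path.stem), nodes)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "marker" not in df.columns or "compartment" not in df.columns:
        raise SchemaError("pathway TSV needs 'marker' and 'compartment' columns")
    nodes = tuple(
        PathwayNode(
            row["marker"],
            row["compartment"],
            row["phospho"] if "phospho" in df.columns and row.get("phospho") else None,
        )
        for _, row in df.iterrows()
    )
    return PathwayDefinition(path.stem, nodes)


def write_metrics_table(
    metrics: Mapping[str, Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a per-sample metrics map as TSV, one row per sample.

    Column order is deterministic: ``sample_id`` first, then ``columns`` if
    given, else the sorted union of metric keys.  Floats keep 12 significant
    digits so a read-back round-trips.
    """
    if columns is None:
        keys: set[str] = set()
        for m in metrics.values():
            keys.update(m)
        columns = sorted(keys)
    rows = [{"sample_id": sid, **{k: m.get(k) for k in columns}} for sid, m in metrics.items()]
    df = pd.DataFrame(rows, columns=["sample_id", *columns])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
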