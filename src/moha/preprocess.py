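"""Morphological / staining-quality filters and ordinal discretization.

Segmentation artifacts are removed by morphological criteria (nuclei count,
area bounds, image-edge margin, epithelial mask membership); biomarker
measures from degraded staining rounds are masked out; surviving intensities
are converted to ordinal levels with an n-state threshold model whose
cutpoints are percentiles of the study-wide pooled intensities.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cell_table_io import QC_PREFIX, CellTable


@dataclasses.dataclass
class QualityFilterConfig:
    """Morphological and QC filter settings.

    Area bounds (µm²) apply to the nuclear and cytosol areas when those
    columns are present, otherwise to the whole-cell area.  ``edge_margin``
    removes cells whose centroid lies within that many µm of the field
    bounds.  Samples retaining fewer than ``min_cells_per_sample`` cells are
    flagged excluded.
    """

    min_area: float = 1.4
    max_area: float = 140.0
    allowed_nuclei: frozenset[int] = frozenset({1, 2})
    edge_margin: float = 2.0
    min_cells_per_sample: int = 100
    qc_round_threshold: float = 0.8
    epithelial_only: bool = True

    def __post_init__(self) -> None:
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")
        if not 0.0 <= self.qc_round_threshold <= 1.0:
            raise ValueError("qc_round_threshold must lie in [0, 1]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["allowed_nuclei"] = sorted(self.allowed_nuclei)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "QualityFilterConfig":
        d = json.loads(text)
        d["allowed_nuclei"] = frozenset(d["allowed_nuclei"])
        return cls(**d)


@dataclasses.dataclass
class ThresholdModel:
    """Per-(marker, compartment) intensity cutpoints for n ordinal states.

    ``cutpoints[key]`` holds the n−1 sorted threshold intensities for one
    panel key; a value's level is the number of cutpoints strictly below it
    (ties fall in the lower bin).
    """

    n_states: int
    cutpoints: dict[str, list[float]]
    percentile_spec: list[float]

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        for key, cps in self.cutpoints.items():
            if len(cps) != self.n_states - 1:
                raise ValueError(f"{key!r}: expected {self.n_states - 1} cutpoints")
            if any(a > b for a, b in zip(cps, cps[1:])):
                raise ValueError(f"{key!r}: cutpoints must be non-decreasing")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ThresholdModel":
        return cls(**json.loads(text))


@dataclasses.dataclass
class FilterReport:
    sample_id: str
    n_input: int
    removed: dict[str, int]
    n_surviving: int
    excluded: bool


def apply_morphology_filters(
    table: CellTable, config: QualityFilterConfig | None = None
) -> tuple[CellTable, FilterReport]:
    """Drop cells failing the morphological quality criteria.

    Returns the filtered table plus a report counting removals per criterion
    (a cell failing several criteria is counted under each).  The report's
    ``excluded`` flag is set when fewer than ``min_cells_per_sample`` cells
    survive.
    """
    config = config or QualityFilterConfig()
    df = table.cells
    if "cell_area" not in df.columns:
        raise ValueError("cell table lacks an area column")
    n = len(df)
    ok = pd.Series(True, index=df.index)
    removed: dict[str, int] = {}

    area_cols = [c for c in ("nuclear_area", "cytosol_area") if c in df.columns]
    if not area_cols:
        area_cols = ["cell_area"]
    bad_area = pd.Series(False, index=df.index)
    for col in area_cols:
        bad_area |= (df[col] < config.min_area) | (df[col] > config.max_area)
    removed["area"] = int(bad_area.sum())
    ok &= ~bad_area

    if "nuclei_count" in df.columns:
        bad_nuc = ~df["nuclei_count"].isin(list(config.allowed_nuclei))
        removed["nuclei"] = int(bad_nuc.sum())
        ok &= ~bad_nuc

    xmin, xmax, ymin, ymax = table.bounds()
    m = config.edge_margin
    bad_edge = (
        (df["x"] < xmin + m) | (df["x"] > xmax - m)
        | (df["y"] < ymin + m) | (df["y"] > ymax - m)
    )
    removed["edge"] = int(bad_edge.sum())
    ok &= ~bad_edge

    if config.epithelial_only and "is_epithelial" in df.columns:
        bad_epi = ~df["is_epithelial"].astype(bool)
        removed["epithelial"] = int(bad_epi.sum())
        ok &= ~bad_epi

    surv = df[ok].reset_index(drop=True)
    report = FilterReport(
        sample_id=table.sample_id,
        n_input=n,
        removed=removed,
        n_surviving=len(surv),
        excluded=len(surv) < config.min_cells_per_sample,
    )
    return CellTable(table.sample_id, surv, table.field_bounds), report


def apply_qc_round_filter(
    table: CellTable,
    round_of_marker: Mapping[str, str],
    threshold: float = 0.8,
) -> CellTable:
    """Mask biomarker measures from low-quality staining rounds.

    For each intensity column whose marker maps to a round, cells with that
    round's quality score below ``threshold`` get the intensity set to
    missing.  Cells themselves are retained.
    """
    df = table.cells.copy()
    for col in table.intensity_columns:
        marker = col.split("@", 1)[0]
        if marker not in round_of_marker:
            continue
        qc_col = QC_PREFIX + str(round_of_marker[marker])
        if qc_col not in df.columns:
            raise KeyError(
                f"marker {marker!r} references round {round_of_marker[marker]!r} "
                f"but column {qc_col!r} is absent"
            )
        df.loc[df[qc_col] < threshold, col] = np.nan
    return CellTable(table.sample_id, df, table.field_bounds)


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile of pooled values: the ceil(p/100·n)-th sorted
    value, no interpolation.  Bit-reproducible across platforms."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("no values")
    rank = int(np.ceil(pct / 100.0 * n))
    rank = min(max(rank, 1), n)
    return float(v[rank - 1])


def fit_thresholds(
    tables: Iterable[CellTable],
    n_states: int = 3,
    percentiles: Sequence[float] | None = None,
) -> ThresholdModel:
    """Fit study-wide cutpoints per (marker, compartment) panel key.

    Intensities are pooled over all samples (the study), missing values
    dropped; the cutpoints are nearest-rank percentiles of the pooled sorted
    values (defaults 33/67 for the three-state model).
    """
    if percentiles is None:
        # equal-occupancy split to the nearest integer percentile: the
        # three-state default is the study's 33rd and 67th
        percentiles = [round(100.0 * k / n_states) for k in range(1, n_states)]
    if len(percentiles) != n_states - 1:
        raise ValueError("need n_states - 1 percentiles")
    tables = list(tables)
    keys: list[str] = []
    for t in tables:
        for c in t.intensity_columns:
            if c not in keys:
                keys.append(c)
    cutpoints: dict[str, list[float]] = {}
    for key in keys:
        pooled = np.concatenate(
            [t.cells[key].dropna().to_numpy(float) for t in tables if key in t.cells.columns]
        ) if any(key in t.cells.columns for t in tables) else np.array([])
        if pooled.size == 0:
            raise ValueError(f"panel key {key!r} has no non-missing intensities")
        cutpoints[key] = [nearest_rank_percentile(pooled, p) for p in percentiles]
    return ThresholdModel(n_states, cutpoints, list(percentiles))


def ordinalize(table: CellTable, model: ThresholdModel) -> pd.DataFrame:
    """Convert a sample's intensities to ordinal levels.

    Returns a DataFrame indexed like the cell table, one column per panel
    key, values in {0..n_states−1} as floats with NaN for missing.  The
    level of a value is the number of cutpoints strictly below it; a value
    equal to a cutpoint falls in the lower bin.
    """
    cols = table.intensity_columns
    missing = [c for c in cols if c not in model.cutpoints]
    if missing:
        raise KeyError(f"threshold model lacks cutpoints for {missing}")
    out = {}
    for col in cols:
        v = table.cells[col].to_numpy(float)
        cps = np.asarray(model.cutpoints[col], dtype=float)
        lev = np.searchsorted(cps, v, side="left").astype(float)
        lev[np.isnan(v)] = np.nan
        out[col] = lev
    df = pd.DataFrame(out, index=table.cells.index)
    if "cell_id" in table.cells.columns:
        df.index = pd.Index(table.cells["cell_id"], name="cell_id")
    return df
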