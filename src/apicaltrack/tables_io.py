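"""Typed data model and CSV I/O for tracked cell/junction tables.

Four tables make up a dataset:

* ``cell_surfaces`` — one row per cell per frame (geometry, per-domain
  intensities, genotype context).
* ``junctions`` — one row per junction per frame (endpoints, lengths,
  orientation, intensities).
* ``cell_surface_stats`` / ``junction_stats`` — one row per track with the
  delta statistics (final minus initial standardized value).

Columns follow the data dictionary of the public tracking deposits this
package consumes; common misspelled variants (``*_standarized``) are accepted
on read and normalized.  Missing values are serialized as empty strings and
parsed as missing, never as zero.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CELL_COLUMNS",
    "JUNCTION_COLUMNS",
    "CELL_STATS_COLUMNS",
    "JUNCTION_STATS_COLUMNS",
    "TABLE_COLUMNS",
    "Dataset",
    "EmbryoConfig",
    "SchemaError",
    "ValidationReport",
    "Violation",
    "read_tables",
    "write_tables",
    "validate",
    "encode_vertices",
    "parse_vertices",
]

# Canonical column order, one list per table.
CELL_COLUMNS = [
    "region",
    "movie",
    "track_id_cells",
    "minute",
    "center_x_cells",
    "center_y_cells",
    "vx_coords_cells",
    "CRISPR",
    "control_neighbors",
    "crispant_neighbors",
    "apical_area_pixels",
    "apical_area_pixels_smoothed",
    "apical_area_micron_smoothed",
    "apical_area_standardized",
    "medial_actin",
    "medial_actin_smoothed",
    "medial_actin_standardized",
    "junctional_actin",
    "junctional_actin_smoothed",
    "junctional_actin_standardized",
    "medial_Ncadherin",
    "medial_Ncadherin_smoothed",
    "medial_Ncadherin_standardized",
    "junctional_Ncadherin",
    "junctional_Ncadherin_smoothed",
    "junctional_Ncadherin_standardized",
    "medial_memBFP",
    "medial_memBFP_smoothed",
    "junctional_memBFP",
    "junctional_memBFP_smoothed",
]

JUNCTION_COLUMNS = [
    "region",
    "movie",
    "track_id_junctions",
    "CRISPR",
    "minute",
    "vx_1_x",
    "vx_1_y",
    "vx_2_x",
    "vx_2_y",
    "actin",
    "actin_smooth",
    "actin_standardized",
    "Ncadherin",
    "Ncadherin_smooth",
    "Ncadherin_standardized",
    "length_px",
    "length_micron",
    "delta_z_micron",
    "length_corrected",
    "length_smooth",
    "length_standardized",
    "orientation",
]

CELL_STATS_COLUMNS = [
    "region",
    "movie",
    "track_id_cells",
    "CRISPR",
    "at_mosaic_interface",
    "start_area_micron",
    "end_area_micron",
    "delta_apical_area",
    "delta_medial_actin",
    "delta_junctional_actin",
    "delta_medial_Ncadherin",
    "delta_junctional_Ncadherin",
]

JUNCTION_STATS_COLUMNS = [
    "region",
    "movie",
    "track_id_junctions",
    "CRISPR",
    "delta_length",
    "delta_actin",
    "delta_Ncadherin",
    "mean_orientation",
]

TABLE_COLUMNS: dict[str, list[str]] = {
    "cell_surfaces": CELL_COLUMNS,
    "junctions": JUNCTION_COLUMNS,
    "cell_surface_stats": CELL_STATS_COLUMNS,
    "junction_stats": JUNCTION_STATS_COLUMNS,
}

# Mandatory identifier columns per table; all other dictionary columns may be
# absent (reported missing, not fatal).
MANDATORY = {
    "cell_surfaces": ["region", "movie", "track_id_cells", "minute"],
    "junctions": ["region", "movie", "track_id_junctions", "minute"],
    "cell_surface_stats": ["region", "movie", "track_id_cells"],
    "junction_stats": ["region", "movie", "track_id_junctions"],
}

_STRING_COLUMNS = {"region", "movie", "CRISPR", "vx_coords_cells"}
_INT_COLUMNS = {"minute", "control_neighbors", "crispant_neighbors"}
_BOOL_COLUMNS = {"at_mosaic_interface"}
# track identifiers may be numeric or arbitrary strings
_ID_COLUMNS = {"track_id_cells", "track_id_junctions"}

# Misspellings seen in the wild -> canonical names.
_ALIASES = {
    "apical_area_standarized": "apical_area_standardized",
    "medial_actin_standarized": "medial_actin_standardized",
    "junctional_actin_standarized": "junctional_actin_standardized",
    "medial_Ncadherin_standarized": "medial_Ncadherin_standardized",
    "junctional_Ncadherin_standarized": "junctional_Ncadherin_standardized",
    "junctional_ memBFP": "junctional_memBFP",
    "junctional_ memBFP_smoothed": "junctional_memBFP_smoothed",
    "actin_standarized": "actin_standardized",
    "Ncadherin_standarized": "Ncadherin_standardized",
    "length_standarized": "length_standardized",
}

CONTROL = "control"
CRISPANT = "shroom3 crispant"
INTERFACE = "at mosaic interface"


class SchemaError(ValueError):
    """A table is missing mandatory columns or a cell cannot be parsed."""


def encode_vertices(vertices: np.ndarray | list) -> str:
    """Encode an ordered vertex list as ``X:Y#X:Y`` (pixel coordinates)."""
    return "#".join(f"{float(x):g}:{float(y):g}" for x, y in np.asarray(vertices))


def parse_vertices(text: str) -> np.ndarray:
    """Parse an ``X:Y#X:Y`` vertex string into an (n, 2) float array."""
    if not isinstance(text, str) or not text:
        return np.empty((0, 2))
    pairs = [p.split(":") for p in text.split("#")]
    return np.array([[float(x), float(y)] for x, y in pairs])


@dataclass
class Dataset:
    """A full tracked dataset: frame-by-frame tables plus track summaries.

    Tables absent from a read are ``None``; ``tables()`` iterates the present
    ones by canonical name.
    """

    cells: pd.DataFrame | None = None
    junctions: pd.DataFrame | None = None
    cell_stats: pd.DataFrame | None = None
    junction_stats: pd.DataFrame | None = None

    _ATTR = {
        "cell_surfaces": "cells",
        "junctions": "junctions",
        "cell_surface_stats": "cell_stats",
        "junction_stats": "junction_stats",
    }

    def tables(self):
        for name, attr in self._ATTR.items():
            df = getattr(self, attr)
            if df is not None:
                yield name, df

    def copy(self) -> "Dataset":
        return Dataset(
            **{
                attr: getattr(self, attr).copy()
                if getattr(self, attr) is not None
                else None
                for attr in self._ATTR.values()
            }
        )


@dataclass
class EmbryoConfig:
    """Per-embryo calibration and analysis configuration.

    Parameters
    ----------
    movie : embryo identifier matching the ``movie`` column.
    region : ``anterior`` or ``posterior``.
    microns_per_pixel : lateral pixel size, µm/px (> 0).
    z_step_micron : z-stack spacing, µm (> 0).
    ap_axis_angle_deg : image-frame angle of the embryonic AP axis in degrees
        (x rightward, y downward); the ML axis is this minus 90°.
    bfp_threshold : optional manual membrane-BFP genotype threshold; when set
        it overrides automatic thresholding.
    masked_frame_ranges : inclusive (start, end) frame ranges whose
        fluorescence values are discarded (imaging anomalies).
    genotype_overrides : manual per-track genotype annotations, applied last.
    """

    movie: str = "synthetic"
    region: str = "anterior"
    microns_per_pixel: float = 1.0
    z_step_micron: float = 1.0
    ap_axis_angle_deg: float = 90.0
    bfp_threshold: float | None = None
    masked_frame_ranges: list[tuple[int, int]] = field(default_factory=list)
    genotype_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.z_step_micron <= 0:
            raise ValueError("z_step_micron must be positive")
        ranges = []
        for r in self.masked_frame_ranges:
            start, end = int(r[0]), int(r[1])
            if end < start:
                raise ValueError(f"malformed masked frame range {r!r}")
            ranges.append((start, end))
        self.masked_frame_ranges = sorted(ranges)

    @classmethod
    def from_yaml(cls, path) -> "EmbryoConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown EmbryoConfig keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["masked_frame_ranges"] = [list(r) for r in self.masked_frame_ranges]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _coerce(df: pd.DataFrame, table: str) -> pd.DataFrame:
    for col in df.columns:
        if col in _STRING_COLUMNS:
            df[col] = df[col].astype("string").astype(object)
        elif col in _BOOL_COLUMNS:
            df[col] = df[col].map(
                lambda v: v
                if isinstance(v, (bool, np.bool_)) or pd.isna(v)
                else str(v).strip().lower() in ("true", "1")
            )
        elif col in _ID_COLUMNS:
            try:
                coerced = df[col].astype(float)
                if coerced.notna().all() and (coerced % 1 == 0).all():
                    coerced = coerced.astype(np.int64)
                df[col] = coerced
            except (ValueError, TypeError):
                df[col] = df[col].astype("string").astype(object)
        elif col in _INT_COLUMNS:
            df[col] = df[col].astype(float)
            if df[col].notna().all():
                df[col] = df[col].astype(np.int64)
        else:
            try:
                # float() per cell is exact round-trip, unlike to_numeric
                df[col] = df[col].astype(float)
            except (ValueError, TypeError) as exc:
                bad = None
                for i, v in enumerate(df[col]):
                    try:
                        float(v)
                    except (ValueError, TypeError):
                        bad = (i, v)
                        break
                raise SchemaError(
                    f"{table}: unparseable value {bad[1]!r} in column "
                    f"{col!r}, row {bad[0]}"
                ) from exc
    return df


def read_tables(paths: Mapping[str, object] | str | Path) -> Dataset:
    """Read dataset tables from CSV files.

    ``paths`` is either a mapping ``{table_name: path}`` or a directory
    containing files named ``<table>.csv``.  Unknown extra columns are
    preserved with a warning; mandatory identifier columns must be present.
    """
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        paths = {
            name: root / f"{name}.csv"
            for name in TABLE_COLUMNS
            if (root / f"{name}.csv").exists()
        }
        if not paths:
            raise FileNotFoundError(f"no dataset tables found under {root}")
    ds = Dataset()
    for name, path in paths.items():
        if name not in TABLE_COLUMNS:
            raise SchemaError(f"unknown table name {name!r}")
        df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=False, dtype=object)
        df = df.rename(columns=_ALIASES)
        missing = [c for c in MANDATORY[name] if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}: missing mandatory column(s) {missing}")
        extras = [c for c in df.columns if c not in TABLE_COLUMNS[name]]
        if extras:
            warnings.warn(f"{name}: preserving unknown extra column(s) {extras}")
        df = _coerce(df, name)
        order = [c for c in TABLE_COLUMNS[name] if c in df.columns] + extras
        setattr(ds, Dataset._ATTR[name], df[order].reset_index(drop=True))
    return ds


def write_tables(dataset: Dataset, out_dir) -> dict[str, Path]:
    """Write dataset tables as CSV under ``out_dir``.

    Floats are serialized with ``repr`` round-trip precision (>= 9 significant
    digits); missing values become empty strings.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in dataset.tables():
        known = [c for c in TABLE_COLUMNS[name] if c in df.columns]
        extras = [c for c in df.columns if c not in TABLE_COLUMNS[name]]
        path = out / f"{name}.csv"
        df[known + extras].to_csv(path, index=False, na_rep="")
        written[name] = path
    return written


@dataclass
class Violation:
    table: str
    row: int | None
    column: str | None
    message: str

    def __str__(self):
        loc = f"{self.table}"
        if self.row is not None:
            loc += f"[row {self.row}]"
        if self.column:
            loc += f".{self.column}"
        return f"{loc}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    def add(self, table, row, column, message):
        self.violations.append(Violation(table, row, column, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self):
        return len(self.violations)

    def __str__(self):
        if self.ok:
            return "validation: clean"
        return "\n".join(str(v) for v in self.violations)


_STD_TOL = 1e-9


def _check_standardized(report, table, df, col, track_col):
    """Per-track standardized series must have mean 0 and sample s.d. 1."""
    if col not in df.columns:
        return
    for (movie, track), grp in df.groupby(["movie", track_col], sort=False):
        vals = grp[col].astype(float).dropna()
        if len(vals) < 2:
            continue
        m, s = vals.mean(), vals.std(ddof=1)
        if abs(m) > _STD_TOL or abs(s - 1.0) > _STD_TOL:
            report.add(
                table,
                int(grp.index[0]),
                col,
                f"track {movie}/{track}: standardized series has "
                f"mean {m:.3g}, s.d. {s:.6g} (expected 0, 1)",
            )


def validate(dataset: Dataset) -> ValidationReport:
    """Check every declared invariant; returns a report of violations.

    An empty report means every invariant holds on the rows where the
    relevant columns are present and non-missing.
    """
    report = ValidationReport()
    cells = dataset.cells
    if cells is not None:
        if "apical_area_pixels" in cells.columns:
            bad = cells.index[cells["apical_area_pixels"].astype(float) <= 0]
            for i in bad:
                report.add("cell_surfaces", int(i), "apical_area_pixels",
                           "apical_area_pixels must be > 0")
        for (movie, track), grp in cells.groupby(["movie", "track_id_cells"],
                                                 sort=False):
            minutes = grp["minute"].to_numpy()
            if not np.all(np.diff(minutes) > 0):
                report.add("cell_surfaces", int(grp.index[0]), "minute",
                           f"track {movie}/{track}: minute not strictly increasing")
        for movie, grp in cells.groupby("movie", sort=False):
            if grp["region"].nunique() > 1:
                report.add("cell_surfaces", int(grp.index[0]), "region",
                           f"movie {movie}: region not constant")
        for col in cells.columns:
            if col.endswith("_standardized"):
                _check_standardized(report, "cell_surfaces", cells, col,
                                    "track_id_cells")

    jx = dataset.junctions
    if jx is not None:
        if "orientation" in jx.columns:
            ori = jx["orientation"].astype(float)
            for i in jx.index[(ori < 0) | (ori > 90)]:
                report.add("junctions", int(i), "orientation",
                           "orientation must lie in [0, 90]")
        if "delta_z_micron" in jx.columns:
            for i in jx.index[jx["delta_z_micron"].astype(float) < 0]:
                report.add("junctions", int(i), "delta_z_micron",
                           "delta_z_micron must be >= 0")
        if {"length_corrected", "length_micron"} <= set(jx.columns):
            lc = jx["length_corrected"].astype(float)
            lm = jx["length_micron"].astype(float)
            for i in jx.index[lc < lm - 1e-9]:
                report.add("junctions", int(i), "length_corrected",
                           "length_corrected must be >= length_micron")
        for col in jx.columns:
            if col.endswith("_standardized"):
                _check_standardized(report, "junctions", jx, col,
                                    "track_id_junctions")

    jstats = dataset.junction_stats
    if jstats is not None and "mean_orientation" in jstats.columns:
        mo = jstats["mean_orientation"].astype(float)
        for i in jstats.index[(mo < 0) | (mo > 90)]:
            report.add("junction_stats", int(i), "mean_orientation",
                       "mean_orientation must lie in [0, 90]")
    return report
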