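"""Gridded-raster data model, sample-table I/O, and predictor extraction.

Rasters are square-celled, row-major grids anchored at the north-west
corner; coordinates refer to cell centres.  Point-in-cell assignment uses
half-open intervals with the west and north edges inclusive, so a point on
a shared edge belongs to exactly one cell.  Missing cells are carried as
NaN in memory regardless of the on-disk sentinel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

EARTH_RADIUS_KM = 6371.0088

#: default column names for sample CSVs
SAMPLE_SCHEMA = {
    "sample_id": "sample_id",
    "longitude": "longitude_dd",
    "latitude": "latitude_dd",
    "sr_ratio": "sr87_sr86",
    "sample_type": "sample_type",
    "source": "source",
    "reference": "reference",
}

#: plausible bioavailable-Sr window; values outside trigger a warning only
SR_PLAUSIBLE = (0.70, 0.90)


class AlignmentError(ValueError):
    """Two grids disagree on CRS, origin, cell size or shape."""


class ConfigurationError(ValueError):
    """Invalid user configuration (missing columns, bad paths, bad grids)."""


class InfillError(RuntimeError):
    """Predictor infilling could not complete for one or more samples."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry and geodetic metadata of a raster grid.

    ``x_min``/``y_max`` are the outer (west/north) edges of the grid, in CRS
    units (decimal degrees for geographic CRSs).  ``cell_size`` is the square
    cell edge length in the same units.
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_max: float
    cell_size: float
    crs: str = "EPSG:4326"
    nodata: float = float("nan")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def is_geographic(self) -> bool:
        crs = self.crs.upper()
        return "4326" in crs or "WGS84" in crs or "WGS 84" in crs

    def cell_center(self, row, col):
        """Centre coordinates (x, y) of cell (row, col); accepts arrays."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x_min + (col + 0.5) * self.cell_size
        y = self.y_max - (row + 0.5) * self.cell_size
        return x, y

    def index_of(self, x, y):
        """Map point coordinates to (row, col).

        Half-open cells: the west and north edges are inclusive.  Points
        outside the grid extent get index -1 in the offending axis.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        # floor puts a point on a cell's west/north edge into that cell;
        # the grid's own east/south outer edges are excluded
        col = np.floor((x - self.x_min) / self.cell_size).astype(int)
        row = np.floor((self.y_max - y) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def matches(self, other: "GridSpec", atol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.x_min - other.x_min) <= atol
            and abs(self.y_max - other.y_max) <= atol
            and abs(self.cell_size - other.cell_size) <= atol
            and self.crs == other.crs
        )

    def cell_center_distances(self, row, col, rows, cols):
        """Distance from one cell centre to arrays of cell centres.

        Great-circle km for geographic CRSs, Euclidean CRS units otherwise.
        """
        x0, y0 = self.cell_center(row, col)
        xs, ys = self.cell_center(rows, cols)
        if self.is_geographic:
            return haversine_km(y0, x0, ys, xs)
        return np.hypot(xs - x0, ys - y0)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class Raster:
    """A single-band grid; missing cells are NaN."""

    values: np.ndarray
    spec: GridSpec

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise AlignmentError(
                f"raster shape {self.values.shape} != grid {self.spec.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values.astype(float))


def write_raster(raster: Raster, path) -> Path:
    """Write a single-band TIFF with the GridSpec as JSON metadata.

    Round-trips float32/float64 payloads bit-exactly; NaN is the on-disk
    missing marker for float payloads.
    """
    path = Path(path)
    meta = asdict(raster.spec)
    meta["nodata"] = None if np.isnan(raster.spec.nodata) else raster.spec.nodata
    values = raster.values
    if values.dtype not in (np.float32, np.float64):
        values = values.astype(np.float64)
    tifffile.imwrite(path, values, description=json.dumps({"grid_spec": meta}))
    return path


def read_raster(path) -> Raster:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise ConfigurationError(f"{path}: no grid metadata")
        meta = json.loads(desc.value)["grid_spec"]
    if meta.get("nodata") is None:
        meta["nodata"] = float("nan")
    spec = GridSpec(**meta)
    return Raster(values, spec)


@dataclass
class PredictorStack:
    """Aligned multi-layer predictor grid.

    ``kinds`` maps layer name -> 'continuous' | 'categorical'.  Categorical
    layers hold integer codes stored as floats (NaN = missing).
    """

    layers: dict[str, np.ndarray]
    kinds: dict[str, str]
    spec: GridSpec

    def __post_init__(self):
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.spec.shape:
                raise AlignmentError(f"layer {name!r}: shape mismatch")
            self.layers[name] = arr
        unknown = set(self.kinds.values()) - {"continuous", "categorical"}
        if unknown:
            raise ConfigurationError(f"unknown layer kinds: {sorted(unknown)}")
        if set(self.kinds) != set(self.layers):
            raise ConfigurationError("kinds must name exactly the stack's layers")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def any_missing(self) -> np.ndarray:
        """Boolean grid, True where any layer is missing."""
        out = np.zeros(self.spec.shape, dtype=bool)
        for arr in self.layers.values():
            out |= np.isnan(arr)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per cell (row-major), columns = layers."""
        return pd.DataFrame(
            {name: arr.ravel() for name, arr in self.layers.items()}
        )

    @classmethod
    def from_rasters(cls, rasters: dict[str, Raster], kinds: dict[str, str]):
        specs = [r.spec for r in rasters.values()]
        first = specs[0]
        for s in specs[1:]:
            if not first.matches(s):
                raise AlignmentError("predictor rasters are not on one grid")
        return cls({n: r.values for n, r in rasters.items()}, kinds, first)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_raster(Raster(arr, self.spec), directory / f"{name}.tif")
        (directory / "kinds.json").write_text(json.dumps(self.kinds, indent=2))

    @classmethod
    def read(cls, directory):
        directory = Path(directory)
        kinds_path = directory / "kinds.json"
        if not kinds_path.exists():
            raise ConfigurationError(f"{directory}: missing kinds.json")
        kinds = json.loads(kinds_path.read_text())
        rasters = {name: read_raster(directory / f"{name}.tif") for name in kinds}
        return cls.from_rasters(rasters, kinds)


@dataclass
class SampleTable:
    """Georeferenced bioavailable Sr measurements plus a rejection report."""

    frame: pd.DataFrame
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )

    def __len__(self):
        return len(self.frame)


def read_samples(path, schema: dict | None = None) -> SampleTable:
    """Read a sample CSV into a :class:`SampleTable`.

    ``schema`` maps canonical field names (keys of :data:`SAMPLE_SCHEMA`)
    to the file's column names.  Rows with unparseable coordinates or
    ratios, or coordinates outside valid lon/lat ranges, are moved to the
    rejection report rather than silently dropped.
    """
    schema = {**SAMPLE_SCHEMA, **(schema or {})}
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"sample file not found: {path}")
    raw = pd.read_csv(path, dtype=str)
    mandatory = ["sample_id", "longitude", "latitude", "sr_ratio"]
    missing = [schema[k] for k in mandatory if schema[k] not in raw.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory columns: {missing}")
    if raw.empty:
        raise ValueError(f"{path}: empty sample table")

    frame = pd.DataFrame({"sample_id": raw[schema["sample_id"]]})
    for key in ("longitude", "latitude", "sr_ratio"):
        frame[key] = pd.to_numeric(raw[schema[key]], errors="coerce")
    for key in ("sample_type", "source", "reference"):
        col = schema[key]
        frame[key] = raw[col] if col in raw.columns else ""

    reasons = pd.Series("", index=frame.index)
    for key in ("longitude", "latitude", "sr_ratio"):
        reasons[frame[key].isna()] += f"unparseable {key};"
    reasons[(frame["longitude"] < -180) | (frame["longitude"] > 180)] += "longitude out of range;"
    reasons[(frame["latitude"] < -90) | (frame["latitude"] > 90)] += "latitude out of range;"
    bad = reasons != ""
    rejected = pd.DataFrame({"row": frame.index[bad], "reason": reasons[bad]})

    kept = frame[~bad].reset_index(drop=True)
    implausible = (kept["sr_ratio"] <= SR_PLAUSIBLE[0]) | (kept["sr_ratio"] >= SR_PLAUSIBLE[1])
    if implausible.any():
        warnings.warn(
            f"{int(implausible.sum())} sample(s) with 87Sr/86Sr outside "
            f"{SR_PLAUSIBLE}; kept but check units/typos",
            stacklevel=2,
        )
    return SampleTable(kept, rejected.reset_index(drop=True))


def dataset_summary(samples: SampleTable) -> dict:
    """Descriptive statistics of the Sr ratios: n, min, max, mean, sd, Q1, Q3."""
    sr = samples.frame["sr_ratio"].to_numpy(dtype=float)
    return {
        "n": int(sr.size),
        "min": float(np.min(sr)),
        "max": float(np.max(sr)),
        "mean": float(np.mean(sr)),
        "sd": float(np.std(sr, ddof=1)),
        "q1": float(np.quantile(sr, 0.25)),
        "q3": float(np.quantile(sr, 0.75)),
    }


@dataclass
class DesignMatrix:
    """Per-sample predictor values, missing entries infilled.

    ``infill_log`` records (sample_row, layer, method) for every originally
    missing entry; after construction the frame holds no NaN.
    """

    frame: pd.DataFrame
    kinds: dict[str, str]
    infill_log: list[tuple[int, str, str]] = field(default_factory=list)

    def predictors(self) -> pd.DataFrame:
        """Predictor columns only (drops the helper cell-index columns)."""
        return self.frame[list(self.kinds)]

    @property
    def continuous_columns(self) -> list[str]:
        return [c for c, k in self.kinds.items() if k == "continuous"]

    @property
    def categorical_columns(self) -> list[str]:
        return [c for c, k in self.kinds.items() if k == "categorical"]


def _nearest_valid_cells(spec, layer, row, col, k, max_search_radius=None):
    """Indices of the k nearest non-missing cells to (row, col), by centre
    distance; ties broken by row-major flat index."""
    valid_rows, valid_cols = np.nonzero(~np.isnan(layer))
    if valid_rows.size == 0:
        return None
    d = spec.cell_center_distances(row, col, valid_rows, valid_cols)
    if max_search_radius is not None:
        within = d <= max_search_radius
        valid_rows, valid_cols, d = valid_rows[within], valid_cols[within], d[within]
        if valid_rows.size < k:
            return None
    flat = valid_rows * spec.n_cols + valid_cols
    order = np.lexsort((flat, d))[:k]
    return valid_rows[order], valid_cols[order]


def extract_predictors(
    samples: SampleTable,
    stack: PredictorStack,
    n_neighbors: int = 5,
    max_search_radius: float | None = None,
) -> DesignMatrix:
    """Extract predictor values at sample points, infilling missing cells.

    Infill rules: categorical layers take the value of the nearest
    non-missing cell; continuous layers take the arithmetic mean of the
    ``n_neighbors`` nearest non-missing cells.  Distances are between cell
    centres (great-circle for geographic CRSs), ties broken by row-major
    cell index.
    """
    spec = stack.spec
    lon = samples.frame["longitude"].to_numpy(dtype=float)
    lat = samples.frame["latitude"].to_numpy(dtype=float)
    rows, cols = spec.index_of(lon, lat)
    outside = rows < 0
    if outside.any():
        ids = samples.frame["sample_id"][outside].tolist()
        raise ValueError(f"samples outside grid extent: {ids}")

    data = {}
    infill_log: list[tuple[int, str, str]] = []
    failures: list[tuple[int, str]] = []
    for name, layer in stack.layers.items():
        kind = stack.kinds[name]
        vals = layer[rows, cols].astype(float)
        for i in np.nonzero(np.isnan(vals))[0]:
            if kind == "categorical":
                found = _nearest_valid_cells(
                    spec, layer, rows[i], cols[i], 1, max_search_radius
                )
                if found is None:
                    failures.append((int(i), name))
                    continue
                vals[i] = layer[found[0][0], found[1][0]]
                infill_log.append((int(i), name, "nearest_cell"))
            else:
                found = _nearest_valid_cells(
                    spec, layer, rows[i], cols[i], n_neighbors, max_search_radius
                )
                if found is None:
                    failures.append((int(i), name))
                    continue
                vals[i] = float(np.mean(layer[found[0], found[1]]))
                infill_log.append((int(i), name, f"mean_{n_neighbors}_nearest"))
        data[name] = vals

    if failures:
        raise InfillError(
            f"infill failed for (sample_row, layer): {failures}; "
            "no valid donor cells within the search radius"
        )
    frame = pd.DataFrame(data, index=samples.frame.index)
    frame["_row"] = rows
    frame["_col"] = cols
    return DesignMatrix(frame, dict(stack.kinds), infill_log)
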