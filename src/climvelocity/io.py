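"""Readers and writers for the formats the pipeline touches.

Rasters are ESRI ASCII grids (plain text, one file per band) on a
regular geographic grid; tables are CSV; the ordination model is JSON;
run configuration and the manifest are TOML.  Grid congruence (same
shape, corner and cell size) is an explicit contract: nothing is ever
silently resampled, and nodata cells propagate as NaN, never as zeros.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate_space import ClimateGrid
from .synthetic import KM_PER_DEG

__all__ = [
    "RasterHeader",
    "RunConfig",
    "write_ascii_grid",
    "read_ascii_grid",
    "field_to_raster",
    "raster_to_field",
    "write_climate_grid",
    "read_climate_grid",
    "write_toml",
    "read_toml",
]

NODATA = -9999.0


@dataclass(frozen=True)
class RasterHeader:
    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = NODATA

    def congruent(self, other: "RasterHeader") -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and abs(self.xllcorner - other.xllcorner) < 1e-9
            and abs(self.yllcorner - other.yllcorner) < 1e-9
            and abs(self.cellsize - other.cellsize) < 1e-12
        )


def field_to_raster(
    values: np.ndarray, x_index: np.ndarray, y_index: np.ndarray, nx: int, ny: int
) -> np.ndarray:
    """Scatter per-cell values into a (nrows, ncols) array, row 0 = north."""
    out = np.full((ny, nx), np.nan)
    out[np.asarray(y_index), np.asarray(x_index)] = values
    return out


def raster_to_field(
    arr: np.ndarray, x_index: np.ndarray, y_index: np.ndarray
) -> np.ndarray:
    return arr[np.asarray(y_index), np.asarray(x_index)]


def write_ascii_grid(
    path, arr: np.ndarray, header: RasterHeader, integer: bool = False
) -> None:
    """Write a 2-D array (row 0 = northernmost) as an ESRI ASCII grid."""
    arr = np.asarray(arr, dtype=float)
    if arr.shape != (header.nrows, header.ncols):
        raise ValueError(f"array shape {arr.shape} does not match header")
    body = np.where(np.isnan(arr), header.nodata, arr)
    fmt = "%d" if integer else "%.10g"
    with open(path, "w") as fh:
        fh.write(
            f"ncols {header.ncols}\nnrows {header.nrows}\n"
            f"xllcorner {header.xllcorner!r}\nyllcorner {header.yllcorner!r}\n"
            f"cellsize {header.cellsize!r}\nNODATA_value {header.nodata!r}\n"
        )
        np.savetxt(fh, body, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, RasterHeader]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    keys = {}
    with open(path) as fh:
        for _ in range(6):
            name, val = fh.readline().split()
            keys[name.lower()] = float(val)
        body = np.loadtxt(fh, ndmin=2)
    header = RasterHeader(
        ncols=int(keys["ncols"]),
        nrows=int(keys["nrows"]),
        xllcorner=keys["xllcorner"],
        yllcorner=keys["yllcorner"],
        cellsize=keys["cellsize"],
        nodata=keys.get("nodata_value", NODATA),
    )
    if body.shape != (header.nrows, header.ncols):
        raise ValueError(f"{path}: body shape {body.shape} does not match header")
    body = np.where(body == header.nodata, np.nan, body)
    return body, header


def grid_header(grid: ClimateGrid | object) -> RasterHeader:
    """Header for an object carrying nx/ny or x_index/y_index plus lon/lat."""
    x = np.asarray(grid.x_index)
    y = np.asarray(grid.y_index)
    nx = int(x.max()) + 1
    ny = int(y.max()) + 1
    cs = grid.cell_size_km / KM_PER_DEG
    lon = np.asarray(grid.lon, dtype=float)
    lat = np.asarray(grid.lat, dtype=float)
    # cell centers -> lower-left corner of the raster
    xll = float(lon.min() - cs / 2.0)
    yll = float(lat.min() - cs / 2.0)
    return RasterHeader(ncols=nx, nrows=ny, xllcorner=xll, yllcorner=yll, cellsize=cs)


def write_climate_grid(grid: ClimateGrid, out_dir) -> list[Path]:
    """One ASCII raster per bioclimatic variable, named <period>_<gcm>_<var>.asc."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if grid.x_index is None:
        raise ValueError("grid lacks raster indices; cannot rasterize")
    header = grid_header(grid)
    paths = []
    for j, var in enumerate(grid.var_names):
        arr = field_to_raster(
            grid.values[:, j], grid.x_index, grid.y_index, header.ncols, header.nrows
        )
        p = out_dir / f"{grid.period}_{grid.gcm_id}_{var}.asc"
        write_ascii_grid(p, arr, header)
        paths.append(p)
    return paths


def read_climate_grid(
    paths: list, var_names: list[str], period: str, gcm_id: str, cell_size_km: float
) -> ClimateGrid:
    """Assemble a ClimateGrid from congruent single-variable rasters.

    All rasters must share shape, corner and cell size; the first
    incongruent file is named in the error.  Cells that are nodata in any
    band are excluded from the grid.
    """
    if len(paths) != len(var_names):
        raise ValueError("one raster path per variable is required")
    arrays, header0 = [], None
    for p in paths:
        arr, header = read_ascii_grid(p)
        if header0 is None:
            header0 = header
        elif not header.congruent(header0):
            raise ValueError(f"raster {p} is not congruent with {paths[0]}")
        arrays.append(arr)
    stack = np.stack(arrays)  # (vars, rows, cols)
    valid = ~np.any(np.isnan(stack), axis=0)
    yi, xi = np.nonzero(valid)
    cs = header0.cellsize
    lon = header0.xllcorner + (xi + 0.5) * cs
    lat = header0.yllcorner + (header0.nrows - 1 - yi + 0.5) * cs
    values = stack[:, yi, xi].T
    return ClimateGrid(
        cell_id=(yi * header0.ncols + xi).astype(np.int64),
        lon=lon,
        lat=lat,
        values=values,
        var_names=list(var_names),
        period=period,
        gcm_id=gcm_id,
        cell_size_km=cell_size_km,
        x_index=xi,
        y_index=yi,
    )


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def write_toml(data: dict, path) -> None:
    """Minimal TOML writer for flat tables of scalars and lists."""
    lines = []
    scalars = {k: v for k, v in data.items() if not isinstance(v, dict)}
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    for k, v in scalars.items():
        lines.append(f"{k} = {_toml_value(v)}")
    for name, table in tables.items():
        lines.append(f"\n[{name}]")
        for k, v in table.items():
            lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_toml(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run, with validated defaults."""

    nx: int = 40
    ny: int = 40
    n_mountains: int = 2
    max_elev: float = 2500.0
    cell_size_km: float = 50.0
    n_pseudo_gcms: int = 3
    warming_mean: list[float] = field(default_factory=lambda: [2.0, 3.0, 4.0])
    spatial_noise_sd: float = 0.2
    precip_change_frac: list[float] = field(default_factory=lambda: [-0.05, 0.0, 0.05])
    years_between: float = 110.0
    n_vars: int = 8
    lapse_rate: float = -6.5
    var_noise_sd: float = 0.1
    n_species: int = 20
    halfwidth_range: tuple[float, float] = (0.3, 1.2)
    n_pa: int = 8
    pa_radius_range: tuple[int, int] = (1, 3)
    n_zones: int = 4
    bin_width: float = 2.0
    n_offsets: int = 20
    min_variance_fraction: float = 0.02
    min_area_km2: float = 200.0
    distance_mode: str = "sphere"
    fit_basis: str = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "nx", "ny", "cell_size_km", "n_pseudo_gcms", "years_between",
            "n_vars", "n_species", "bin_width", "n_offsets",
            "min_variance_fraction", "min_area_km2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.distance_mode not in ("sphere", "planar"):
            raise ValueError("distance_mode must be 'sphere' or 'planar'")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        raw = read_toml(path)
        flat = {}
        for k, v in raw.items():
            if isinstance(v, dict):
                flat.update(v)
            else:
                flat[k] = v
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for tup in ("halfwidth_range", "pa_radius_range"):
            if tup in flat:
                flat[tup] = tuple(flat[tup])
        return cls(**flat)

    def to_manifest(self) -> dict:
        d = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            d[k] = list(v) if isinstance(v, tuple) else v
        return d
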