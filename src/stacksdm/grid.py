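"""Raster data model, ESRI ASCII grid I/O, spherical geometry and occurrence conditioning.

Every stage of the pipeline exchanges data as :class:`Layer` objects on a shared
:class:`GridSpec` — a regular lon/lat grid with corner registration at the lower-left
cell edge.  Internally row 0 is the *southernmost* row (latitude increases with row
index); the ASCII grid format stores rows north-to-south, so I/O flips row order.

Areas use the authalic Earth radius (sphere of equal surface area); the equatorial
arc helper uses the WGS84 equatorial radius, which is the convention used when a
grid resolution is quoted as "km at the equator".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Authalic Earth radius, km (sphere with the same surface area as WGS84).
EARTH_RADIUS_AUTHALIC_KM = 6371.0088
#: WGS84 equatorial radius, km.
EARTH_RADIUS_EQUATORIAL_KM = 6378.137


class AsciiGridError(ValueError):
    """Raised for malformed ESRI ASCII grid files."""


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid, corner-registered at the lower-left cell edge.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; row 0 is the southernmost row.
    lon_min, lat_min
        Coordinates of the outer corner of cell (0, 0), degrees.
    cell_size
        Cell edge length in degrees, identical in longitude and latitude.
    """

    n_rows: int
    n_cols: int
    lon_min: float
    lat_min: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid shape must be positive")
        if self.lat_min + self.n_rows * self.cell_size > 90 + 1e-9:
            raise ValueError("grid extends beyond the north pole")
        if self.n_cols * self.cell_size > 360 + 1e-9:
            raise ValueError("longitudinal extent exceeds 360 degrees")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.cell_size

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.cell_size

    def row_lats(self, edge: str = "center") -> np.ndarray:
        """Latitudes of every row ('bottom', 'center' or 'top' edge), degrees."""
        base = self.lat_min + np.arange(self.n_rows) * self.cell_size
        if edge == "bottom":
            return base
        if edge == "top":
            return base + self.cell_size
        if edge == "center":
            return base + 0.5 * self.cell_size
        raise ValueError(f"unknown edge {edge!r}")

    def col_lons(self) -> np.ndarray:
        """Cell-center longitudes, degrees."""
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center, degrees."""
        return (
            self.lon_min + (col + 0.5) * self.cell_size,
            self.lat_min + (row + 0.5) * self.cell_size,
        )

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon < self.lon_max)
            & (lat >= self.lat_min)
            & (lat < self.lat_max)
        )

    def point_to_cell(self, lon: float, lat: float) -> tuple[int, int]:
        """Half-open cell assignment: [edge, edge + cell_size) on both axes."""
        col = int(np.floor((lon - self.lon_min) / self.cell_size))
        row = int(np.floor((lat - self.lat_min) / self.cell_size))
        return row, col


@dataclass
class Layer:
    """One gridded predictor: values plus a nodata mask (True = no data, e.g. land)."""

    grid: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.nodata_mask.shape != self.grid.shape:
            raise ValueError("nodata_mask shape does not match grid")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-finite values outside the nodata mask")

    def copy(self) -> "Layer":
        return Layer(self.grid, self.values.copy(), self.nodata_mask.copy())


@dataclass
class EnvStack:
    """Named predictor layers sharing one grid, tagged with a climate scenario."""

    layers: dict[str, Layer]
    scenario: str
    sea_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.scenario not in ("present", "2050", "2100"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if len({l.grid for l in self.layers.values()}) > 1:
            raise ValueError("layers are not grid-compatible")
        self.sea_mask = np.asarray(self.sea_mask, dtype=bool)
        for name, layer in self.layers.items():
            if layer.nodata_mask.shape != self.sea_mask.shape:
                raise ValueError(f"layer {name!r} shape mismatch with sea mask")
            if np.any(layer.nodata_mask & self.sea_mask):
                raise ValueError(f"layer {name!r} has nodata on sea cells")

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.layers.values())).grid

    @property
    def names(self) -> list[str]:
        return sorted(self.layers)

    def sea_cells(self) -> np.ndarray:
        """(n, 2) array of (row, col) for all sea cells, row-major order."""
        rows, cols = np.nonzero(self.sea_mask)
        return np.column_stack([rows, cols])

    def values_at(self, cells: np.ndarray, predictors: Sequence[str]) -> np.ndarray:
        """Predictor matrix (n_cells, n_predictors) at the given (row, col) cells."""
        cells = np.asarray(cells, dtype=int)
        out = np.empty((len(cells), len(predictors)), dtype=float)
        for j, name in enumerate(predictors):
            if name not in self.layers:
                raise KeyError(f"predictor {name!r} not in stack")
            out[:, j] = self.layers[name].values[cells[:, 0], cells[:, 1]]
        return out


@dataclass
class OccurrenceSet:
    """Conditioned presence records for one species.

    ``points`` are the raw (lon, lat) records; ``cells`` the unique sea cells
    after thinning to one record per grid cell and snapping land points to the
    nearest sea cell.
    """

    species_id: str
    points: np.ndarray  # (n, 2) lon, lat
    cells: np.ndarray  # (m, 2) row, col
    range_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.cells = np.asarray(self.cells, dtype=int).reshape(-1, 2)
        if self.range_tags and len(self.range_tags) != len(self.points):
            raise ValueError("range_tags length must match points")
        for tag in self.range_tags:
            if tag not in ("native", "invaded", "unknown"):
                raise ValueError(f"unknown range tag {tag!r}")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path: str | Path) -> Layer:
    """Read an ESRI ASCII grid (.asc) into a :class:`Layer`.

    The six-line header (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value)
    is required; data rows run north to south and are flipped into the internal
    south-up orientation.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    idx = 0
    for idx in range(6):
        if idx >= len(lines):
            raise AsciiGridError(f"{path}: truncated header at line {idx + 1}")
        parts = lines[idx].split()
        if len(parts) != 2:
            raise AsciiGridError(f"{path}: malformed header line {idx + 1}: {lines[idx]!r}")
        key = parts[0].lower()
        if key not in _HEADER_KEYS:
            raise AsciiGridError(f"{path}: unexpected header key on line {idx + 1}: {parts[0]!r}")
        try:
            header[key] = float(parts[1])
        except ValueError as exc:
            raise AsciiGridError(f"{path}: bad header value on line {idx + 1}: {parts[1]!r}") from exc
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise AsciiGridError(f"{path}: missing header keys {missing}")

    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = header["nodata_value"]
    data_lines = [ln for ln in lines[6:] if ln.strip()]
    if len(data_lines) != n_rows:
        raise AsciiGridError(
            f"{path}: expected {n_rows} data rows, found {len(data_lines)}"
        )
    rows = []
    for i, ln in enumerate(data_lines):
        vals = ln.split()
        if len(vals) != n_cols:
            raise AsciiGridError(
                f"{path}: data line {7 + i} has {len(vals)} values, expected {n_cols}"
            )
        try:
            rows.append(np.array(vals, dtype=float))
        except ValueError as exc:
            raise AsciiGridError(f"{path}: non-numeric value on data line {7 + i}") from exc
    north_up = np.vstack(rows)
    values = north_up[::-1].copy()  # store south-up
    mask = values == nodata
    values[mask] = np.nan
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        lon_min=header["xllcorner"],
        lat_min=header["yllcorner"],
        cell_size=header["cellsize"],
    )
    return Layer(grid, values, mask)


def write_ascii_grid(layer: Layer, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a :class:`Layer` as an ESRI ASCII grid; finite cells round-trip exactly."""
    path = Path(path)
    g = layer.grid
    out = np.where(layer.nodata_mask, nodata, layer.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.lon_min!r}\n")
        fh.write(f"yllcorner {g.lat_min!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out[::-1]:  # north to south
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Spherical geometry
# ---------------------------------------------------------------------------


def cell_area_km2(grid: GridSpec, row: int | np.ndarray) -> np.ndarray | float:
    """Area of one grid cell in the given latitude row, km².

    Spherical-zone formula A = R² · Δλ · (sin φ_top − sin φ_bot) with the
    authalic radius R; strictly decreasing with |latitude|.
    """
    row_arr = np.asarray(row)
    if np.any(row_arr < 0) or np.any(row_arr >= grid.n_rows):
        raise ValueError("row outside grid")
    lat_bot = np.deg2rad(grid.lat_min + row_arr * grid.cell_size)
    lat_top = np.deg2rad(grid.lat_min + (row_arr + 1) * grid.cell_size)
    dlam = np.deg2rad(grid.cell_size)
    area = EARTH_RADIUS_AUTHALIC_KM**2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))
    if np.isscalar(row):
        return float(area)
    return area


def area_layer_km2(grid: GridSpec) -> np.ndarray:
    """(n_rows, n_cols) matrix of per-cell areas, km²."""
    per_row = cell_area_km2(grid, np.arange(grid.n_rows))
    return np.repeat(np.asarray(per_row)[:, None], grid.n_cols, axis=1)


def equatorial_arc_km(arcmin: float) -> float:
    """Great-circle length of an arc at the equator, km (WGS84 equatorial radius)."""
    if arcmin <= 0:
        raise ValueError("arcmin must be positive")
    return EARTH_RADIUS_EQUATORIAL_KM * (arcmin / 60.0) * np.pi / 180.0


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance between points, km (authalic radius)."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_AUTHALIC_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


# ---------------------------------------------------------------------------
# Occurrence conditioning
# ---------------------------------------------------------------------------


def thin_to_cells(points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """One record per grid cell: map points to cells (half-open convention) and dedupe.

    Points outside the grid extent are rejected with a warning, not an error.
    Returns (m, 2) unique (row, col) pairs in first-occurrence order.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        return np.empty((0, 2), dtype=int)
    inside = grid.contains(points[:, 0], points[:, 1])
    n_out = int(np.sum(~inside))
    if n_out:
        warnings.warn(f"{n_out} point(s) outside grid extent rejected", stacklevel=2)
    pts = points[inside]
    if len(pts) == 0:
        return np.empty((0, 2), dtype=int)
    cols = np.floor((pts[:, 0] - grid.lon_min) / grid.cell_size).astype(int)
    rows = np.floor((pts[:, 1] - grid.lat_min) / grid.cell_size).astype(int)
    cells = np.column_stack([rows, cols])
    _, first = np.unique(cells, axis=0, return_index=True)
    return cells[np.sort(first)]


def snap_to_sea(cell: tuple[int, int], grid: GridSpec, sea_mask: np.ndarray) -> tuple[int, int]:
    """Nearest sea cell by great-circle distance between cell centers.

    A sea cell maps to itself.  Distance ties are broken by smallest row-major
    index (distances are rounded to the millimetre before comparison so that
    geometric ties are exact).
    """
    sea_mask = np.asarray(sea_mask, dtype=bool)
    if not sea_mask.any():
        raise ValueError("sea mask has no sea cells")
    r, c = cell
    if sea_mask[r, c]:
        return (int(r), int(c))
    rows, cols = np.nonzero(sea_mask)  # row-major order
    lon0, lat0 = grid.cell_center(r, c)
    lons = grid.lon_min + (cols + 0.5) * grid.cell_size
    lats = grid.lat_min + (rows + 0.5) * grid.cell_size
    d = great_circle_km(lon0, lat0, lons, lats)
    d = np.round(d, 6)  # mm precision: make symmetric ties exact
    k = int(np.argmin(d))  # first minimum = smallest row-major index
    return (int(rows[k]), int(cols[k]))


def condition_occurrences(
    species_id: str,
    points: np.ndarray,
    grid: GridSpec,
    sea_mask: np.ndarray,
    range_tags: Iterable[str] | None = None,
) -> OccurrenceSet:
    """Full conditioning: assign points to cells, snap land cells to sea, thin to unique cells."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    cells = thin_to_cells(points, grid)
    snapped = [snap_to_sea((int(r), int(c)), grid, sea_mask) for r, c in cells]
    if snapped:
        arr = np.asarray(snapped, dtype=int)
        _, first = np.unique(arr, axis=0, return_index=True)
        cells_out = arr[np.sort(first)]
    else:
        cells_out = np.empty((0, 2), dtype=int)
    return OccurrenceSet(
        species_id=species_id,
        points=points,
        cells=cells_out,
        range_tags=list(range_tags) if range_tags is not None else [],
    )
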