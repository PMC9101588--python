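"""Gridded covariate handling: grid geometry, layer stacks, raster text I/O.

Conventions are the common north-up geo-raster ones: WGS84 lon/lat, 0-based
(row, col) indices with row 0 the northernmost row, and half-open cells
``[edge, edge + cell_size)`` so a point exactly on an interior edge belongs to
the cell to the east / south of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely

__all__ = [
    "GridSpec",
    "Layer",
    "CovariateStack",
    "point_to_cell",
    "cell_center",
    "extract_covariates",
    "read_ascii_grid",
    "write_ascii_grid",
    "region_mask_from_geojson",
    "read_geojson_geometry",
]

#: Grids are combinable when their geometry agrees to this many degrees.
GRID_TOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up regular lon/lat grid.

    ``x_origin`` is the west edge and ``y_origin`` the NORTH edge of the grid,
    in degrees; ``cell_size`` is the square cell width in degrees (30 arc
    seconds = 1/120 degree in the intended use).
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    crs_id: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) in degrees."""
        return (
            self.x_origin,
            self.y_origin - self.n_rows * self.cell_size,
            self.x_origin + self.n_cols * self.cell_size,
            self.y_origin,
        )

    def matches(self, other: "GridSpec", tol: float = GRID_TOL) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (lon, lat) of cell-center coordinates, shape (n_rows, n_cols)."""
        lon = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)


def point_to_cell(lon: float, lat: float, grid: GridSpec) -> tuple[int, int]:
    """Map a lon/lat point to its 0-based (row, col) grid cell.

    Half-open convention: ``col = floor((lon - x_origin)/cell_size)``,
    ``row = floor((y_origin - lat)/cell_size)``.  Raises ``ValueError`` for a
    point outside the grid bounding box.
    """
    west, south, east, north = grid.bounds
    if not (west <= lon < east) or not (south < lat <= north):
        raise ValueError(
            f"point (lon={lon!r}, lat={lat!r}) lies outside grid bounds "
            f"W={west} S={south} E={east} N={north}"
        )
    col = int(np.floor((lon - grid.x_origin) / grid.cell_size))
    row = int(np.floor((grid.y_origin - lat) / grid.cell_size))
    # guard the exact-north-edge / exact-west-edge cases against fp drift
    col = min(max(col, 0), grid.n_cols - 1)
    row = min(max(row, 0), grid.n_rows - 1)
    return row, col


def cell_center(row: int, col: int, grid: GridSpec) -> tuple[float, float]:
    """(lon, lat) of the center of cell (row, col)."""
    lon = grid.x_origin + (col + 0.5) * grid.cell_size
    lat = grid.y_origin - (row + 0.5) * grid.cell_size
    return lon, lat


@dataclass
class Layer:
    """One covariate layer: a (n_rows, n_cols) float array with NaN nodata."""

    name: str
    values: np.ndarray
    kind: str = "continuous"  # "continuous" | "categorical"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("layer values must be a 2-D array")
        if self.kind == "categorical":
            finite = np.isfinite(self.values)
            if not np.allclose(self.values[finite], np.round(self.values[finite])):
                raise ValueError(f"categorical layer {self.name!r} holds non-integer codes")


class CovariateStack:
    """Aligned multi-layer covariate grid with a shared validity mask.

    A cell is valid when it lies inside the (optional) study-region mask and
    no layer is nodata there.  All statistics in the package exclude masked
    cells.
    """

    def __init__(
        self,
        grid: GridSpec,
        layers: Sequence[Layer],
        region_mask: np.ndarray | None = None,
    ) -> None:
        self.grid = grid
        self.layers: list[Layer] = []
        seen: set[str] = set()
        for layer in layers:
            if layer.values.shape != grid.shape:
                raise ValueError(
                    f"layer {layer.name!r} shape {layer.values.shape} does not "
                    f"match grid shape {grid.shape}"
                )
            if layer.name in seen:
                raise ValueError(f"duplicate layer name {layer.name!r}")
            seen.add(layer.name)
            self.layers.append(layer)
        if region_mask is None:
            region_mask = np.ones(grid.shape, dtype=bool)
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != grid.shape:
            raise ValueError("region mask shape does not match grid")
        self.region_mask = region_mask

    @property
    def layer_names(self) -> list[str]:
        return [layer.name for layer in self.layers]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        mask = self.region_mask.copy()
        for layer in self.layers:
            mask &= np.isfinite(layer.values)
        return mask

    def get_layer(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(f"no layer named {name!r}; have {self.layer_names}")

    def subset(self, names: Iterable[str]) -> "CovariateStack":
        """New stack restricted to ``names``, preserving the given order."""
        return CovariateStack(
            self.grid, [self.get_layer(n) for n in names], self.region_mask
        )

    def valid_cells(self) -> np.ndarray:
        """(n_valid, 2) array of (row, col) indices of valid cells."""
        rows, cols = np.nonzero(self.valid_mask)
        return np.column_stack([rows, cols])


def extract_covariates(
    points: Sequence[tuple[int, int]] | np.ndarray, stack: CovariateStack
) -> np.ndarray:
    """Covariate matrix (n_points, n_layers) at the given (row, col) cells.

    Layer order is preserved; categorical layers are returned as integer
    codes.  Raises ``ValueError`` listing any point on a masked cell.
    """
    pts = np.asarray(points, dtype=int)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (row, col) pairs")
    valid = stack.valid_mask
    bad = [
        (int(r), int(c))
        for r, c in pts
        if not (0 <= r < stack.grid.n_rows and 0 <= c < stack.grid.n_cols) or not valid[r, c]
    ]
    if bad:
        raise ValueError(f"points on masked or out-of-grid cells: {bad}")
    out = np.empty((len(pts), stack.n_layers), dtype=float)
    for j, layer in enumerate(stack.layers):
        out[:, j] = layer.values[pts[:, 0], pts[:, 1]]
    return out


# ---------------------------------------------------------------------------
# raster text I/O (ESRI ASCII grid) and GeoJSON geometry
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read a single-band ESRI ASCII grid; nodata becomes NaN.

    Both ``yllcorner`` and ``yllcenter``/``xllcenter`` header variants are
    accepted; ``cellsize`` must be square.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            ) and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {req!r}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x_origin = header["xllcorner"]
    elif "xllcenter" in header:
        x_origin = header["xllcenter"] - cell / 2
    else:
        raise ValueError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        y_origin = header["yllcorner"] + n_rows * cell
    elif "yllcenter" in header:
        y_origin = header["yllcenter"] - cell / 2 + n_rows * cell
    else:
        raise ValueError(f"{path}: missing yllcorner/yllcenter")
    values = np.loadtxt(data_lines, dtype=float).reshape(n_rows, n_cols)
    if "nodata_value" in header:
        values = np.where(values == header["nodata_value"], np.nan, values)
    grid = GridSpec(n_rows=n_rows, n_cols=n_cols, x_origin=x_origin,
                    y_origin=y_origin, cell_size=cell)
    return values, grid


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    grid: GridSpec,
    nodata: float = -9999.0,
    fmt: str = "%.10g",
) -> None:
    """Write a single-band ESRI ASCII grid; NaN cells become ``nodata``."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    out = np.where(np.isfinite(values), values, nodata)
    west, south, _, _ = grid.bounds
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {west:.17g}\n")
        fh.write(f"yllcorner {south:.17g}\n")
        fh.write(f"cellsize {grid.cell_size:.17g}\n")
        fh.write(f"NODATA_value {nodata:.17g}\n")
        np.savetxt(fh, out, fmt=fmt)


def read_geojson_geometry(path: str | Path):
    """Union of all geometries in a GeoJSON file, as a shapely geometry."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shapely.geometry.shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shapely.geometry.shape(gj["geometry"])]
    else:
        geoms = [shapely.geometry.shape(gj)]
    if not geoms:
        raise ValueError(f"{path}: no geometries")
    return shapely.union_all(geoms)


def region_mask_from_geojson(path: str | Path, grid: GridSpec) -> np.ndarray:
    """Boolean mask of cells whose centers fall inside the region polygon."""
    polygon = read_geojson_geometry(path)
    lon, lat = grid.cell_centers()
    inside = shapely.contains_xy(polygon, lon.ravel(), lat.ravel())
    return inside.reshape(grid.shape)
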