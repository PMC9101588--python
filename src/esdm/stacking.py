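"""Binarized species maps, stacked richness ("hotspot") maps and stream
buffering.

Each species' continuous ensemble prediction is binarized at its own optimal
threshold (strict ``>``: a cell exactly at threshold is an absence), and the
per-species binary maps are summed cellwise into a richness map giving the
predicted number of species per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from .grids import GridSpec, read_geojson_geometry
from .terrain import meters_per_degree

__all__ = ["BinaryMap", "RichnessMap", "binarize", "stack_richness", "mask_stream_buffer"]


@dataclass
class BinaryMap:
    """Per-cell {0, 1, nodata(NaN)} presence map for one species."""

    grid: GridSpec
    values: np.ndarray
    species: str = ""
    threshold: float = float("nan")

    def count_presences(self) -> int:
        return int(np.nansum(self.values))


@dataclass
class RichnessMap:
    """Per-cell predicted species count (integer, or NaN where no input had data)."""

    grid: GridSpec
    values: np.ndarray
    species_list: list[str] = field(default_factory=list)
    n_contributing: np.ndarray | None = None

    def total(self) -> int:
        return int(np.nansum(self.values))


def binarize(prediction: np.ndarray, threshold: float, grid: GridSpec,
             species: str = "") -> BinaryMap:
    """1 where prediction > threshold, 0 otherwise, NaN preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    prediction = np.asarray(prediction, dtype=float)
    if prediction.shape != grid.shape:
        raise ValueError("prediction shape does not match grid")
    values = np.where(np.isnan(prediction), np.nan, (prediction > threshold).astype(float))
    return BinaryMap(grid=grid, values=values, species=species, threshold=threshold)


def stack_richness(binary_maps: list[BinaryMap]) -> RichnessMap:
    """Cellwise sum of per-species binary maps.

    A cell is nodata only where ALL inputs are nodata; where some inputs are
    nodata the sum runs over the others and ``n_contributing`` records how
    many species' maps had data there.
    """
    if not binary_maps:
        raise ValueError("need at least one binary map to stack")
    grid = binary_maps[0].grid
    for bm in binary_maps[1:]:
        if not grid.matches(bm.grid):
            raise ValueError("binary maps are on different grids")
    stackv = np.stack([bm.values for bm in binary_maps])
    has_data = np.isfinite(stackv)
    n_contributing = has_data.sum(axis=0)
    values = np.where(n_contributing > 0, np.nansum(stackv, axis=0), np.nan)
    return RichnessMap(
        grid=grid,
        values=values,
        species_list=[bm.species for bm in binary_maps],
        n_contributing=n_contributing,
    )


def mask_stream_buffer(map_obj, streams, buffer_km: float = 2.0):
    """Restrict a map to cells whose centers lie within ``buffer_km`` of a stream.

    ``streams`` is a shapely geometry (LineString/MultiLineString/collection)
    or a path to a GeoJSON file.  Distance uses an equirectangular
    approximation anchored at the grid center (adequate at buffers of a few
    km); cells farther than the buffer become nodata.  Returns a new object
    of the same type.
    """
    if buffer_km <= 0:
        raise ValueError("buffer_km must be positive")
    if isinstance(streams, (str, Path)):
        streams = read_geojson_geometry(streams)
    if streams is None or streams.is_empty:
        raise ValueError("empty stream geometry")

    grid = map_obj.grid
    lon0 = grid.x_origin + grid.n_cols * grid.cell_size / 2
    lat0 = grid.y_origin - grid.n_rows * grid.cell_size / 2
    m_lon, m_lat = meters_per_degree(lat0)

    def project(geom):
        return shapely.transform(
            geom,
            lambda coords: np.column_stack([
                (coords[:, 0] - lon0) * m_lon / 1000.0,
                (coords[:, 1] - lat0) * m_lat / 1000.0,
            ]),
        )

    streams_km = project(streams)
    lon, lat = grid.cell_centers()
    px = (lon - lon0) * m_lon / 1000.0
    py = (lat - lat0) * m_lat / 1000.0
    points = shapely.points(px.ravel(), py.ravel())
    dist = shapely.distance(points, streams_km).reshape(grid.shape)
    values = np.where(dist <= buffer_km, map_obj.values, np.nan)

    if isinstance(map_obj, BinaryMap):
        return BinaryMap(grid=grid, values=values, species=map_obj.species,
                         threshold=map_obj.threshold)
    return RichnessMap(
        grid=grid,
        values=values,
        species_list=list(map_obj.species_list),
        n_contributing=None if map_obj.n_contributing is None
        else np.where(dist <= buffer_km, map_obj.n_contributing, 0),
    )
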