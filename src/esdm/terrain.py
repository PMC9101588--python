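"""Percent-slope derivation from a gridded elevation layer.

Slope is computed with Horn's 3x3 third-order finite differences, the de
facto standard of GIS terrain routines.  Horizontal distances are converted
from degrees to meters with the latitude of each cell, so the same elevation
field yields steeper percent slopes where meridians converge.
"""

from __future__ import annotations

import numpy as np

from .grids import GridSpec, Layer

__all__ = ["meters_per_degree", "derive_percent_slope"]


def meters_per_degree(latitude: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(meters per degree longitude, meters per degree latitude) on WGS84.

    Truncated spherical-harmonic series; accurate to well under 1 m/degree,
    far below the needs of a 30 arc-second grid.
    """
    phi = np.deg2rad(np.asarray(latitude, dtype=float))
    m_lat = (
        111132.92
        - 559.82 * np.cos(2 * phi)
        + 1.175 * np.cos(4 * phi)
        - 0.0023 * np.cos(6 * phi)
    )
    m_lon = (
        111412.84 * np.cos(phi)
        - 93.5 * np.cos(3 * phi)
        + 0.118 * np.cos(5 * phi)
    )
    return m_lon, m_lat


def _pad_linear(values: np.ndarray) -> np.ndarray:
    """Pad by one cell on every side with linear extrapolation.

    Linear extrapolation keeps planar ramps exactly planar, so edge cells
    effectively receive one-sided differences.
    """
    padded = np.pad(values, 1, mode="edge")
    padded[0, 1:-1] = 2 * values[0] - values[1]
    padded[-1, 1:-1] = 2 * values[-1] - values[-2]
    padded[:, 0] = 2 * padded[:, 1] - padded[:, 2]
    padded[:, -1] = 2 * padded[:, -2] - padded[:, -3]
    return padded


def derive_percent_slope(elevation: Layer | np.ndarray, grid: GridSpec) -> Layer:
    """Per-cell percent slope, ``100 * sqrt((dz/dx)^2 + (dz/dy)^2)``.

    ``dz/dx`` and ``dz/dy`` use Horn's 3x3 weights over the 8 neighbours;
    nodata neighbours are replaced by the centre value (degrading gracefully
    to one-sided differences) and the output is nodata exactly where the
    elevation itself is nodata.  Raises on an all-nodata elevation layer or a
    grid smaller than 3x3.
    """
    z = elevation.values if isinstance(elevation, Layer) else np.asarray(elevation, float)
    if z.shape != grid.shape:
        raise ValueError("elevation shape does not match grid")
    if grid.n_rows < 3 or grid.n_cols < 3:
        raise ValueError("slope derivation requires a grid of at least 3x3 cells")
    center_nan = ~np.isfinite(z)
    if center_nan.all():
        raise ValueError("elevation layer is entirely nodata")

    padded = _pad_linear(np.where(center_nan, 0.0, z))
    nan_pad = np.pad(center_nan, 1, mode="constant", constant_values=False)

    def window(dr: int, dc: int) -> np.ndarray:
        sl_r = slice(1 + dr, 1 + dr + grid.n_rows)
        sl_c = slice(1 + dc, 1 + dc + grid.n_cols)
        vals = padded[sl_r, sl_c]
        nans = nan_pad[sl_r, sl_c]
        return np.where(nans, z_filled, vals)

    z_filled = np.where(center_nan, 0.0, z)
    a, b, c = window(-1, -1), window(-1, 0), window(-1, 1)
    d, f = window(0, -1), window(0, 1)
    g, h, i = window(1, -1), window(1, 0), window(1, 1)

    _, lat = grid.cell_centers()
    m_lon, m_lat = meters_per_degree(lat)
    dx = grid.cell_size * m_lon
    dy = grid.cell_size * m_lat

    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * dx)
    dz_dy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * dy)
    slope = 100.0 * np.sqrt(dz_dx**2 + dz_dy**2)
    slope[center_nan] = np.nan
    name = elevation.name if isinstance(elevation, Layer) else "elevation"
    return Layer(name=f"{name}_pct_slope", values=slope, kind="continuous")
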