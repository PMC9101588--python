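"""Occurrence tables: loading, validation, cell-level deduplication and the
minimum-sample species filter.

An occurrence table is a pandas DataFrame with columns
``species, longitude, latitude`` and optionally ``source``.  "Location" for
deduplication purposes is the grid cell: the unit at which the models predict.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .grids import GridSpec, point_to_cell

__all__ = [
    "load_occurrences",
    "validate_occurrences",
    "deduplicate_occurrences",
    "filter_species_min_unique",
]

REQUIRED_COLUMNS = ("species", "longitude", "latitude")


def validate_occurrences(table: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, coordinate ranges and non-empty species names."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns {missing}")
    if table["species"].isna().any() or (table["species"].astype(str).str.strip() == "").any():
        raise ValueError("occurrence table contains empty species names")
    lon = table["longitude"].astype(float)
    lat = table["latitude"].astype(float)
    if ((lon < -180) | (lon > 180)).any():
        raise ValueError("longitude outside [-180, 180]")
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude outside [-90, 90]")
    return table


def load_occurrences(path: str | Path) -> pd.DataFrame:
    """Read a ``species,longitude,latitude[,source]`` CSV."""
    table = pd.read_csv(path)
    return validate_occurrences(table)


def deduplicate_occurrences(
    table: pd.DataFrame, grid: GridSpec
) -> dict[str, set[tuple[int, int]]]:
    """Unique occupied grid cells per species.

    Duplicate observations of the same species in the same cell collapse to
    one; species order and record order do not affect the result.
    """
    validate_occurrences(table)
    cells: dict[str, set[tuple[int, int]]] = {}
    for species, lon, lat in zip(
        table["species"], table["longitude"], table["latitude"]
    ):
        cells.setdefault(str(species), set()).add(point_to_cell(float(lon), float(lat), grid))
    return cells


def filter_species_min_unique(
    species_cells: dict[str, set[tuple[int, int]]], min_unique: int = 10
) -> tuple[dict[str, set[tuple[int, int]]], list[tuple[str, int]]]:
    """Drop species with fewer than ``min_unique`` unique cells.

    Species with exactly ``min_unique`` cells are retained.  Returns the
    retained mapping and a list of ``(species, unique_count)`` exclusions.
    """
    if min_unique < 1:
        raise ValueError("min_unique must be >= 1")
    retained: dict[str, set[tuple[int, int]]] = {}
    excluded: list[tuple[str, int]] = []
    for species, cells in species_cells.items():
        if len(cells) >= min_unique:
            retained[species] = cells
        else:
            excluded.append((species, len(cells)))
    return retained, excluded
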