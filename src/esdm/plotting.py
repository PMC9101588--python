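"""Small plotting helpers for prediction/richness rasters and family metrics."""

from __future__ import annotations

import numpy as np

from .grids import GridSpec

__all__ = ["plot_raster", "plot_family_metrics"]


def plot_raster(values: np.ndarray, grid: GridSpec, ax=None, title: str | None = None,
                cmap: str = "viridis", colorbar: bool = True):
    """Image plot of a raster in lon/lat extent; NaN cells are transparent."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    west, south, east, north = grid.bounds
    im = ax.imshow(values, extent=(west, east, south, north), origin="upper", cmap=cmap)
    if colorbar:
        ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    return ax


def plot_family_metrics(results, metric: str = "auc", ax=None):
    """Box plot of per-replicate test metrics by family for one species."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = results.replicate_metrics
    families = sorted(df["family"].unique())
    ax.boxplot([df.loc[df["family"] == f, metric] for f in families],
               tick_labels=families)
    ax.set_ylabel(f"test {metric.upper() if metric in ('auc', 'tss') else metric}")
    ax.set_title(results.species)
    ax.tick_params(axis="x", rotation=45)
    return ax
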