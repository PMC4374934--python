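"""Rendered maps on the study's fixed colour scales.

Both map types use a 12-step linear purple-to-red scale: isodensity
maps saturate at a population-specific maximum (4,800 cells/mm² for
RGCs, 9,200 for GCL nuclei), neighbour maps run from 0 to >= 11
neighbours within the fixed radius.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .topography import IsodensityGrid, NeighbourMap, NEIGHBOUR_TOP_BIN

__all__ = ["plot_isodensity", "plot_neighbour_map"]


def _scale_cmap(n: int):
    return plt.get_cmap("rainbow", n)


def plot_isodensity(grid: IsodensityGrid, ax=None, title: str | None = None):
    """Render an isodensity grid; undefined (out-of-contour) bins are
    left blank."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cmap = _scale_cmap(grid.n_colours)
    shown = np.ma.masked_invalid(grid.densities)
    im = ax.pcolormesh(
        grid.x_edges, grid.y_edges, shown, cmap=cmap, vmin=0.0, vmax=grid.scale_max
    )
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm, +nasal)")
    ax.set_ylabel("y (mm, +superior)")
    if title:
        ax.set_title(title)
    cbar = plt.colorbar(im, ax=ax, shrink=0.8)
    cbar.set_label(f"cells/mm² (red ≥ {grid.scale_max:g})")
    return ax


def plot_neighbour_map(nmap: NeighbourMap, ax=None, title: str | None = None):
    """Scatter each cell coloured by its neighbour count (purple 0 to
    red >= 11)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cmap = _scale_cmap(NEIGHBOUR_TOP_BIN + 1)
    sc = ax.scatter(
        nmap.x, nmap.y, c=nmap.colour_bin, cmap=cmap, vmin=-0.5,
        vmax=NEIGHBOUR_TOP_BIN + 0.5, s=8,
    )
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm, +nasal)")
    ax.set_ylabel("y (mm, +superior)")
    if title:
        ax.set_title(title)
    cbar = plt.colorbar(sc, ax=ax, ticks=range(NEIGHBOUR_TOP_BIN + 1), shrink=0.8)
    cbar.set_label(f"neighbours within {nmap.radius_mm:g} mm (red ≥ {NEIGHBOUR_TOP_BIN})")
    return ax
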