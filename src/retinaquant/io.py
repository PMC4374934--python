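"""Readers and writers for the pipeline's on-disk formats.

All tables are comma-separated UTF-8 with a mandatory header and '.'
decimals; images are single-channel 16-bit TIFF frames named
``frame_{row}_{col}.tif`` with a JSON sidecar describing the grid
geometry (and, for synthetic data, the ground truth).  Schema
violations are fatal by default and name the offending column or line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from .cellmap import CellMap
from .synthetic.imaging import FrameGrid, TileSet

__all__ = [
    "read_cells_csv",
    "write_cells_csv",
    "read_contour_csv",
    "write_contour_csv",
    "read_sections_csv",
    "write_sections_csv",
    "read_iop_csv",
    "write_iop_csv",
    "write_tiles",
    "read_tiles",
]

CELL_COLUMNS = ["animal_id", "eye", "population", "x_mm", "y_mm"]
SECTION_COLUMNS = ["bregma_mm", "area_mm2", "usable"]
IOP_COLUMNS = ["animal_id", "time_h", "iop_mmHg", "eye"]


def _read_csv_checked(path, required: list, numeric: list) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())][:5]
            raise ValueError(f"{path}: non-numeric values in '{col}' at line(s) {lines}")
        df[col] = coerced
    return df


def read_cells_csv(path) -> pd.DataFrame:
    return _read_csv_checked(path, CELL_COLUMNS, ["x_mm", "y_mm"])


def write_cells_csv(cells, path) -> None:
    df = cells.to_frame() if isinstance(cells, CellMap) else cells
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing column(s) {missing}")
    df.to_csv(path, index=False)


def read_contour_csv(path) -> Polygon:
    df = _read_csv_checked(path, ["x_mm", "y_mm"], ["x_mm", "y_mm"])
    if len(df) < 3:
        raise ValueError(f"{path}: a contour needs at least 3 vertices")
    return Polygon(df[["x_mm", "y_mm"]].to_numpy())


def write_contour_csv(contour: Polygon, path) -> None:
    xy = np.asarray(contour.exterior.coords)[:-1]  # drop the closing vertex
    pd.DataFrame({"x_mm": xy[:, 0], "y_mm": xy[:, 1]}).to_csv(path, index=False)


def read_sections_csv(path) -> pd.DataFrame:
    df = _read_csv_checked(path, SECTION_COLUMNS, ["bregma_mm", "area_mm2"])
    df["usable"] = df["usable"].astype(bool)
    return df


def write_sections_csv(df: pd.DataFrame, path) -> None:
    missing = [c for c in SECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"section table missing column(s) {missing}")
    df.to_csv(path, index=False)


def read_iop_csv(path) -> pd.DataFrame:
    return _read_csv_checked(path, IOP_COLUMNS, ["time_h", "iop_mmHg"])


def write_iop_csv(df: pd.DataFrame, path) -> None:
    missing = [c for c in IOP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"IOP table missing column(s) {missing}")
    df.to_csv(path, index=False)


# ----------------------------------------------------------------- TIFF


def write_tiles(tileset: TileSet, directory) -> Path:
    """Write frames as 16-bit TIFFs plus a JSON sidecar with the grid
    geometry and the ground-truth cell table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (i, j), tile in tileset.tiles.items():
        tifffile.imwrite(directory / f"frame_{i}_{j}.tif", tile.astype(np.uint16))
    g = tileset.grid
    sidecar = {
        "rows": g.rows,
        "cols": g.cols,
        "frame_width_mm": g.frame_width_mm,
        "frame_height_mm": g.frame_height_mm,
        "origin_mm": list(g.origin_mm),
        "mm_per_pixel": g.mm_per_pixel,
        "ground_truth": {
            "x_mm": tileset.ground_truth.x.tolist(),
            "y_mm": tileset.ground_truth.y.tolist(),
            "population": tileset.ground_truth.population,
        },
    }
    with open(directory / "grid.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return directory


def read_tiles(directory) -> TileSet:
    directory = Path(directory)
    sidecar_path = directory / "grid.json"
    if not sidecar_path.exists():
        raise ValueError(f"{directory}: missing grid.json sidecar")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    grid = FrameGrid(
        rows=meta["rows"],
        cols=meta["cols"],
        frame_width_mm=meta["frame_width_mm"],
        frame_height_mm=meta["frame_height_mm"],
        origin_mm=tuple(meta["origin_mm"]),
        mm_per_pixel=meta["mm_per_pixel"],
    )
    tiles = {}
    for i in range(grid.rows):
        for j in range(grid.cols):
            path = directory / f"frame_{i}_{j}.tif"
            if not path.exists():
                raise ValueError(f"missing tile file {path.name}")
            tiles[(i, j)] = tifffile.imread(path)
    gt = meta.get("ground_truth", {})
    ground_truth = CellMap(
        x=np.asarray(gt.get("x_mm", []), dtype=float),
        y=np.asarray(gt.get("y_mm", []), dtype=float),
        population=gt.get("population", "OHSt"),
    )
    return TileSet(tiles=tiles, grid=grid, ground_truth=ground_truth)
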