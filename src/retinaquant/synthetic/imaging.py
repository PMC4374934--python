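"""Synthetic fluorescence tiles for a wholemount montage.

Mimics the acquisition scheme in which a motorised stage captures a
grid of frames side-by-side with no gap or overlap; each labelled cell
appears as a Gaussian blob on a noisy background.  The ground-truth
positions are kept as a sidecar so detection can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..cellmap import CellMap
from ..geometry import mm_to_px

__all__ = ["FrameGrid", "TileSet", "render_tiles"]

#: Default frame footprint in mm — a 20x-objective field stand-in.
DEFAULT_FRAME_MM = (0.45, 0.34)  # (width, height)
DEFAULT_MM_PER_PIXEL = 0.001


@dataclass(frozen=True)
class FrameGrid:
    """Rows x cols of abutting frames covering a rectangular region.

    ``origin_mm`` is the (x, y) of the montage's top-left corner; frames
    tile the region exactly (no gap, no overlap).
    """

    rows: int
    cols: int
    frame_width_mm: float = DEFAULT_FRAME_MM[0]
    frame_height_mm: float = DEFAULT_FRAME_MM[1]
    origin_mm: tuple = (0.0, 0.0)
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one frame")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.frame_px[0] < 1 or self.frame_px[1] < 1:
            raise ValueError("frame smaller than one pixel")

    @property
    def frame_px(self):
        """(height_px, width_px) of a single frame."""
        return (
            int(round(self.frame_height_mm / self.mm_per_pixel)),
            int(round(self.frame_width_mm / self.mm_per_pixel)),
        )

    @property
    def montage_px(self):
        h, w = self.frame_px
        return (self.rows * h, self.cols * w)

    @property
    def extent_mm(self):
        """(width, height) of the tiled region in mm."""
        return (self.cols * self.frame_width_mm, self.rows * self.frame_height_mm)

    @classmethod
    def covering(cls, x_range, y_range, **kw) -> "FrameGrid":
        """Smallest grid of default-size frames covering the given mm
        bounding box, anchored at its top-left corner."""
        fw = kw.pop("frame_width_mm", DEFAULT_FRAME_MM[0])
        fh = kw.pop("frame_height_mm", DEFAULT_FRAME_MM[1])
        cols = max(1, int(np.ceil((x_range[1] - x_range[0]) / fw)))
        rows = max(1, int(np.ceil((y_range[1] - y_range[0]) / fh)))
        return cls(rows=rows, cols=cols, frame_width_mm=fw, frame_height_mm=fh,
                   origin_mm=(x_range[0], y_range[1]), **kw)


@dataclass
class TileSet:
    """Rendered frames plus acquisition geometry and ground truth."""

    tiles: dict  # (row, col) -> uint16 array
    grid: FrameGrid
    ground_truth: CellMap

    def frame(self, row: int, col: int) -> np.ndarray:
        return self.tiles[(row, col)]


def render_tiles(
    cells: CellMap,
    grid: FrameGrid,
    psf_sigma_px: float = 1.0,
    amplitude: float = 1000.0,
    background: float = 100.0,
    noise_model: str = "poisson+gaussian",
    read_noise_sd: float = 10.0,
    seed: int = 0,
) -> TileSet:
    """Render each cell as a Gaussian blob on the tiled frames.

    noise_model: "none", "gaussian" (additive read noise only) or
    "poisson+gaussian" (shot noise on the signal plus read noise).
    Cells must fall inside the tiled region.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    if noise_model not in ("none", "gaussian", "poisson+gaussian"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    H, W = grid.montage_px
    canvas = np.full((H, W), float(background))
    rows, cols = mm_to_px(cells.x, cells.y, grid.origin_mm, grid.mm_per_pixel)
    w_mm, h_mm = grid.extent_mm
    x0, y0 = grid.origin_mm
    if len(cells) and (
        cells.x.min() < x0
        or cells.x.max() > x0 + w_mm
        or cells.y.max() > y0
        or cells.y.min() < y0 - h_mm
    ):
        raise ValueError("cells outside the tiled region")
    # stamp each blob over a +/-5 sigma window
    half = max(2, int(np.ceil(5 * psf_sigma_px)))
    offs = np.arange(-half, half + 1)
    for r0, c0 in zip(rows, cols):
        ri = int(round(r0))
        ci = int(round(c0))
        rs = offs + ri
        cs = offs + ci
        rmask = (rs >= 0) & (rs < H)
        cmask = (cs >= 0) & (cs < W)
        rr = rs[rmask]
        cc = cs[cmask]
        gy = np.exp(-0.5 * ((rr - r0) / psf_sigma_px) ** 2)
        gx = np.exp(-0.5 * ((cc - c0) / psf_sigma_px) ** 2)
        canvas[np.ix_(rr, cc)] += amplitude * np.outer(gy, gx)
    rng = np.random.default_rng(seed)
    if noise_model == "poisson+gaussian":
        canvas = rng.poisson(np.clip(canvas, 0, None)).astype(float)
    if noise_model in ("gaussian", "poisson+gaussian") and read_noise_sd > 0:
        canvas += rng.normal(0.0, read_noise_sd, canvas.shape)
    canvas = np.clip(np.round(canvas), 0, 65535).astype(np.uint16)
    fh, fw = grid.frame_px
    tiles = {
        (i, j): canvas[i * fh : (i + 1) * fh, j * fw : (j + 1) * fw].copy()
        for i in range(grid.rows)
        for j in range(grid.cols)
    }
    return TileSet(tiles=tiles, grid=grid, ground_truth=cells)
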