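"""Montage assembly and automated cell detection.

The detector is a conventional fluorescence blob-counting chain:
difference-of-Gaussians band-pass at the expected blob scale, automatic
(Otsu) or fixed thresholding of the enhanced image, connected-component
extraction with an area filter, intensity-weighted sub-pixel centroids,
and a minimum-separation merge that keeps the brighter of two peaks.
It stands in for the proprietary image-analysis macros such pipelines
historically relied on, with every step specified and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .cellmap import CellMap
from .geometry import px_to_mm

__all__ = ["Montage", "DetectionParams", "assemble_montage", "detect_cells", "count_cells"]

log = logging.getLogger(__name__)


@dataclass
class Montage:
    """Assembled single-channel image with its acquisition geometry."""

    pixels: np.ndarray
    mm_per_pixel: float
    grid_shape: tuple  # (rows, cols) of frames
    origin_mm: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")


def assemble_montage(tiles: dict, grid_shape: tuple, mm_per_pixel: float,
                     origin_mm: tuple = (0.0, 0.0)) -> Montage:
    """Losslessly concatenate a complete (rows x cols) grid of frames.

    ``tiles`` maps (row, col) -> 2-D array; all frames must share shape
    and dtype.  Pixel (r, c) of tile (i, j) maps to montage pixel
    (i*H + r, j*W + c); the inverse mapping is exact.
    """
    rows, cols = grid_shape
    missing = [(i, j) for i in range(rows) for j in range(cols) if (i, j) not in tiles]
    if missing:
        raise ValueError(f"missing tiles at grid positions: {missing}")
    shapes = {tiles[k].shape for k in tiles}
    dtypes = {tiles[k].dtype for k in tiles}
    if len(shapes) != 1 or len(dtypes) != 1:
        raise ValueError("all tiles must share shape and dtype")
    (h, w) = shapes.pop()
    out = np.empty((rows * h, cols * w), dtype=dtypes.pop())
    for (i, j), tile in tiles.items():
        out[i * h : (i + 1) * h, j * w : (j + 1) * w] = tile
    return Montage(pixels=out, mm_per_pixel=mm_per_pixel, grid_shape=grid_shape,
                   origin_mm=origin_mm)


def split_montage(montage: Montage) -> dict:
    """Inverse of :func:`assemble_montage` (exact round-trip)."""
    rows, cols = montage.grid_shape
    H, W = montage.pixels.shape
    h, w = H // rows, W // cols
    return {
        (i, j): montage.pixels[i * h : (i + 1) * h, j * w : (j + 1) * w].copy()
        for i in range(rows)
        for j in range(cols)
    }


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the blob-detection chain.

    ``psf_sigma_px`` sets the band-pass scale (DoG with sigmas sigma and
    2*sigma).  ``intensity_threshold`` is "automatic" (Otsu on the
    enhanced image) or a fixed float applied to the enhanced image.
    """

    psf_sigma_px: float = 1.0
    intensity_threshold: object = "automatic"
    min_area_px: int = 3
    max_area_px: int = 500
    min_separation_px: float = 0.5

    def __post_init__(self):
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.min_area_px > self.max_area_px:
            raise ValueError("min_area_px must not exceed max_area_px")
        if isinstance(self.intensity_threshold, (int, float)) and self.intensity_threshold < 0:
            raise ValueError("threshold must be non-negative")


def detect_cells(montage: Montage, params: DetectionParams = DetectionParams()) -> CellMap:
    """Detect labelled cells on a calibrated montage.

    Returns sub-pixel centroids in mm coordinates with per-detection
    integrated intensity and pixel area.  Blank or saturated montages
    yield an empty result with a logged warning (not an exception).
    """
    img = montage.pixels.astype(float)
    if img.size == 0 or np.ptp(img) == 0:
        log.warning("montage is blank or saturated; returning no detections")
        return _empty_result(montage)
    s = params.psf_sigma_px
    # band-pass: narrow sigma below the blob scale preserves two-point
    # resolution of close pairs; the wide sigma subtracts background
    enhanced = ndimage.gaussian_filter(img, 0.5 * s) - ndimage.gaussian_filter(img, 2 * s)
    if np.ptp(enhanced) == 0:
        log.warning("enhanced montage is flat; returning no detections")
        return _empty_result(montage)
    if params.intensity_threshold == "automatic":
        thr = float(threshold_otsu(enhanced))
    else:
        thr = float(params.intensity_threshold)
    mask = enhanced > thr
    if not mask.any():
        log.warning("no pixels above threshold")
        return _empty_result(montage, threshold=thr)
    # candidate peaks: strict 3x3 local maxima of the enhanced image
    # above the threshold
    peaks = peak_local_max(
        enhanced, min_distance=1, threshold_abs=thr, exclude_border=False
    )
    if peaks.shape[0] == 0:
        log.warning("no local maxima above threshold")
        return _empty_result(montage, threshold=thr)
    # area filter on the thresholded component supporting each peak
    labels = cc_label(mask, connectivity=2)
    comp_areas = np.bincount(labels.ravel())
    peak_area = comp_areas[labels[peaks[:, 0], peaks[:, 1]]]
    keep = (peak_area >= params.min_area_px) & (peak_area <= params.max_area_px)
    peaks, peak_area = peaks[keep], peak_area[keep]
    if peaks.shape[0] == 0:
        return _empty_result(montage, threshold=thr)
    # sub-pixel centroid: intensity-weighted mean of (enhanced - thr)+
    # over a +/-1 sigma window around each peak (a tight window keeps
    # the centroids of close pairs from biasing toward each other)
    H, W = enhanced.shape
    weights = np.clip(enhanced - thr, 0.0, None)
    half = max(1, int(np.ceil(s)))
    com = np.empty((peaks.shape[0], 2))
    totals = np.empty(peaks.shape[0])
    for k, (pr, pc) in enumerate(peaks):
        r0, r1 = max(0, pr - half), min(H, pr + half + 1)
        c0, c1 = max(0, pc - half), min(W, pc + half + 1)
        win = weights[r0:r1, c0:c1]
        tot = win.sum()
        if tot <= 0:  # degenerate plateau: fall back to the peak pixel
            com[k] = (pr, pc)
            totals[k] = float(enhanced[pr, pc])
            continue
        rr = np.arange(r0, r1)
        cc = np.arange(c0, c1)
        com[k, 0] = (win.sum(axis=1) * rr).sum() / tot
        com[k, 1] = (win.sum(axis=0) * cc).sum() / tot
        totals[k] = tot
    # merge centroids closer than min_separation: the larger integrated
    # intensity wins; ties resolve by lexicographic pixel order
    order = np.lexsort((com[:, 1], com[:, 0], -totals))
    tree = cKDTree(com)
    suppressed = np.zeros(com.shape[0], dtype=bool)
    kept: list = []
    for k in order:
        if suppressed[k]:
            continue
        kept.append(k)
        for m in tree.query_ball_point(com[k], params.min_separation_px):
            if m != k:
                suppressed[m] = True
    kept = sorted(kept, key=lambda k: (com[k, 0], com[k, 1]))
    com, totals, areas = com[kept], totals[kept], peak_area[kept]
    x_mm, y_mm = px_to_mm(com[:, 0], com[:, 1], montage.origin_mm, montage.mm_per_pixel)
    extras = pd.DataFrame({"intensity": totals, "area_px": areas.astype(int)})
    return CellMap(x=x_mm, y=y_mm, population="detected", contour=None,
                   animal_id="detected", eye="NA", extras=extras)


def _empty_result(montage: Montage, threshold: float | None = None) -> CellMap:
    return CellMap(
        x=np.empty(0), y=np.empty(0), population="detected", contour=None,
        animal_id="detected", eye="NA",
        extras=pd.DataFrame({"intensity": [], "area_px": []}),
    )


def count_cells(cellmap: CellMap, contour: Polygon) -> int:
    """Number of detections inside a simple closed contour.

    Points exactly on the boundary count as inside.  Self-intersecting
    contours are rejected.
    """
    if not isinstance(contour, Polygon):
        contour = Polygon(contour)
    if not contour.is_valid or contour.area == 0:
        raise ValueError("contour must be a simple (non-self-intersecting) closed polygon")
    if len(cellmap) == 0:
        return 0
    prepared = prep(contour)
    return int(sum(prepared.covers(Point(px, py)) for px, py in zip(cellmap.x, cellmap.y)))
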