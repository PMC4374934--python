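"""Retinal wholemount geometry and angle conventions.

Coordinates are retina-centred millimetres with the optic disc at the
origin.  For a left-eye wholemount viewed from the vitreal side the axes
are +y superior (dorsal) and +x nasal; the temporal pole therefore lies
on the -x axis.

Angles on the wholemount use the *retina convention*: 0° at the temporal
pole, increasing counter-clockwise as viewed from the vitreal side, so
90° is superior, 180° nasal and 270° inferior.  :func:`retina_to_math_deg`
maps this convention onto ordinary mathematical angles (measured from +x,
counter-clockwise in the (x, y) frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "RetinaGeometry",
    "retina_to_math_deg",
    "math_to_retina_deg",
    "cell_angles_deg",
]


def retina_to_math_deg(angle_deg):
    """Convert retina-convention angles (0° temporal, CCW) to math angles."""
    return (180.0 - np.asarray(angle_deg, dtype=float)) % 360.0


def math_to_retina_deg(angle_deg):
    """Inverse of :func:`retina_to_math_deg` (the map is an involution)."""
    return (180.0 - np.asarray(angle_deg, dtype=float)) % 360.0


def cell_angles_deg(x_mm, y_mm):
    """Retina-convention angle of each point about the optic disc."""
    math_deg = np.degrees(np.arctan2(np.asarray(y_mm, float), np.asarray(x_mm, float)))
    return math_to_retina_deg(math_deg)


@dataclass(frozen=True)
class RetinaGeometry:
    """Disc model of a flattened wholemount.

    Parameters
    ----------
    radius_mm : float
        Retinal radius; the wholemount is modelled as a disc centred on
        the optic disc.  Default 2.2 mm (typical adult C57BL/6 retina).
    cut_angles_deg : tuple of float
        Azimuths (retina convention) of the four radial relieving cuts
        used to flatten and orient the wholemount.  The first entry is
        the deepest cut, which marks the superior pole.
    contour_vertices : int
        Number of vertices used to polygonise the circular contour.
    """

    radius_mm: float = 2.2
    cut_angles_deg: tuple = (90.0, 0.0, 180.0, 270.0)
    contour_vertices: int = 256

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        angles = np.mod(np.asarray(self.cut_angles_deg, float), 360.0)
        if len(np.unique(np.round(angles, 9))) != len(angles):
            raise ValueError("cut_angles_deg must be distinct modulo 360°")

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.radius_mm**2)

    def contour(self) -> Polygon:
        """Closed polygonal contour of the wholemount (a regular n-gon
        inscribed in the retinal circle)."""
        t = np.linspace(0.0, 2.0 * np.pi, self.contour_vertices, endpoint=False)
        pts = np.column_stack([self.radius_mm * np.cos(t), self.radius_mm * np.sin(t)])
        return Polygon(pts)

    def contains(self, x_mm, y_mm) -> np.ndarray:
        """Vectorised membership test against the exact circle."""
        x = np.asarray(x_mm, float)
        y = np.asarray(y_mm, float)
        return x * x + y * y <= self.radius_mm**2


# Centralised mm <-> pixel conversions (images use 0-based pixel indices,
# origin at the top-left; +y in mm maps to decreasing row index).


def mm_to_px(x_mm, y_mm, origin_mm, mm_per_pixel):
    """Map retina-frame mm coordinates to (row, col) pixel coordinates.

    ``origin_mm`` is the (x, y) mm position of pixel (0, 0)'s centre-of
    the image's top-left corner.
    """
    x = np.asarray(x_mm, float)
    y = np.asarray(y_mm, float)
    col = (x - origin_mm[0]) / mm_per_pixel
    row = (origin_mm[1] - y) / mm_per_pixel
    return row, col


def px_to_mm(row, col, origin_mm, mm_per_pixel):
    """Inverse of :func:`mm_to_px`."""
    r = np.asarray(row, float)
    c = np.asarray(col, float)
    x = origin_mm[0] + c * mm_per_pixel
    y = origin_mm[1] - r * mm_per_pixel
    return x, y
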