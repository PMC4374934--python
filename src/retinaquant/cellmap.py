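"""Labelled 2-D point patterns of cells on a wholemount."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = ["CellMap", "POPULATIONS"]

#: Recognised population labels: retrogradely traced RGCs (OHSt), the
#: general RGC population (Brn3a), melanopsin-expressing RGCs, and the
#: non-RGC nucleus pool of the ganglion cell layer.
POPULATIONS = ("OHSt", "Brn3a", "melanopsin", "DAPI_nonRGC")


@dataclass
class CellMap:
    """A point pattern of detected or ground-truth cells.

    Coordinates are retina-centred mm (optic disc at the origin, +y
    superior, +x nasal for a left eye).  ``extras`` carries optional
    per-cell columns (e.g. detection intensity and area) aligned with
    ``x``/``y``.
    """

    x: np.ndarray
    y: np.ndarray
    population: str = "OHSt"
    contour: Polygon | None = None
    animal_id: str = "synthetic"
    eye: str = "RE"
    extras: pd.DataFrame | None = None

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if self.extras is not None and len(self.extras) != len(self.x):
            raise ValueError("extras must align with coordinates")

    def __len__(self) -> int:
        return self.x.size

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) mm coordinates."""
        return np.column_stack([self.x, self.y])

    def subset(self, mask: np.ndarray) -> "CellMap":
        extras = self.extras.loc[mask].reset_index(drop=True) if self.extras is not None else None
        return replace(self, x=self.x[mask], y=self.y[mask], extras=extras)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "eye": self.eye,
                "population": self.population,
                "x_mm": self.x,
                "y_mm": self.y,
            }
        )
        if self.extras is not None:
            df = pd.concat([df, self.extras.reset_index(drop=True)], axis=1)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, contour: Polygon | None = None) -> "CellMap":
        required = {"animal_id", "eye", "population", "x_mm", "y_mm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing cell-table columns: {sorted(missing)}")
        extras_cols = [c for c in df.columns if c not in required]
        extras = df[extras_cols].reset_index(drop=True) if extras_cols else None
        first = df.iloc[0] if len(df) else None
        return cls(
            x=df["x_mm"].to_numpy(dtype=float),
            y=df["y_mm"].to_numpy(dtype=float),
            population=str(first["population"]) if first is not None else "OHSt",
            contour=contour,
            animal_id=str(first["animal_id"]) if first is not None else "synthetic",
            eye=str(first["eye"]) if first is not None else "RE",
            extras=extras,
        )
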