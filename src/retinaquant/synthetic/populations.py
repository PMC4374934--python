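"""Ground-truth wholemount point patterns and lesions.

Cell populations are simulated as inhomogeneous Poisson point processes
on the wholemount disc.  The density profiles encode what is known of
the real topography: the general RGC population (traced or Brn3a+) is
densest around the optic disc and thins towards the periphery, while
melanopsin RGCs are additionally enriched in the dorso-temporal retina.
Ocular-hypertension damage is modelled as pie-shaped sectorial loss
(wedges with apex at the optic disc) superimposed on diffuse loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..cellmap import CellMap, POPULATIONS
from ..geometry import RetinaGeometry, cell_angles_deg, retina_to_math_deg

__all__ = [
    "PopulationSpec",
    "LesionSpec",
    "generate_population",
    "apply_lesion",
    "default_spec",
]

#: Control-group mean totals used as generator targets: retrogradely
#: traced RGCs ~38,500, Brn3a+ RGCs ~37,900, melanopsin RGCs ~1,059 and
#: the DAPI+ non-RGC nucleus pool of the GCL ~45,500 per retina.
DEFAULT_TARGETS = {
    "OHSt": 38_479,
    "Brn3a": 37_904,
    "melanopsin": 1_059,
    "DAPI_nonRGC": 45_471,
}


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of one simulated cell population.

    ``density_profile`` identifies the (unnormalised) intensity shape:

    - ``"radial_linear"``: linearly decreasing with eccentricity,
      ``centre_edge_ratio``:1 from optic disc to periphery (default 2:1).
    - ``"uniform"``: constant over the disc.
    - ``"dorsotemporal"``: radial_linear modulated by a cosine bump
      centred on the dorso-temporal quadrant (45° retina convention)
      with ``peak_trough_ratio``:1 contrast — the melanopsin topography.
    """

    label: str = "OHSt"
    target_total: float = 38_479
    density_profile: str = "radial_linear"
    centre_edge_ratio: float = 2.0
    peak_trough_ratio: float = 2.0
    bump_centre_deg: float = 45.0
    seed: int = 0

    def __post_init__(self):
        if self.label not in POPULATIONS:
            raise ValueError(f"unknown population label {self.label!r}")
        if self.target_total < 0:
            raise ValueError("target_total must be non-negative")
        if self.density_profile not in ("radial_linear", "uniform", "dorsotemporal"):
            raise ValueError(f"unknown density profile {self.density_profile!r}")
        if self.centre_edge_ratio < 1 or self.peak_trough_ratio < 1:
            raise ValueError("contrast ratios must be >= 1 (density must stay positive)")


def default_spec(label: str, seed: int = 0) -> PopulationSpec:
    """Population spec with the study's control-group target and the
    field-typical topography for ``label``."""
    profile = "dorsotemporal" if label == "melanopsin" else "radial_linear"
    return PopulationSpec(
        label=label,
        target_total=DEFAULT_TARGETS[label],
        density_profile=profile,
        seed=seed,
    )


def _relative_intensity(spec: PopulationSpec, geom: RetinaGeometry, x, y):
    """Unnormalised intensity in [0, 1]; maximum value is exactly 1."""
    r = np.hypot(x, y) / geom.radius_mm
    if spec.density_profile == "uniform":
        return np.ones_like(r)
    k = spec.centre_edge_ratio
    radial = 1.0 - (1.0 - 1.0 / k) * r  # 1 at centre, 1/k at the edge
    if spec.density_profile == "radial_linear":
        return radial
    # dorsotemporal: multiply by (1 + b cos(theta - theta0)) / (1 + b)
    b = (spec.peak_trough_ratio - 1.0) / (spec.peak_trough_ratio + 1.0)
    theta = np.radians(retina_to_math_deg(spec.bump_centre_deg))
    ang = np.arctan2(y, x)
    angular = (1.0 + b * np.cos(ang - theta)) / (1.0 + b)
    return radial * angular


def generate_population(
    geom: RetinaGeometry, spec: PopulationSpec, rng: np.random.Generator | None = None
) -> CellMap:
    """Draw an inhomogeneous Poisson pattern with expected total
    ``spec.target_total`` inside the wholemount disc.

    The realised count is Poisson(target_total); positions are sampled
    from the normalised density profile by rejection against the disc's
    uniform measure.  Deterministic for a fixed ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(rng.poisson(spec.target_total))
    if n == 0:
        return CellMap(
            x=np.empty(0), y=np.empty(0), population=spec.label,
            contour=geom.contour(), eye="RE",
        )
    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    R = geom.radius_mm
    # Rejection sampling: proposals uniform on the disc, acceptance
    # proportional to the relative intensity (sup = 1 by construction).
    while filled < n:
        m = max(2 * (n - filled), 1024)
        u = rng.random((m, 3))
        rr = R * np.sqrt(u[:, 0])
        tt = 2.0 * np.pi * u[:, 1]
        px = rr * np.cos(tt)
        py = rr * np.sin(tt)
        keep = u[:, 2] <= _relative_intensity(spec, geom, px, py)
        px, py = px[keep], py[keep]
        take = min(n - filled, px.size)
        xs[filled : filled + take] = px[:take]
        ys[filled : filled + take] = py[:take]
        filled += take
    return CellMap(
        x=xs, y=ys, population=spec.label, contour=geom.contour(), eye="RE",
    )


@dataclass(frozen=True)
class LesionSpec:
    """Sectorial plus diffuse cell loss.

    ``wedges`` is a list of ``(start_deg, span_deg, loss_fraction)``
    pie-shaped sectors with apex at the optic disc, angles in the retina
    convention (0° temporal, CCW).  Overlapping wedges combine as
    ``1 - prod(1 - f_i)``.  Every cell surviving the wedges is then
    removed independently with probability ``diffuse_fraction``; with
    ``diffuse_gradient="eccentric"`` the diffuse probability scales
    linearly with eccentricity (mean preserved), otherwise it is
    spatially uniform.
    """

    wedges: tuple = ()
    diffuse_fraction: float = 0.0
    diffuse_gradient: str = "uniform"

    def __post_init__(self):
        for start, span, frac in self.wedges:
            if not (0.0 < span <= 360.0):
                raise ValueError("wedge span must be in (0°, 360°]")
            if not (0.0 <= frac <= 1.0):
                raise ValueError("loss fractions must lie in [0, 1]")
        if not (0.0 <= self.diffuse_fraction <= 1.0):
            raise ValueError("diffuse_fraction must lie in [0, 1]")
        if self.diffuse_gradient not in ("uniform", "eccentric"):
            raise ValueError("diffuse_gradient must be 'uniform' or 'eccentric'")


def _wedge_membership(angles_deg: np.ndarray, start: float, span: float) -> np.ndarray:
    rel = np.mod(angles_deg - start, 360.0)
    if span >= 360.0:
        return np.ones_like(rel, dtype=bool)
    return rel < span


def apply_lesion(cells: CellMap, lesion: LesionSpec, seed: int = 0,
                 radius_mm: float | None = None) -> CellMap:
    """Thin a cell pattern according to a lesion specification.

    Survivors keep their exact coordinates (the operation is a subset);
    reproducible for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = len(cells)
    if n == 0:
        return cells.subset(np.zeros(0, dtype=bool))
    p_loss = np.zeros(n)
    if lesion.wedges:
        angles = cell_angles_deg(cells.x, cells.y)
        survive = np.ones(n)
        for start, span, frac in lesion.wedges:
            inside = _wedge_membership(angles, start, span)
            survive[inside] *= 1.0 - frac
        p_loss = 1.0 - survive
    keep = rng.random(n) >= p_loss
    if lesion.diffuse_fraction > 0:
        if lesion.diffuse_gradient == "eccentric":
            if radius_mm is None:
                radius_mm = float(np.hypot(cells.x, cells.y).max()) or 1.0
            ecc = np.hypot(cells.x, cells.y) / radius_mm
            # linear in eccentricity, mean-preserving over the disc
            # (E[ecc] = 2/3 for uniform-on-disc points)
            p_diff = np.clip(lesion.diffuse_fraction * ecc / (2.0 / 3.0), 0.0, 1.0)
        else:
            p_diff = np.full(n, lesion.diffuse_fraction)
        keep &= rng.random(n) >= p_diff
    return cells.subset(keep)
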