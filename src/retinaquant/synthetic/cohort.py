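"""Whole-cohort simulation: paired treated/control retinas plus IOP.

Each simulated animal carries a control right eye (RE) and a laser-
treated left eye (LE); the treated eye's cell populations are thinned
by a shared lesion so that cross-population correlations arise the way
they do in the real data (one eye, one insult).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..geometry import RetinaGeometry
from .populations import LesionSpec, PopulationSpec, apply_lesion, default_spec, generate_population
from .iop import generate_iop_series

__all__ = ["CohortDesign", "simulate_cohort"]


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic treated-vs-control cohort.

    ``lesion`` applies to every treated eye; per-animal severity is
    scaled by a lognormal factor with coefficient of variation
    ``severity_cv`` (the model shows large inter-animal variability).
    ``iop_peaks_mmHg``, if given, fixes each animal's designed IOP peak;
    otherwise peaks are drawn Normal(mean 32, sd 3).
    """

    n_animals: int = 7
    timepoint: str = "2wk"
    populations: tuple = ("OHSt",)
    lesion: LesionSpec = LesionSpec(wedges=((0.0, 90.0, 1.0),), diffuse_fraction=1.0 / 3.0)
    severity_cv: float = 0.0
    iop_peaks_mmHg: tuple | None = None
    iop_peak_time_h: float = 24.0


def _scaled_lesion(lesion: LesionSpec, scale: float) -> LesionSpec:
    wedges = tuple((s, sp, min(1.0, f * scale)) for s, sp, f in lesion.wedges)
    return LesionSpec(
        wedges=wedges,
        diffuse_fraction=min(1.0, lesion.diffuse_fraction * scale),
        diffuse_gradient=lesion.diffuse_gradient,
    )


def simulate_cohort(design: CohortDesign, seed: int = 0, geom: RetinaGeometry | None = None):
    """Simulate a cohort; returns (counts table, iop table).

    The counts table has one row per (animal, eye, population) with the
    realised total cell count; the IOP table holds each treated eye's
    tonometry series.
    """
    if geom is None:
        geom = RetinaGeometry()
    ss = np.random.SeedSequence([seed, 2_001])
    child = ss.spawn(design.n_animals)
    rows = []
    iop_frames = []
    if design.iop_peaks_mmHg is not None and len(design.iop_peaks_mmHg) != design.n_animals:
        raise ValueError("iop_peaks_mmHg must have one entry per animal")
    for i in range(design.n_animals):
        rng = np.random.default_rng(child[i])
        animal = f"M{i + 1:03d}"
        scale = 1.0
        if design.severity_cv > 0:
            sigma = np.sqrt(np.log1p(design.severity_cv**2))
            scale = rng.lognormal(-0.5 * sigma**2, sigma)
        lesion = _scaled_lesion(design.lesion, scale)
        for pop in design.populations:
            spec = default_spec(pop)
            for eye in ("RE", "LE"):
                cells = generate_population(geom, spec, rng=rng)
                if eye == "LE":
                    cells = apply_lesion(
                        cells, lesion, seed=int(rng.integers(2**31)), radius_mm=geom.radius_mm
                    )
                rows.append(
                    {
                        "animal_id": animal,
                        "eye": eye,
                        "timepoint": design.timepoint,
                        "population": pop,
                        "value": len(cells),
                    }
                )
        if design.iop_peaks_mmHg is not None:
            peak = float(design.iop_peaks_mmHg[i])
        else:
            peak = float(rng.normal(32.0, 3.0))
        series = generate_iop_series(
            peak_mmHg=max(peak, 0.0),
            peak_time_h=design.iop_peak_time_h,
            seed=int(rng.integers(2**31)),
        )
        series.insert(0, "animal_id", animal)
        iop_frames.append(series)
    counts = pd.DataFrame(rows)
    iop = pd.concat(iop_frames, ignore_index=True)
    return counts, iop
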