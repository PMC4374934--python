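"""Top-level pipeline: generate → (detect) → topography → volumetry → stats.

Each stage writes its artifacts into the output directory and records
them in a manifest (inputs, parameters, seed, SHA-256 content hash);
identical config + seed yields byte-identical artifacts and therefore
identical manifest hashes.  A stage failure halts the run after writing
a machine-readable error record.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .cellmap import CellMap
from .config import PipelineConfig, stage_seed
from .detection import DetectionParams, assemble_montage, detect_cells
from .geometry import RetinaGeometry
from .stats import filter_by_iop, group_summary, mann_whitney, percent_loss, survival_fraction
from .synthetic import (
    CohortDesign,
    FrameGrid,
    LesionSpec,
    SCProfileSpec,
    apply_lesion,
    default_spec,
    generate_population,
    generate_sc_profile,
    render_tiles,
    simulate_cohort,
)
from .topography import isodensity, wedge_loss_profile
from .volumetry import fit_area_profile, percent_innervation

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the configured stages in order; returns the report dict.

    Artifacts, the manifest and the report are written under
    ``config.out_dir`` (or ``out_dir`` if given).
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    report: dict = {}
    state: dict = {}
    stages = [
        ("generate", _stage_generate),
        ("detect", _stage_detect),
        ("topography", _stage_topography),
        ("volumetry", _stage_volumetry),
        ("stats", _stage_stats),
    ]
    for name, fn in stages:
        cfg = getattr(config, name)
        if not cfg.enabled:
            continue
        seed = stage_seed(config, name)
        try:
            artifacts, section = fn(config, seed, out, state)
        except Exception as exc:  # halt with a machine-readable record
            record = {
                "stage": name,
                "error": type(exc).__name__,
                "message": str(exc),
                "traceback": traceback.format_exc(),
            }
            (out / "error.json").write_text(json.dumps(record, indent=1))
            raise
        manifest["stages"][name] = {
            "seed": seed,
            "parameters": cfg.model_dump(mode="json"),
            "artifacts": {str(p.name): _sha256(p) for p in artifacts},
        }
        report[name] = section
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _stage_generate(config: PipelineConfig, seed: int, out: Path, state: dict):
    g = config.generate
    design = CohortDesign(
        n_animals=g.n_animals,
        timepoint=g.timepoint,
        populations=tuple(g.populations),
        lesion=LesionSpec(
            wedges=tuple(tuple(w) for w in g.wedges),
            diffuse_fraction=g.diffuse_fraction,
        ),
        severity_cv=g.severity_cv,
    )
    geom = RetinaGeometry(radius_mm=g.radius_mm)
    counts, iop = simulate_cohort(design, seed=seed, geom=geom)
    counts_path = out / "cohort_counts.csv"
    iop_path = out / "cohort_iop.csv"
    counts.to_csv(counts_path, index=False)
    rio.write_iop_csv(iop, iop_path)
    # one example retina pair kept in memory for the topography stage
    spec = default_spec(g.populations[0], seed=seed)
    control = generate_population(geom, spec)
    treated = apply_lesion(control, design.lesion, seed=seed + 1, radius_mm=geom.radius_mm)
    state.update(counts=counts, iop=iop, geom=geom, design=design,
                 example_control=control, example_treated=treated)
    return [counts_path, iop_path], {
        "n_animals": g.n_animals,
        "populations": list(g.populations),
        "total_rows": int(len(counts)),
    }


def _stage_detect(config: PipelineConfig, seed: int, out: Path, state: dict):
    """Small-field detection QC: render a 2x2-frame patch of the example
    control retina and score detection against the ground truth."""
    d = config.detect
    geom: RetinaGeometry = state["geom"]
    grid = FrameGrid(rows=2, cols=2, origin_mm=(-0.45, 0.34))
    control: CellMap = state["example_control"]
    w_mm, h_mm = grid.extent_mm
    inside = (
        (control.x >= grid.origin_mm[0])
        & (control.x <= grid.origin_mm[0] + w_mm)
        & (control.y <= grid.origin_mm[1])
        & (control.y >= grid.origin_mm[1] - h_mm)
    )
    patch = control.subset(inside)
    tiles = render_tiles(patch, grid, psf_sigma_px=d.psf_sigma_px, seed=seed)
    tile_dir = rio.write_tiles(tiles, out / "tiles")
    montage = assemble_montage(tiles.tiles, (grid.rows, grid.cols),
                               grid.mm_per_pixel, grid.origin_mm)
    params = DetectionParams(
        psf_sigma_px=d.psf_sigma_px,
        intensity_threshold=d.intensity_threshold,
        min_area_px=d.min_area_px,
        max_area_px=d.max_area_px,
        min_separation_px=d.min_separation_px,
    )
    detected = detect_cells(montage, params)
    det_path = out / "detections.csv"
    rio.write_cells_csv(detected, det_path)
    qc = {
        "n_ground_truth": len(patch),
        "n_detected": len(detected),
        "params": params.__dict__ | {"intensity_threshold": str(params.intensity_threshold)},
    }
    qc_path = out / "detection_qc.json"
    qc_path.write_text(json.dumps(qc, indent=1))
    artifacts = [det_path, qc_path] + sorted(tile_dir.glob("frame_*.tif")) + [tile_dir / "grid.json"]
    return artifacts, {"n_ground_truth": len(patch), "n_detected": len(detected)}


def _stage_topography(config: PipelineConfig, seed: int, out: Path, state: dict):
    t = config.topography
    control: CellMap = state["example_control"]
    treated: CellMap = state["example_treated"]
    grid = isodensity(treated, bin_size_mm=t.bin_size_mm, scale_max=t.scale_max)
    dens_path = out / "isodensity_treated.csv"
    pd.DataFrame(grid.densities).to_csv(dens_path, index=False)
    profile = wedge_loss_profile(treated, control, n_wedges=t.n_wedges,
                                 threshold=t.loss_threshold)
    prof_path = out / "wedge_profile.csv"
    pd.DataFrame(
        {
            "start_deg": profile.edges_deg[:-1],
            "count_treated": profile.counts_exp,
            "count_control": profile.counts_ctrl,
            "loss": profile.loss,
        }
    ).to_csv(prof_path, index=False)
    sector = profile.sector
    section = {
        "isodensity_total": grid.total_count,
        "sector": None
        if sector is None
        else {"start_deg": sector[0], "span_deg": sector[1], "loss": sector[2]},
    }
    return [dens_path, prof_path], section


def _stage_volumetry(config: PipelineConfig, seed: int, out: Path, state: dict):
    v = config.volumetry
    b0, b1, frac = v.patch
    control_spec = SCProfileSpec(noise_cv=v.noise_cv, seed=seed)
    treated_spec = SCProfileSpec(noise_cv=v.noise_cv, seed=seed + 1,
                                 patches=((b0, b1, frac),))
    control = generate_sc_profile(control_spec)
    treated = generate_sc_profile(treated_spec)
    c_path = out / "sc_sections_control.csv"
    t_path = out / "sc_sections_treated.csv"
    rio.write_sections_csv(control, c_path)
    rio.write_sections_csv(treated, t_path)
    fit_c = fit_area_profile(control, degree=v.degree)
    fit_t = fit_area_profile(treated, degree=v.degree)
    innervated, deafferented = percent_innervation(fit_t, fit_c)
    fit_path = out / "sc_volumetry.json"
    fit_path.write_text(
        json.dumps(
            {
                "control": {"r2": fit_c.r_squared, "volume_mm3": fit_c.volume_mm3,
                            "coefficients_raw": fit_c.coef_raw.tolist()},
                "treated": {"r2": fit_t.r_squared, "volume_mm3": fit_t.volume_mm3,
                            "coefficients_raw": fit_t.coef_raw.tolist()},
                "percent_innervated": innervated,
                "percent_deafferented": deafferented,
            },
            indent=1,
        )
    )
    return [c_path, t_path, fit_path], {
        "control_volume_mm3": fit_c.volume_mm3,
        "treated_volume_mm3": fit_t.volume_mm3,
        "percent_innervated": innervated,
        "percent_deafferented": deafferented,
    }


def _stage_stats(config: PipelineConfig, seed: int, out: Path, state: dict):
    s = config.stats
    counts: pd.DataFrame = state["counts"]
    iop: pd.DataFrame = state["iop"]
    included, exclusions = filter_by_iop(counts, iop, s.iop_threshold_mmHg, s.iop_window_h)
    summary = group_summary(included, ["population", "eye"])
    section: dict = {"n_excluded": len(exclusions), "populations": {}}
    for pop in included["population"].unique():
        sub = summary[summary["population"] == pop].set_index("eye")
        ctrl_mean = float(sub.loc["RE", "mean"])
        trt_mean = float(sub.loc["LE", "mean"])
        loss_raw, loss_int = percent_loss(ctrl_mean, trt_mean)
        surv_raw, surv_int = survival_fraction(ctrl_mean, trt_mean)
        a = included.query("population == @pop and eye == 'RE'")["value"].to_numpy()
        b = included.query("population == @pop and eye == 'LE'")["value"].to_numpy()
        test = mann_whitney(a, b, alternative=s.alternative)
        section["populations"][pop] = {
            "control_mean": ctrl_mean,
            "treated_mean": trt_mean,
            "percent_loss": loss_raw,
            "percent_loss_rounded": loss_int,
            "percent_survival": surv_raw,
            "percent_survival_rounded": surv_int,
            "mann_whitney_U": test.statistic,
            "p_value": test.p_value,
        }
    stats_path = out / "group_stats.json"
    stats_path.write_text(json.dumps(section, indent=1, sort_keys=True))
    excl_path = out / "exclusions.json"
    excl_path.write_text(json.dumps(exclusions, indent=1))
    return [stats_path, excl_path], section
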