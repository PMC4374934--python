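"""Pipeline configuration: nested, validated, file-round-trippable.

Unknown keys are rejected (a typo in a parameter name is an error, not
a silent default) and a config survives a YAML round-trip losslessly.
A single global seed fans out deterministically to per-stage child
seeds via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "load_config", "save_config", "stage_seed"]

#: Stable stage ordering used for seed fan-out.
STAGES = ("generate", "detect", "topography", "volumetry", "stats")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenerateConfig(_Strict):
    enabled: bool = True
    n_animals: int = 7
    timepoint: str = "2wk"
    populations: list[str] = Field(default_factory=lambda: ["OHSt"])
    wedges: list[list[float]] = Field(default_factory=lambda: [[0.0, 90.0, 1.0]])
    diffuse_fraction: float = 1.0 / 3.0
    severity_cv: float = 0.0
    radius_mm: float = 2.2


class DetectConfig(_Strict):
    enabled: bool = False
    psf_sigma_px: float = 1.0
    intensity_threshold: str | float = "automatic"
    min_area_px: int = 3
    max_area_px: int = 500
    min_separation_px: float = 3.0


class TopographyConfig(_Strict):
    enabled: bool = True
    bin_size_mm: float = 0.1
    scale_max: float = 4800.0
    neighbour_radius_mm: float = 0.165
    n_wedges: int = 24
    loss_threshold: float = 0.8


class VolumetryConfig(_Strict):
    enabled: bool = True
    degree: int = 5
    patch: list[float] = Field(default_factory=lambda: [-4.3, -3.6, 0.5])
    noise_cv: float = 0.05


class StatsConfig(_Strict):
    enabled: bool = True
    iop_threshold_mmHg: float = 25.0
    iop_window_h: float = 48.0
    alternative: str = "two-sided"


class PipelineConfig(_Strict):
    seed: int = 0
    out_dir: str = "pipeline_out"
    verbosity: str = "info"
    generate: GenerateConfig = Field(default_factory=GenerateConfig)
    detect: DetectConfig = Field(default_factory=DetectConfig)
    topography: TopographyConfig = Field(default_factory=TopographyConfig)
    volumetry: VolumetryConfig = Field(default_factory=VolumetryConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @classmethod
    def paper_demo(cls, seed: int = 0) -> "PipelineConfig":
        """Demo cohort: control targets from the study's control means
        and a lesion designed for 50% overall loss (one fully ablated
        90° wedge plus 1/3 diffuse loss: 0.75 x 2/3 = 0.5 survival)."""
        return cls(seed=seed)


def stage_seed(config: PipelineConfig, stage: str) -> int:
    """Deterministic child seed (< 2**31) for a pipeline stage."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(config.seed), idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
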