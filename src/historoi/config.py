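"""Validated pipeline configuration (YAML) shared by the CLI subcommands."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict

from .conspicuity import PyramidConfig
from .fixtures import FixtureSpec
from .learning import GPSConfig
from .quality import DistanceWeighting
from .segmentation import SegmentationParams


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixturesConfig(_Section):
    width: int = 128
    height: int = 128
    n_islets: int = 2
    islet_radius_range: Tuple[float, float] = (14.0, 24.0)
    background_color: Tuple[int, int, int] = (230, 200, 210)
    islet_color: Tuple[int, int, int] = (120, 90, 160)
    islet_texture_noise_sd: float = 45.0
    background_noise_sd: float = 5.0
    blur_sigma: float = 0.8

    def spec(self, seed: int = 0) -> FixtureSpec:
        return FixtureSpec(seed=seed, **self.model_dump())


class PyramidSection(_Section):
    n_levels: Optional[int] = None  # None: pick by image size
    center_levels: Optional[Tuple[int, ...]] = None
    surround_deltas: Optional[Tuple[int, ...]] = None
    n_orientations: int = 4

    def pyramid(self) -> Optional[PyramidConfig]:
        if self.n_levels is None:
            return None
        return PyramidConfig(n_levels=self.n_levels,
                             center_levels=self.center_levels or (1, 2),
                             surround_deltas=self.surround_deltas or (2,),
                             n_orientations=self.n_orientations)


class EntropySection(_Section):
    window: int = 9
    bins: int = 32
    normalize: bool = False


class SegmentationSection(_Section):
    k: float = 500.0
    smooth_sigma: float = 0.8
    min_size: int = 20
    connectivity: int = 4
    color_edges: bool = False

    def params(self) -> SegmentationParams:
        return SegmentationParams(**self.model_dump())


class MetricSection(_Section):
    slope: float = 1.0
    offset: float = 1.0
    d_max: float = 20.0

    def weighting(self) -> DistanceWeighting:
        return DistanceWeighting(**self.model_dump())


class GPSSection(_Section):
    initial_mesh: float = 1.0
    max_refinements: int = 6

    def gps(self) -> GPSConfig:
        return GPSConfig(initial_mesh=self.initial_mesh,
                         max_refinements=self.max_refinements)


class WeightsSection(_Section):
    intensity: float = 0.25
    color: float = 0.25
    orientation: float = 0.25
    entropy: float = 0.25


class PipelineConfig(_Section):
    """Top-level configuration; unknown keys anywhere raise a validation error."""

    fixtures: FixturesConfig = FixturesConfig()
    pyramid: PyramidSection = PyramidSection()
    entropy: EntropySection = EntropySection()
    segmentation: SegmentationSection = SegmentationSection()
    metric: MetricSection = MetricSection()
    gps: GPSSection = GPSSection()
    weights: WeightsSection = WeightsSection()
    coverage_threshold: float = 0.70
    seed: int = 0


def load_config(path: Optional[str | Path] = None) -> PipelineConfig:
    """Load and validate a YAML config; an empty or missing file gives all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.model_validate(raw or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
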