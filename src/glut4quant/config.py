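"""Pipeline configuration.

All geometric constants default to the values used throughout the package:
a 3-pixel plasma-membrane band centred on the membrane midline, five 1-µm
concentric intracellular layers, and a 1-µm equivalent-diameter split
between small and large GLUT4 spots.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator


class SnakeConfig(BaseModel):
    """Active-contour parameters for membrane midline finding."""

    alpha: float = Field(0.02, gt=0, description="tension (first-derivative) weight")
    beta: float = Field(0.5, gt=0, description="rigidity (second-derivative) weight")
    gamma: float = Field(2.0, gt=0, description="implicit Euler step size")
    sigma: float = Field(2.0, gt=0, description="Gaussian smoothing of the image, px")
    force_scale: float = Field(4.0, gt=0, description="external force multiplier")
    tolerance_px: float = Field(0.02, gt=0, description="mean vertex displacement to declare convergence")
    max_iterations: int = Field(500, gt=0)
    n_vertices: int = Field(200, ge=16)
    min_area_px: float = Field(500.0, gt=0, description="minimum enclosed area; smaller -> segmentation failure")


class StatisticsConfig(BaseModel):
    """Mixed-model options."""

    count_transform: Literal["log1p", "none"] = "log1p"
    posthoc_adjust: Literal["bonferroni", "none"] = "bonferroni"
    alpha: float = Field(0.05, gt=0, lt=1)


class PipelineConfig(BaseModel):
    """Complete parameter set for a segmentation + quantification run."""

    pixel_size_um: float = Field(0.2, gt=0, description="µm per pixel")
    layer_width_um: float = Field(1.0, gt=0, description="width of each intracellular layer")
    n_layers: int = Field(5, ge=1)
    pm_thickness_px: float = Field(3.0, gt=0, description="plasma-membrane band thickness, px")
    layer_origin: Literal["pm_inner_edge", "midline"] = "pm_inner_edge"
    spot_min_area_px: int = Field(2, ge=1, description="minimum spot area, px")
    size_threshold_um: float = Field(1.0, gt=0, description="small/large equivalent-diameter split")
    pcc_region: Literal["whole_fibre", "pm_band"] = "whole_fibre"
    fibre_type_fallback_cut: float = Field(1000.0, gt=0, description="MHC1 positivity cut when the cohort is degenerate")
    channel_order: tuple[str, str, str] = ("dystrophin", "glut4", "mhc1")
    snake: SnakeConfig = Field(default_factory=SnakeConfig)
    statistics: StatisticsConfig = Field(default_factory=StatisticsConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _check_layer_resolution(self) -> "PipelineConfig":
        if self.layer_width_um / self.pixel_size_um < 2:
            import warnings

            warnings.warn(
                "layer width is below 2 px at this pixel size; layer masks will be coarse",
                stacklevel=2,
            )
        return self

    @property
    def layer_width_px(self) -> float:
        return self.layer_width_um / self.pixel_size_um

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)
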