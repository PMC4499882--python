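"""Validated run configuration.

Defaults encode the study conditions: Poisson ratio 0.2, a cylindrical
gel domain 2 mm in height and diameter, the 50-um near/far bead distance
threshold and the 2-hour imaging cadence. Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialConfig(_Strict):
    E: float = Field(500.0, gt=0, description="Young's modulus, Pa")
    nu: float = Field(0.2, ge=0, lt=0.5, description="Poisson ratio")


class MeshConfig(_Strict):
    gel_shape: Literal["cylinder", "sphere", "box"] = "cylinder"
    height: float = Field(2000.0, gt=0, description="cylinder height, um")
    diameter: float = Field(2000.0, gt=0, description="cylinder diameter, um")
    sphere_radius: float = Field(1000.0, gt=0)
    n_layers: int = Field(8, ge=1)
    order: Literal[1, 2] = 2
    surface_radius: float = Field(50.0, gt=0, description="tissue sphere, um")
    surface_subdivisions: int = Field(2, ge=0, le=4)


class InterpolationConfig(_Strict):
    method: Literal["thin_plate_spline", "gaussian", "linear", "cubic"] = \
        "thin_plate_spline"
    length_scale: float | None = Field(None, gt=0)
    neighbors: int | None = Field(128, ge=8)


class CcfConfig(_Strict):
    max_lag: int = Field(5, ge=1)
    estimator: Literal["biased", "unbiased"] = "biased"
    sd_ddof: Literal[0, 1] = 1


class AlignmentConfig(_Strict):
    subregion_size_px: int = Field(24, ge=8)
    window_px: int | None = Field(None, ge=4)
    coherence_min: float = Field(0.2, ge=0, le=1)
    n_bins: int = Field(18, ge=2)
    grad_sigma: float = Field(2.0, gt=0)


class ThresholdConfig(_Strict):
    near_far_um: float = Field(50.0, gt=0)


class RunConfig(_Strict):
    material: MaterialConfig = MaterialConfig()
    mesh: MeshConfig = MeshConfig()
    interpolation: InterpolationConfig = InterpolationConfig()
    ccf: CcfConfig = CcfConfig()
    alignment: AlignmentConfig = AlignmentConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    seed: int = 0
    out_dir: str = "runs"

    @model_validator(mode="after")
    def _check_geometry(self) -> "RunConfig":
        if self.mesh.gel_shape == "cylinder":
            bound = min(self.mesh.height, self.mesh.diameter) / 2.0
        elif self.mesh.gel_shape == "sphere":
            bound = self.mesh.sphere_radius
        else:
            bound = min(self.mesh.height, self.mesh.diameter) / 2.0
        if self.mesh.surface_radius >= bound:
            raise ValueError("tissue surface must fit inside the gel domain")
        return self


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config (all keys optional) and apply overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    data.update(overrides)
    return RunConfig(**data)
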