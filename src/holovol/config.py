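"""Optical and pipeline configuration.

All unit conversions in the package flow through :class:`OpticalConfig`:
the vacuum wavelength sets the phase-to-thickness scale, the refractive
index contrast sets the optical path per micron of material, and the
camera pitch divided by the lateral magnification sets the object-plane
sampling of every raster.
"""

from __future__ import annotations

from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class OpticalConfig(BaseModel):
    """Interferometer and imaging-train parameters.

    Defaults describe a 633 nm Mach-Zehnder transmission setup with a 60x
    objective and a 3.45 um camera, measuring cells (n = 1.38) in culture
    medium (n = 1.33).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    wavelength_um: float = 0.633
    n_object: float = 1.38
    n_medium: float = 1.33
    magnification: float = 60.0
    camera_pixel_um: float = 3.45

    @model_validator(mode="after")
    def _check_physical(self) -> "OpticalConfig":
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if not (self.n_object > self.n_medium > 1.0):
            raise ValueError(
                "refractive indices must satisfy n_object > n_medium > 1 "
                f"(got n_object={self.n_object}, n_medium={self.n_medium})"
            )
        if self.magnification <= 0 or self.camera_pixel_um <= 0:
            raise ValueError("magnification and camera_pixel_um must be positive")
        return self

    @property
    def object_pixel_um(self) -> float:
        """Object-plane sampling: camera pitch demagnified by the objective."""
        return self.camera_pixel_um / self.magnification

    @property
    def contrast(self) -> float:
        """Refractive-index contrast n_object - n_medium (> 0 by validation)."""
        return self.n_object - self.n_medium


class ReconstructionParams(BaseModel):
    """Sideband filtering, propagation and autofocus settings."""

    model_config = ConfigDict(extra="forbid")

    carrier_cycles_per_um: Optional[Tuple[float, float]] = None  # None -> auto-locate
    radius_frac: float = 0.5
    dc_exclusion_frac: float = 0.1
    distance_um: Optional[float] = 0.0  # fixed reconstruction distance
    focus_range_um: Optional[Tuple[float, float]] = None  # overrides distance_um
    focus_step_um: float = 5.0


class FlattenParams(BaseModel):
    """Background compensation settings (Zernike + median)."""

    model_config = ConfigDict(extra="forbid")

    zernike_order: int = 4
    median_kernel_px: int = 51


class SegmentationParams(BaseModel):
    """Dual-threshold + morphological-reconstruction segmentation settings."""

    model_config = ConfigDict(extra="forbid")

    high_frac: float = Field(default=0.5, gt=0.0, lt=1.0)
    low_thresh_um: Optional[float] = None  # None -> background median + 3*MAD
    min_area_px: int = Field(default=64, ge=1)
    closing_radius_px: int = Field(default=5, ge=0)


class PipelineConfig(BaseModel):
    """Full end-to-end pipeline configuration; strict on unknown keys."""

    model_config = ConfigDict(extra="forbid")

    optical: OpticalConfig = OpticalConfig()
    reconstruction: ReconstructionParams = ReconstructionParams()
    flatten: FlattenParams = FlattenParams()
    segmentation: SegmentationParams = SegmentationParams()
    association_radius_um: float = 10.0
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        return cls.model_validate(data)
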