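"""Core raster containers passed between pipeline stages.

A :class:`Hologram` is the recorded real-valued interference pattern; a
:class:`Spectrum` is its DC-centered 2-D Fourier transform; a
:class:`ComplexField` is a reconstructed complex wavefront at a stated
propagation distance; a :class:`PhaseMap` is a real phase raster tagged
with its processing state (wrapped / unwrapped / compensated) so stages
cannot be chained out of order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Tuple

import numpy as np

from .config import OpticalConfig

PhaseState = Literal["wrapped", "unwrapped", "compensated"]


class StateError(RuntimeError):
    """A phase raster was passed to a stage in the wrong processing state."""


@dataclass
class Hologram:
    """Off-axis interference raster with object-plane pixel calibration."""

    intensity: np.ndarray
    pixel_um: float
    config: OpticalConfig
    timestamp_min: Optional[float] = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError(f"hologram must be 2-D, got shape {self.intensity.shape}")
        if any(s % 2 for s in self.intensity.shape):
            raise ValueError(f"hologram dimensions must be even, got {self.intensity.shape}")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("hologram contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensities must be non-negative")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.intensity.shape


@dataclass
class Spectrum:
    """DC-centered complex spectrum of a hologram."""

    data: np.ndarray
    freq_step_per_um: Tuple[float, float]  # (dfy, dfx), cycles/um per bin
    source_shape: Tuple[int, int]
    pixel_um: float
    config: OpticalConfig

    @property
    def nyquist_per_um(self) -> float:
        return 0.5 / self.pixel_um


@dataclass
class ComplexField:
    """Complex wavefront at ``distance_um`` from the hologram plane."""

    data: np.ndarray
    pixel_um: float
    distance_um: float
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("field must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field contains non-finite values")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    def copy_with(self, **kw) -> "ComplexField":
        return replace(self, **kw)


@dataclass
class PhaseMap:
    """Phase raster in radians with an explicit processing state."""

    data: np.ndarray
    state: PhaseState
    pixel_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("phase map must be 2-D")
        if self.state not in ("wrapped", "unwrapped", "compensated"):
            raise ValueError(f"unknown phase state {self.state!r}")
        if self.state == "wrapped":
            lo, hi = self.data.min(), self.data.max()
            if lo <= -np.pi - 1e-12 or hi > np.pi + 1e-12:
                raise ValueError(
                    f"wrapped phase must lie in (-pi, pi], got range [{lo}, {hi}]"
                )

    def require_state(self, state: PhaseState) -> None:
        if self.state != state:
            raise StateError(f"expected {state!r} phase map, got {self.state!r}")
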