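"""TIFF / JSON input-output for holograms, rasters and ground truth."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .config import OpticalConfig
from .fields import Hologram
from .phantoms import GroundTruth

PathLike = Union[str, Path]


def read_hologram(
    path: PathLike, config: Optional[OpticalConfig], timestamp_min: Optional[float] = None
) -> Hologram:
    """Read a single-channel TIFF as a hologram with pixel calibration.

    Integer rasters are cast to float with their range preserved; RGB or
    multi-page inputs and missing calibration are rejected.
    """
    if config is None:
        raise ValueError(
            "missing calibration: an OpticalConfig is required to read holograms"
        )
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2-D TIFF, got shape {arr.shape} "
            "(RGB/multi-channel input is not supported)"
        )
    return Hologram(
        intensity=arr.astype(np.float64),
        pixel_um=config.object_pixel_um,
        config=config,
        timestamp_min=timestamp_min,
    )


def write_raster(path: PathLike, data: np.ndarray) -> None:
    """Write a raster as single-channel 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32))


def write_mask(path: PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_raster(path: PathLike) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D raster, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_ground_truth(
    path: PathLike,
    gt: GroundTruth,
    config: OpticalConfig,
    mask_path: Optional[str] = None,
) -> None:
    """Sidecar JSON with the phantom's exact volume and render parameters."""
    payload = {
        "volume_um3": gt.volume_um3,
        "pixel_um": gt.pixel_um,
        "defocus_um": gt.defocus_um,
        "zernike_coeffs": list(gt.zernike_coeffs),
        "carrier_cycles_per_um": (
            list(gt.carrier_cycles_per_um) if gt.carrier_cycles_per_um else None
        ),
        "seed": gt.seed,
        "mask_path": mask_path,
        "config": config.model_dump(mode="json"),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
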