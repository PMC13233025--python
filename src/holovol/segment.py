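"""Cell-support segmentation of thickness maps.

Dual thresholding: a high threshold (fraction of the maximum thickness)
seeds the thick central core of each cell; a very low absolute threshold
(near the noise floor) captures the full spatial extent including thin
pseudopodia, plus background noise. Morphological reconstruction keeps
only the low-threshold components touched by a seed, discarding noise;
area opening and closing then remove residual specks and fill micro-holes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage import measure, morphology

from .config import SegmentationParams


class EmptyFieldError(ValueError):
    """The thickness map contains no object (all zeros)."""


@dataclass
class CellMask:
    """Boolean cell mask plus its 8-connected component bookkeeping."""

    mask: np.ndarray
    n_components: int
    areas_px: Tuple[int, ...]
    labels: np.ndarray

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "CellMask":
        mask = np.asarray(mask, dtype=bool)
        labels = measure.label(mask, connectivity=2)
        n = int(labels.max())
        areas = tuple(int(a) for a in np.bincount(labels.ravel())[1:])
        return cls(mask=mask, n_components=n, areas_px=areas, labels=labels)


def auto_low_threshold(thickness: np.ndarray) -> float:
    """Background noise floor: median + 3*MAD of the thickness raster.

    The background dominates the field, so the global median/MAD estimate
    the noise floor robustly. If the raster is noise-free (MAD = 0) a small
    fraction of the peak thickness is used instead.
    """
    med = float(np.median(thickness))
    mad = float(np.median(np.abs(thickness - med)))
    low = med + 3.0 * mad
    if low <= 0:
        low = 0.01 * float(thickness.max())
    return low


def dual_threshold(
    thickness: np.ndarray, params: SegmentationParams
) -> Tuple[np.ndarray, np.ndarray]:
    """Seed (core) and boundary (full-extent) masks; seed is a subset."""
    thickness = np.asarray(thickness, dtype=np.float64)
    if not np.all(np.isfinite(thickness)) or np.any(thickness < 0):
        raise ValueError("thickness must be finite and non-negative")
    peak = float(thickness.max())
    if peak == 0:
        raise EmptyFieldError("empty field: maximum thickness is zero")
    low = params.low_thresh_um
    if low is None:
        low = auto_low_threshold(thickness)
    high = params.high_frac * peak
    seed = thickness >= max(high, low)
    boundary = thickness >= low
    return seed, boundary


def reconstruct_by_dilation(seed: np.ndarray, boundary: np.ndarray) -> CellMask:
    """Keep the boundary components that intersect the seed (8-connected)."""
    seed = np.asarray(seed, dtype=bool)
    boundary = np.asarray(boundary, dtype=bool)
    if seed.shape != boundary.shape:
        raise ValueError("seed and boundary shapes differ")
    if np.any(seed & ~boundary):
        raise ValueError("seed mask must be a subset of the boundary mask")
    labels = measure.label(boundary, connectivity=2)
    keep = np.unique(labels[seed])
    keep = keep[keep > 0]
    mask = np.isin(labels, keep)
    return CellMask.from_mask(mask)


def clean_mask(cell_mask: CellMask, params: SegmentationParams) -> CellMask:
    """Area-open specks, close micro-holes; idempotent by construction."""
    # skimage's max_size removes objects/holes of area <= max_size, so the
    # "smaller than min_area_px" rule maps to max_size = min_area_px - 1.
    m = morphology.remove_small_objects(
        cell_mask.mask, connectivity=2, max_size=params.min_area_px - 1
    )
    r = params.closing_radius_px
    if r > 0:
        m = morphology.closing(m, footprint=morphology.disk(r))
        hole_area = int(np.ceil(np.pi * r * r))
        m = morphology.remove_small_holes(m, connectivity=1, max_size=hole_area)
    m = morphology.remove_small_objects(m, connectivity=2, max_size=params.min_area_px - 1)
    return CellMask.from_mask(m)


def segment_cells(thickness: np.ndarray, params: SegmentationParams) -> CellMask:
    """Full segmentation chain: dual threshold, reconstruction, cleanup."""
    seed, boundary = dual_threshold(thickness, params)
    cm = reconstruct_by_dilation(seed, boundary)
    return clean_mask(cm, params)
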