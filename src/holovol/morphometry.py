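"""Thickness conversion, per-cell volume and shape, and time-series analysis.

Phase converts to physical thickness through h = lambda * dtheta /
(2 pi (n_obj - n_med)) under a constant refractive-index contrast; the
integral of thickness over the segmented footprint is the cell's effective
optical volume V = integral h dx dy. Shape is summarized by top-view
circularity 4 pi A / P^2 (Crofton perimeter) and Wadell sphericity
pi^(1/3) (6V)^(2/3) / A_surf with the surface area taken from the thickness
relief (upper surface plus base).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure

from .config import OpticalConfig
from .fields import PhaseMap
from .segment import CellMask

logger = logging.getLogger(__name__)

#: Components below this pixel area get undefined (NaN) shape descriptors.
MIN_DESCRIPTOR_AREA_PX = 16


@dataclass
class CellRecord:
    """Morphometrics of one segmented cell."""

    cell_id: int
    volume_um3: float
    max_thickness_um: float
    area_um2: float
    circularity: float
    sphericity: float
    centroid_xy_um: Tuple[float, float]


@dataclass
class VolumeSeries:
    """Volume trajectory of one tracked cell plus per-frame totals."""

    times_min: List[float]
    volumes_um3: List[float]
    dv_dt_um3_per_min: List[float]
    phase_labels: List[str]
    monotone_decreasing: bool
    sign_change_indices: List[int]  # volume indices at slope sign flips
    total_volumes_um3: List[float] = field(default_factory=list)

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.volumes_um3))


def phase_to_thickness(phase: PhaseMap, config: OpticalConfig) -> np.ndarray:
    """Thickness in um from a compensated phase map; negatives clip to zero."""
    phase.require_state("compensated")
    if config.contrast <= 0:
        raise ValueError("zero or negative refractive-index contrast")
    h = config.wavelength_um * phase.data / (2.0 * np.pi * config.contrast)
    n_neg = int(np.count_nonzero(h < 0))
    if n_neg:
        logger.warning("clipped %d negative-thickness pixels to zero", n_neg)
        h = np.clip(h, 0.0, None)
    return h


def cell_volume(
    thickness: np.ndarray, mask: CellMask, pixel_um: float
) -> Dict[int, float]:
    """Riemann-sum volume (um^3) of each 8-connected component."""
    thickness = np.asarray(thickness, dtype=np.float64)
    if thickness.shape != mask.mask.shape:
        raise ValueError("thickness and mask shapes differ")
    pixel_area = pixel_um**2
    out: Dict[int, float] = {}
    for comp in range(1, mask.n_components + 1):
        sel = mask.labels == comp
        out[comp] = float(pixel_area * thickness[sel].sum())
    return out


def _surface_area(
    thickness: np.ndarray, comp_mask: np.ndarray, pixel_um: float
) -> float:
    """Upper-surface area from the thickness relief plus the base area."""
    gy, gx = np.gradient(thickness, pixel_um)
    integrand = np.sqrt(1.0 + gx**2 + gy**2)
    pixel_area = pixel_um**2
    upper = float(pixel_area * integrand[comp_mask].sum())
    base = float(pixel_area * comp_mask.sum())
    return upper + base


def shape_descriptors(
    mask: CellMask, thickness: np.ndarray, pixel_um: float
) -> Dict[int, Tuple[float, float]]:
    """(circularity, sphericity) per component; NaN for degenerate blobs."""
    out: Dict[int, Tuple[float, float]] = {}
    pixel_area = pixel_um**2
    for comp in range(1, mask.n_components + 1):
        sel = mask.labels == comp
        area_px = int(sel.sum())
        if area_px < MIN_DESCRIPTOR_AREA_PX:
            logger.warning(
                "component %d too small (%d px) for shape descriptors", comp, area_px
            )
            out[comp] = (float("nan"), float("nan"))
            continue
        area = area_px * pixel_area
        perim = measure.perimeter_crofton(sel, directions=4) * pixel_um
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else float("nan")
        vol = float(pixel_area * thickness[sel].sum())
        a_surf = _surface_area(thickness, sel, pixel_um)
        spher = (
            np.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / a_surf
            if a_surf > 0 and vol > 0
            else float("nan")
        )
        out[comp] = (float(circ), float(spher))
    return out


def measure_cells(
    thickness: np.ndarray, mask: CellMask, pixel_um: float
) -> List[CellRecord]:
    """Per-component morphometrics, one :class:`CellRecord` each."""
    volumes = cell_volume(thickness, mask, pixel_um)
    shapes = shape_descriptors(mask, thickness, pixel_um)
    records = []
    for comp in range(1, mask.n_components + 1):
        sel = mask.labels == comp
        rows, cols = np.nonzero(sel)
        centroid = (float(cols.mean() * pixel_um), float(rows.mean() * pixel_um))
        circ, spher = shapes[comp]
        records.append(
            CellRecord(
                cell_id=comp,
                volume_um3=volumes[comp],
                max_thickness_um=float(thickness[sel].max()) if sel.any() else 0.0,
                area_um2=float(sel.sum() * pixel_um**2),
                circularity=circ,
                sphericity=spher,
                centroid_xy_um=centroid,
            )
        )
    return records


class AssociationError(RuntimeError):
    """Frame-to-frame cell association was ambiguous."""


def _associate(
    prev: CellRecord, candidates: Sequence[CellRecord], radius_um: float
) -> Optional[CellRecord]:
    px, py = prev.centroid_xy_um
    hits = [
        c
        for c in candidates
        if np.hypot(c.centroid_xy_um[0] - px, c.centroid_xy_um[1] - py) <= radius_um
    ]
    if len(hits) > 1:
        raise AssociationError(
            f"ambiguous association: {len(hits)} candidates within {radius_um} um "
            f"of centroid ({px:.1f}, {py:.1f}): ids {[c.cell_id for c in hits]}"
        )
    return hits[0] if hits else None


def analyze_series(
    frames: Sequence[Sequence[CellRecord]],
    times_min: Sequence[float],
    association_radius_um: float = 10.0,
    rapid_factor: float = 1.5,
) -> VolumeSeries:
    """Track the primary cell across frames and stage its volume dynamics.

    The primary cell is the largest-volume cell of the first frame; frames
    are linked by nearest-centroid association within the given radius.
    Interval slopes dV/dt are labeled rapid when their magnitude exceeds
    ``rapid_factor`` times the median slope magnitude, else slow; a series
    whose slopes are all negative is flagged as death-like (monotone
    decrease), and slope sign changes mark troughs/peaks (e.g. a division
    spike followed by decline).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 time points")
    times = [float(t) for t in times_min]
    if len(times) != len(frames):
        raise ValueError("times_min length must match frames")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    if not frames[0]:
        raise ValueError("first frame contains no cells")
    current = max(frames[0], key=lambda r: r.volume_um3)
    volumes = [current.volume_um3]
    kept_times = [times[0]]
    for frame, t in zip(frames[1:], times[1:]):
        nxt = _associate(current, frame, association_radius_um)
        if nxt is None:
            logger.warning("track lost at t=%.1f min; series truncated", t)
            break
        current = nxt
        volumes.append(current.volume_um3)
        kept_times.append(t)
    v = np.asarray(volumes)
    t = np.asarray(kept_times)
    slopes = list(np.diff(v) / np.diff(t))
    med = float(np.median(np.abs(slopes))) if slopes else 0.0
    labels = [
        "rapid" if med > 0 and abs(s) > rapid_factor * med else "slow" for s in slopes
    ]
    signs = np.sign(slopes)
    sign_changes = [
        i
        for i in range(1, len(slopes))
        if signs[i] != 0 and signs[i - 1] != 0 and signs[i] != signs[i - 1]
    ]
    totals = [float(sum(r.volume_um3 for r in frame)) for frame in frames]
    return VolumeSeries(
        times_min=kept_times,
        volumes_um3=list(map(float, volumes)),
        dv_dt_um3_per_min=[float(s) for s in slopes],
        phase_labels=labels,
        monotone_decreasing=bool(slopes) and all(s < 0 for s in slopes),
        sign_change_indices=sign_changes,
        total_volumes_um3=totals,
    )
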