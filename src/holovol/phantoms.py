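"""Ground-truthed phase phantoms and off-axis hologram rendering.

Every downstream stage is validated against phantoms whose thickness map,
support mask and integrated volume are known exactly:

* ``sphere`` — a silica-microsphere analog with the chord thickness profile
  h(r) = 2 sqrt((d/2)^2 - r^2);
* ``spherical_cap`` — an adherent rounded cell (M0/M2-like morphology);
* ``pancake_pseudopodia`` — a spread, flattened cell with tapered radial
  protrusions (M1-like morphology), seeded shape jitter.

Thickness maps receive a Gaussian edge blur (sigma = 2 px) before phase
conversion so phase gradients stay below pi per pixel and unwrapping is
well-posed; the ground-truth volume is integrated AFTER blurring, so it is
exact for the rendered object. Holograms follow I = |O + R|^2 with a unit
plane reference tilted to place the object-bearing (+1) sideband at the
requested carrier frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import OpticalConfig
from .fields import ComplexField, Hologram
from .reconstruct import angular_spectrum_propagate
from .zernike import zernike_surface

logger = logging.getLogger(__name__)

EDGE_BLUR_SIGMA_PX = 2.0
#: Default off-axis carrier: 1/8 of the sampling frequency along both axes.
DEFAULT_CARRIER_FRAC = 0.125
DEFAULT_NOISE_SIGMA = 0.01

PHANTOM_KINDS = ("sphere", "spherical_cap", "pancake_pseudopodia")


@dataclass
class PhantomSpec:
    """Declarative phantom description; volumes in um^3, positions in um."""

    kind: str
    target_volume_um3: Optional[float] = None
    diameter_um: Optional[float] = None  # spheres may be sized by diameter
    center_xy_um: Tuple[float, float] = (0.0, 0.0)
    cap_height_ratio: float = 0.8  # cap height / base radius
    pancake_height_um: float = 6.0
    n_pseudopodia: int = 5
    pseudopod_reach: float = 1.2  # tip radius / body radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"kind must be one of {PHANTOM_KINDS}, got {self.kind!r}")
        if self.kind == "sphere":
            if self.diameter_um is None and self.target_volume_um3 is None:
                raise ValueError("sphere needs diameter_um or target_volume_um3")
        elif self.target_volume_um3 is None:
            raise ValueError(f"{self.kind} needs target_volume_um3")
        if self.target_volume_um3 is not None and self.target_volume_um3 <= 0:
            raise ValueError("target_volume_um3 must be positive")
        if self.diameter_um is not None and self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")


@dataclass
class GroundTruth:
    """Exact thickness map, support mask and volume of a rendered phantom."""

    thickness_map: np.ndarray  # um per pixel
    mask: np.ndarray  # boolean support
    volume_um3: float
    pixel_um: float
    defocus_um: float = 0.0
    zernike_coeffs: Tuple[float, ...] = ()
    carrier_cycles_per_um: Optional[Tuple[float, float]] = None
    seed: int = 0


def _object_grid(
    grid_shape: Tuple[int, int], pixel_um: float, center_xy_um: Tuple[float, float]
) -> Tuple[np.ndarray, np.ndarray]:
    ny, nx = grid_shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_um - center_xy_um[1]
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_um - center_xy_um[0]
    return np.meshgrid(x, y)


def _sphere_thickness(spec: PhantomSpec, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    if spec.diameter_um is not None:
        d = spec.diameter_um
    else:
        d = (6.0 * spec.target_volume_um3 / np.pi) ** (1.0 / 3.0)
    r0 = d / 2.0
    r2 = xx**2 + yy**2
    return 2.0 * np.sqrt(np.clip(r0**2 - r2, 0.0, None))


def _cap_thickness(spec: PhantomSpec, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    # Spherical cap of base radius a and height h = ratio * a sized so the
    # analytic volume pi h (3 a^2 + h^2) / 6 hits the target; the post-blur
    # map is rescaled to the target exactly.
    rho = spec.cap_height_ratio
    v = spec.target_volume_um3
    a = (6.0 * v / (np.pi * rho * (3.0 + rho**2))) ** (1.0 / 3.0)
    h = rho * a
    big_r = (a**2 + h**2) / (2.0 * h)
    r2 = xx**2 + yy**2
    t = np.sqrt(np.clip(big_r**2 - r2, 0.0, None)) - (big_r - h)
    t[r2 > a**2] = 0.0
    return np.clip(t, 0.0, None)


def _pancake_thickness(spec: PhantomSpec, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    # Flattened super-Gaussian body plus k tapered radial ridges (pseudopodia)
    # placed with seeded angular/length jitter; rescaled to target volume.
    rng = np.random.default_rng(spec.seed)
    h0 = spec.pancake_height_um
    # effective fill of the super-Gaussian body integral (exp(-(r/a)^6))
    body_fill = 0.87
    a = np.sqrt(spec.target_volume_um3 / (np.pi * body_fill * h0))
    r = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    t = h0 * np.exp(-((r / a) ** 6))
    k = spec.n_pseudopodia
    width = max(0.08 * a, 1.0)
    for i in range(k):
        ang = 2 * np.pi * i / k + rng.uniform(-0.25, 0.25)
        reach = spec.pseudopod_reach * a * rng.uniform(0.9, 1.1)
        # distance along / across the ridge direction; the ridge fades in
        # from mid-body and tapers to zero at the tip, so each pseudopod
        # protrudes past the body edge as a thin tapering extension
        s = xx * np.cos(ang) + yy * np.sin(ang)
        p = -xx * np.sin(ang) + yy * np.cos(ang)
        fade_in = np.clip((s - 0.5 * a) / (0.2 * a), 0.0, 1.0)
        taper = np.clip(1.0 - s / reach, 0.0, 1.0)
        ridge = 0.5 * h0 * fade_in * taper * np.exp(-((p / width) ** 2))
        t = t + ridge
    t[t < 1e-3 * h0] = 0.0  # truncate the analytic tails to a compact support
    return t


def make_phantom(
    spec: PhantomSpec, grid_shape: Tuple[int, int], config: OpticalConfig
) -> GroundTruth:
    """Render a phantom thickness map with exact ground-truth volume.

    Raises if the phantom (after edge blur) does not fit the grid with at
    least a 10% margin on every side, naming the required grid size.
    """
    pixel = config.object_pixel_um
    xx, yy = _object_grid(grid_shape, pixel, spec.center_xy_um)
    if spec.kind == "sphere":
        t = _sphere_thickness(spec, xx, yy)
        if t.max() < pixel:
            raise ValueError(
                "sphere diameter below one pixel; increase diameter or magnification"
            )
    elif spec.kind == "spherical_cap":
        t = _cap_thickness(spec, xx, yy)
    else:
        t = _pancake_thickness(spec, xx, yy)
    if not t.any():
        raise ValueError("phantom renders to an empty thickness map")
    t = ndimage.gaussian_filter(t, sigma=EDGE_BLUR_SIGMA_PX)
    t[t < 0] = 0.0
    support = t > 0
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    ny, nx = grid_shape
    extent = (rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
    margins_frac = (
        rows[0] / ny,
        (ny - 1 - rows[-1]) / ny,
        cols[0] / nx,
        (nx - 1 - cols[-1]) / nx,
    )
    if min(margins_frac) < 0.1:
        need = int(np.ceil(max(extent) / 0.8))
        raise ValueError(
            f"phantom extent {extent} px violates the 10% margin on a "
            f"{grid_shape} grid; need a grid of at least {need} px per side"
        )
    pixel_area = pixel**2
    if spec.kind != "sphere" and spec.target_volume_um3 is not None:
        t *= spec.target_volume_um3 / (pixel_area * t.sum())
    volume = float(pixel_area * t.sum())
    return GroundTruth(
        thickness_map=t,
        mask=support,
        volume_um3=volume,
        pixel_um=pixel,
        seed=spec.seed,
    )


def thickness_to_phase(gt: GroundTruth, config: OpticalConfig) -> np.ndarray:
    """True continuous phase delta-theta = 2 pi (n_obj - n_med) h / lambda."""
    if config.contrast <= 0:
        raise ValueError("n_object must exceed n_medium (zero/negative contrast)")
    return 2.0 * np.pi * config.contrast * gt.thickness_map / config.wavelength_um


def default_carrier(config: OpticalConfig) -> Tuple[float, float]:
    """Default carrier: 1/8 of the sampling frequency along both axes."""
    fs = 1.0 / config.object_pixel_um
    return (DEFAULT_CARRIER_FRAC * fs, DEFAULT_CARRIER_FRAC * fs)


def render_hologram(
    true_phase: np.ndarray,
    carrier: Tuple[float, float],
    config: OpticalConfig,
    defocus_um: float = 0.0,
    zernike_coeffs: Sequence[float] = (),
    noise_sigma: float = 0.0,
    seed: int = 0,
    timestamp_min: Optional[float] = None,
) -> Hologram:
    """Render an off-axis hologram I = |O + R|^2 of a pure-phase object.

    O = exp(i true_phase), back-propagated by ``defocus_um`` (so that the
    stated defocus is the reconstruction distance that refocuses it) and
    multiplied by a Zernike aberration phasor at the detector; R is a unit
    plane wave tilted so the +1 sideband lands at ``carrier`` (cycles/um).
    Gaussian intensity noise of relative sigma ``noise_sigma`` is added and
    the result clipped at zero. Identical seeds give bit-identical rasters.
    """
    true_phase = np.asarray(true_phase, dtype=np.float64)
    if true_phase.ndim != 2:
        raise ValueError("true_phase must be 2-D")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    pixel = config.object_pixel_um
    f_nyq = 0.5 / pixel
    fmag = float(np.hypot(*carrier))
    if fmag == 0 or fmag >= 0.5 * f_nyq:
        raise ValueError(
            "carrier magnitude must be positive and below Nyquist/2 = "
            f"{0.5 * f_nyq:.4g} cycles/um for sideband separability (got {fmag:.4g})"
        )
    obj = np.exp(1j * true_phase)
    if defocus_um != 0.0:
        f = ComplexField(data=obj, pixel_um=pixel, distance_um=0.0, config=config)
        obj = angular_spectrum_propagate(f, -defocus_um).data
    if len(zernike_coeffs):
        obj = obj * np.exp(1j * zernike_surface(zernike_coeffs, true_phase.shape))
    ny, nx = true_phase.shape
    y = np.arange(ny)[:, None] * pixel
    x = np.arange(nx)[None, :] * pixel
    # Reference tilt sign chosen so the object-bearing O R* term sits at
    # +carrier, i.e. in the upper half-plane picked by the reconstructor.
    ref = np.exp(-2j * np.pi * (carrier[0] * x + carrier[1] * y))
    intensity = np.abs(obj + ref) ** 2
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(
            0.0, noise_sigma * intensity.mean(), intensity.shape
        )
        intensity = np.clip(intensity, 0.0, None)
    return Hologram(
        intensity=intensity, pixel_um=pixel, config=config, timestamp_min=timestamp_min
    )


def render_timeseries(
    volumes_um3: Sequence[float],
    kind: str,
    config: OpticalConfig,
    grid_shape: Tuple[int, int] = (1024, 1024),
    interval_min: float = 10.0,
    times_min: Optional[Sequence[float]] = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
) -> List[Tuple[Hologram, GroundTruth]]:
    """Render one hologram per volume; ground truths preserve input order."""
    if len(volumes_um3) == 0:
        raise ValueError("volumes_um3 must be non-empty")
    if any(v <= 0 for v in volumes_um3):
        raise ValueError("all volumes must be positive")
    if times_min is None:
        times_min = [i * interval_min for i in range(len(volumes_um3))]
    if len(times_min) != len(volumes_um3):
        raise ValueError("times_min length must match volumes_um3")
    carrier = default_carrier(config)
    ss = np.random.SeedSequence(seed)
    frame_seeds = [int(s) % (2**31) for s in ss.generate_state(len(volumes_um3))]
    out = []
    for v, t_min, fseed in zip(volumes_um3, times_min, frame_seeds):
        spec = PhantomSpec(kind=kind, target_volume_um3=float(v), seed=fseed)
        gt = make_phantom(spec, grid_shape, config)
        phase = thickness_to_phase(gt, config)
        holo = render_hologram(
            phase,
            carrier,
            config,
            noise_sigma=noise_sigma,
            seed=fseed,
            timestamp_min=float(t_min),
        )
        gt.carrier_cycles_per_um = carrier
        out.append((holo, gt))
    return out
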