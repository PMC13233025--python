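"""Complex-field recovery from off-axis holograms.

The recorded intensity I = |O + R|^2 carries the object wave O on a
spatial-frequency carrier set by the reference tilt. Reconstruction is:
Fourier transform, locate the +1-order sideband, low-pass filter around it
and recenter (demodulate), inverse transform, then numerically refocus by
angular-spectrum propagation, with the reconstruction distance found
automatically from the spectral flatness of the amplitude image.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .fields import ComplexField, Hologram, Spectrum

logger = logging.getLogger(__name__)


class SidebandError(RuntimeError):
    """No off-axis sideband could be located in the spectrum."""


def fourier_spectrum(holo: Hologram) -> Spectrum:
    """DC-centered 2-D Fourier spectrum of the hologram intensity."""
    data = np.fft.fftshift(np.fft.fft2(holo.intensity))
    ny, nx = holo.intensity.shape
    dfy = 1.0 / (ny * holo.pixel_um)
    dfx = 1.0 / (nx * holo.pixel_um)
    return Spectrum(
        data=data,
        freq_step_per_um=(dfy, dfx),
        source_shape=(ny, nx),
        pixel_um=holo.pixel_um,
        config=holo.config,
    )


def _freq_grids(spec: Spectrum) -> Tuple[np.ndarray, np.ndarray]:
    ny, nx = spec.source_shape
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=spec.pixel_um))
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=spec.pixel_um))
    return np.meshgrid(fx, fy)


def locate_sideband(
    spec: Spectrum, dc_exclusion_frac: float = 0.1
) -> Tuple[float, float]:
    """Locate the +1-order sideband peak, in cycles/um, as (fx, fy).

    Searches the magnitude-maximal bin outside a DC exclusion disk of radius
    ``dc_exclusion_frac`` x Nyquist, restricted to the upper half-plane
    (fy > 0, or fy = 0 and fx > 0); the +-1 orders are conjugate-symmetric so
    one deterministic representative suffices.
    """
    fxx, fyy = _freq_grids(spec)
    mag = np.abs(spec.data)
    r_excl = dc_exclusion_frac * spec.nyquist_per_um
    allowed = (np.hypot(fxx, fyy) > r_excl) & (
        (fyy > 0) | ((fyy == 0) & (fxx > 0))
    )
    if not allowed.any():
        raise SidebandError("DC exclusion removes the whole half-plane")
    vals = np.where(allowed, mag, -1.0)
    idx = np.unravel_index(np.argmax(vals), vals.shape)
    peak = mag[idx]
    floor = np.median(mag[allowed])
    if peak <= 3.0 * floor:
        raise SidebandError(
            f"no sideband found: peak {peak:.3g} below 3x median floor {floor:.3g}"
        )
    return float(fxx[idx]), float(fyy[idx])


def filter_plus_one(
    spec: Spectrum,
    center: Tuple[float, float],
    radius_frac: float = 0.5,
    dc_exclusion_frac: float = 0.1,
) -> ComplexField:
    """Isolate and demodulate the +1 order; returns the field at distance 0.

    A circular low-pass mask (hard disk with a 3-bin raised-cosine rim) is
    applied about ``center``; the spectrum is then rolled by an integer
    number of bins so the carrier maps to zero frequency, and inverse
    transformed.
    """
    fx_c, fy_c = center
    dfy, dfx = spec.freq_step_per_um
    rho = float(np.hypot(fx_c, fy_c))
    if rho == 0:
        raise ValueError("sideband center cannot be at DC")
    radius = radius_frac * rho
    df = max(dfx, dfy)
    if radius < df:
        raise ValueError(
            f"filter radius {radius:.4g} cycles/um is below one frequency bin {df:.4g}"
        )
    r_excl = dc_exclusion_frac * spec.nyquist_per_um
    max_radius = rho - r_excl
    if radius > max_radius:
        raise ValueError(
            f"filter radius {radius:.4g} cycles/um overlaps the DC exclusion disk; "
            f"maximum admissible radius is {max_radius:.4g} cycles/um"
        )
    fxx, fyy = _freq_grids(spec)
    dist = np.hypot(fxx - fx_c, fyy - fy_c)
    taper = 3.0 * df
    t = np.clip((radius - dist) / taper, 0.0, 1.0)
    mask = 0.5 - 0.5 * np.cos(np.pi * t)
    filtered = spec.data * mask
    shift_x = int(round(fx_c / dfx))
    shift_y = int(round(fy_c / dfy))
    recentred = np.roll(filtered, (-shift_y, -shift_x), axis=(0, 1))
    field = np.fft.ifft2(np.fft.ifftshift(recentred))
    return ComplexField(
        data=field, pixel_um=spec.pixel_um, distance_um=0.0, config=spec.config
    )


def angular_spectrum_propagate(field: ComplexField, d_um: float) -> ComplexField:
    """Propagate a complex field by a signed distance (angular spectrum method).

    The spectrum is multiplied by exp(i 2 pi d/lambda sqrt(1 - (lambda fx)^2
    - (lambda fy)^2)); evanescent components (negative radicand) are zeroed.
    d = 0 is an exact identity.
    """
    if not np.all(np.isfinite(field.data)):
        raise ValueError("field contains non-finite values")
    if d_um == 0.0:
        return field.copy_with(data=field.data.copy())
    lam = field.config.wavelength_um
    ny, nx = field.data.shape
    fy = np.fft.fftfreq(ny, d=field.pixel_um)[:, None]
    fx = np.fft.fftfreq(nx, d=field.pixel_um)[None, :]
    radicand = 1.0 - (lam * fx) ** 2 - (lam * fy) ** 2
    kz = np.sqrt(np.clip(radicand, 0.0, None))
    transfer = np.where(radicand > 0, np.exp(2j * np.pi * d_um / lam * kz), 0.0)
    out = np.fft.ifft2(np.fft.fft2(field.data) * transfer)
    return field.copy_with(data=out, distance_um=field.distance_um + d_um)


def sharpness_metric(field: ComplexField) -> float:
    """Spectral energy of the amplitude image outside the DC bin, normalized.

    For a phase object the amplitude image is maximally flat at focus, so
    this metric attains a minimum at the correct reconstruction distance;
    defocus converts phase relief into amplitude contrast and raises it.
    """
    amp = np.abs(field.data)
    spec = np.fft.fft2(amp)
    total = float(np.sum(np.abs(spec) ** 2))
    if total == 0:
        return 0.0
    dc = float(np.abs(spec[0, 0]) ** 2)
    return 1.0 - dc / total


def autofocus(
    field: ComplexField,
    d_range: Tuple[float, float],
    step: float,
    refine: bool = True,
) -> float:
    """Best reconstruction distance by coarse scan + bounded golden refine.

    Scans ``d_range`` at ``step`` and minimizes :func:`sharpness_metric`;
    a flat (object-free) field gives a constant metric, in which case the
    range minimum is returned with a warning.
    """
    d_min, d_max = d_range
    if step <= 0:
        raise ValueError("step must be positive")
    if d_max < d_min:
        raise ValueError("empty focus range")
    distances = np.arange(d_min, d_max + step / 2, step)
    if distances.size == 0:
        raise ValueError("empty focus range")
    scores = np.array([sharpness_metric(angular_spectrum_propagate(field, d)) for d in distances])
    if np.ptp(scores) < 1e-12:
        logger.warning("autofocus metric is constant; returning range minimum")
        return float(distances[0])
    best = int(np.argmin(scores))
    d_best = float(distances[best])
    if refine:
        lo = max(d_min, d_best - step)
        hi = min(d_max, d_best + step)
        res = minimize_scalar(
            lambda d: sharpness_metric(angular_spectrum_propagate(field, float(d))),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": step * 1e-3},
        )
        if res.fun <= scores[best]:
            d_best = float(res.x)
    return d_best


def extract_amplitude_phase(field: ComplexField) -> Tuple[np.ndarray, np.ndarray]:
    """Intensity |U|^2 and wrapped phase arctan(Im U / Re U) in (-pi, pi]."""
    intensity = np.abs(field.data) ** 2
    phase = np.angle(field.data)
    return intensity, phase
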