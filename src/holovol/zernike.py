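"""Zernike-polynomial background modeling and phase flattening.

Smooth optical aberrations of the imaging train (tilt, defocus,
astigmatism, coma, spherical) are modeled as a Zernike expansion over the
raster's inscribed unit disk, least-squares fitted on background pixels
and subtracted; residual slowly-varying background is then estimated with
a wide median filter (object pixels in-painted from the nearest
background) and subtracted, yielding a flat-background continuous phase.

Conventions (fixed for coefficient reproducibility):

* single-index OSA/ANSI ordering ``j = (n(n+2) + m) / 2``;
* unit-amplitude (unnormalized) convention — |Z| <= 1 on the unit disk, so
  a coefficient in radians is that aberration's peak phase contribution;
  cosine terms for ``m > 0``, sine for ``m < 0``;
* the unit disk is the inscribed disk of the raster; corner pixels (r > 1)
  are evaluated with the same polynomials so fits and surfaces are defined
  on the full raster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil, factorial, sqrt
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .fields import PhaseMap

logger = logging.getLogger(__name__)


class InsufficientBackgroundError(ValueError):
    """Too few background pixels remain to constrain the background fit."""


def osa_index_to_nm(j: int) -> Tuple[int, int]:
    """Map OSA/ANSI single index j to (radial order n, azimuthal frequency m)."""
    if j < 0:
        raise ValueError("index must be non-negative")
    n = int(ceil((-3 + sqrt(9 + 8 * j)) / 2))
    m = 2 * j - n * (n + 2)
    return n, m


def n_terms(order: int) -> int:
    """Number of Zernike terms up to radial order ``order`` inclusive."""
    return (order + 1) * (order + 2) // 2


def _radial(n: int, m: int, r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    m = abs(m)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        )
        out += c * r ** (n - 2 * k)
    return out


def unit_disk_coords(shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Raster coordinates normalized by the inscribed-disk radius."""
    ny, nx = shape
    radius = (min(ny, nx) - 1) / 2.0
    y = (np.arange(ny) - (ny - 1) / 2.0) / radius
    x = (np.arange(nx) - (nx - 1) / 2.0) / radius
    return np.meshgrid(x, y)


def zernike_basis(order: int, shape: Tuple[int, int]) -> np.ndarray:
    """Stack of Zernike rasters, OSA-ordered, shape (n_terms, ny, nx)."""
    if order < 0:
        raise ValueError("order must be non-negative")
    xx, yy = unit_disk_coords(shape)
    r = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    terms = []
    for j in range(n_terms(order)):
        n, m = osa_index_to_nm(j)
        rad = _radial(n, m, r)
        if m > 0:
            terms.append(rad * np.cos(m * theta))
        elif m < 0:
            terms.append(rad * np.sin(-m * theta))
        else:
            terms.append(rad)
    return np.stack(terms)


def zernike_surface(coeffs: Sequence[float], shape: Tuple[int, int]) -> np.ndarray:
    """Evaluate a coefficient vector as a full-raster background surface."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    order = 0
    while n_terms(order) < coeffs.size:
        order += 1
    if n_terms(order) != coeffs.size:
        raise ValueError(
            f"coefficient count {coeffs.size} does not complete a radial order"
        )
    basis = zernike_basis(order, shape)
    return np.tensordot(coeffs, basis, axes=1)


@dataclass
class ZernikeFit:
    """Least-squares Zernike background fit over non-excluded pixels."""

    coeffs: np.ndarray
    order: int
    shape: Tuple[int, int]
    rms_residual: float

    def surface(self) -> np.ndarray:
        return zernike_surface(self.coeffs, self.shape)


def default_object_mask(
    data: np.ndarray, dilate_px: int = 5, n_iter: int = 3
) -> np.ndarray:
    """Automatic object-pixel mask: above background median + 3*MAD, dilated.

    The median/MAD threshold is re-estimated over the remaining background
    pixels for a few rounds: a cell occupying a large share of the field
    pollutes whole-raster statistics and would otherwise leave its faint
    slopes unmasked. The detected support is then dilated adaptively — by a
    fraction of the object's own diameter, at least ``dilate_px`` — because
    a smooth cell's sub-threshold skirt scales with the cell size and must
    be excluded from background estimation.
    """
    bg = np.ones(data.shape, dtype=bool)
    mask = ~bg
    # Threshold floor at 1% of the peak relief: on near-noiseless data the
    # MAD collapses to the numerical-ripple level and would mask everything.
    # Cap at half the peak relief: a large object inflates the MAD and could
    # otherwise push the threshold past the brightest structure entirely.
    relief = data.max() - np.median(data)
    floor, cap = 0.01 * relief, 0.5 * relief
    for _ in range(n_iter):
        med = np.median(data[bg])
        mad = np.median(np.abs(data[bg] - med))
        new = data > med + min(max(3 * mad, floor), cap)
        if new.sum() == mask.sum() or new.mean() > 0.9:
            mask = new if new.mean() <= 0.9 else mask
            break
        mask = new
        bg = ~mask
    if mask.any():
        mask = ndimage.binary_fill_holes(mask)
        labels, n = ndimage.label(mask)
        areas = np.bincount(labels.ravel())[1:]
        out = (
            ndimage.distance_transform_edt(~mask) <= dilate_px
            if dilate_px > 0
            else mask.copy()
        )
        # grow sizeable components by 15% of their own diameter; tiny noise
        # specks keep the base dilation only
        for comp_id in np.flatnonzero(areas >= 1000) + 1:
            grow = int(round(0.15 * np.sqrt(areas[comp_id - 1])))
            if grow > dilate_px:
                comp = labels == comp_id
                out |= ndimage.distance_transform_edt(~comp) <= grow
        mask = out
    return mask


def quantile_background_surface(
    data: np.ndarray,
    order: int = 4,
    tau: float = 0.1,
    stride: int = 2,
    n_iter: int = 30,
    exclude_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Lower-envelope Zernike surface by quantile regression (IRLS).

    Cells add strictly positive phase relief, so the background is the lower
    envelope of the map: fitting the ``tau`` quantile instead of the mean
    keeps the surface pinned to the background even when the object is a
    large, centered bump that an ordinary least-squares fit would absorb.
    Pixels above half the peak relief are dropped outright (they are object
    beyond doubt), and the IRLS weights are Huberized at a fraction of the
    data's robust scale so the iteration cannot degenerate into
    interpolating tall structures. Used only to expose the object for
    masking; the reported background fit is always the least-squares
    :func:`fit_zernike_background`.
    """
    basis = zernike_basis(order, data.shape)
    a = basis[:, ::stride, ::stride].reshape(basis.shape[0], -1).T
    y = data[::stride, ::stride].ravel()
    med = np.median(y)
    keep = y <= med + 0.5 * (y.max() - med)
    if exclude_mask is not None:
        keep &= ~np.asarray(exclude_mask, bool)[::stride, ::stride].ravel()
    if keep.sum() < 10 * a.shape[1]:
        keep = np.ones(y.size, bool)
    a, y = a[keep], y[keep]
    scale = np.median(np.abs(y - np.median(y))) + 1e-12
    eps = 0.05 * scale
    coeffs, *_ = np.linalg.lstsq(a, y, rcond=None)
    for _ in range(n_iter):
        r = y - a @ coeffs
        w = np.where(r >= 0, tau, 1.0 - tau) / np.maximum(np.abs(r), eps)
        aw = a * w[:, None]
        coeffs = np.linalg.solve(a.T @ aw, aw.T @ y)
    return zernike_surface(coeffs, data.shape)


def fit_zernike_background(
    phase: PhaseMap,
    exclude_mask: Optional[np.ndarray] = None,
    order: int = 4,
) -> ZernikeFit:
    """Fit Zernike terms up to ``order`` on pixels outside ``exclude_mask``."""
    phase.require_state("unwrapped")
    data = phase.data
    if exclude_mask is None:
        exclude_mask = np.zeros(data.shape, dtype=bool)
    exclude_mask = np.asarray(exclude_mask, dtype=bool)
    if exclude_mask.shape != data.shape:
        raise ValueError("exclude_mask shape mismatch")
    frac_excluded = exclude_mask.mean()
    if frac_excluded >= 0.8:
        raise InsufficientBackgroundError(
            f"{frac_excluded:.0%} of pixels excluded; need < 80% for a background fit"
        )
    basis = zernike_basis(order, data.shape)
    keep = ~exclude_mask
    a = basis[:, keep].T
    coeffs, *_ = np.linalg.lstsq(a, data[keep], rcond=None)
    resid = data[keep] - a @ coeffs
    return ZernikeFit(
        coeffs=coeffs,
        order=order,
        shape=data.shape,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def _median_background(
    data: np.ndarray, object_mask: np.ndarray, kernel_px: int
) -> np.ndarray:
    """Wide-kernel median background with object pixels in-painted.

    Object pixels are replaced by the value of the nearest background pixel
    before filtering so the cell does not bleed into its own background
    estimate. The median is evaluated on a decimated grid (the background is
    smooth at the kernel scale by construction) and bilinearly resized back.
    """
    if kernel_px > min(data.shape):
        raise ValueError(
            f"median kernel {kernel_px} px exceeds raster size {min(data.shape)} px"
        )
    filled = data
    if object_mask.any():
        if object_mask.all():
            raise InsufficientBackgroundError("no background pixels to in-paint from")
        iy, ix = ndimage.distance_transform_edt(
            object_mask, return_distances=False, return_indices=True
        )
        filled = data[iy, ix]
    stride = max(1, kernel_px // 9)
    small = filled[::stride, ::stride]
    ksmall = max(3, (kernel_px // stride) | 1)
    med = ndimage.median_filter(small, size=ksmall, mode="nearest")
    if stride == 1:
        return med
    return resize(med, data.shape, order=1, mode="edge", anti_aliasing=False)


def _compensate_once(
    phase: PhaseMap,
    exclude_mask: np.ndarray,
    order: int,
    median_kernel_px: int,
    fit: Optional[ZernikeFit] = None,
) -> PhaseMap:
    data = phase.data
    if fit is None:
        fit = fit_zernike_background(phase, exclude_mask=exclude_mask, order=order)
    flat = data - fit.surface()
    flat = flat - _median_background(flat, exclude_mask, median_kernel_px)
    background = ~exclude_mask
    if background.any():
        flat = flat - np.median(flat[background])
    return PhaseMap(data=flat, state="compensated", pixel_um=phase.pixel_um)


def compensate_background(
    phase: PhaseMap,
    exclude_mask: Optional[np.ndarray] = None,
    order: int = 4,
    median_kernel_px: int = 51,
    fit: Optional[ZernikeFit] = None,
) -> PhaseMap:
    """Flatten an unwrapped phase map: Zernike global + median local removal.

    Returns a ``compensated`` phase map whose background sits at zero; the
    object's phase relief relative to the adjacent background is preserved.

    When no exclusion mask is given, the object support is found
    automatically in two rounds: first against a robust lower-envelope
    (quantile) Zernike surface — a strong aberration background hides the
    object from a raw median+MAD threshold, and an unexcluded least-squares
    pre-fit absorbs large centered cells — then the mask is refined against
    the first-pass compensated map, whose flat background exposes the faint
    object rim that would otherwise bias the in-painted median background.
    """
    phase.require_state("unwrapped")
    if median_kernel_px < 1:
        raise ValueError("median_kernel_px must be >= 1")
    data = phase.data
    if exclude_mask is not None:
        return _compensate_once(
            phase, np.asarray(exclude_mask, bool), order, median_kernel_px, fit=fit
        )
    pre = quantile_background_surface(data, order=order)
    mask = default_object_mask(data - pre)
    result = _compensate_once(phase, mask, order, median_kernel_px, fit=fit)
    for _ in range(3):
        refined = default_object_mask(result.data) | mask
        if refined.mean() >= 0.8:  # refinement ate the background; stop
            break
        if refined.sum() == mask.sum():
            break
        mask = refined
        result = _compensate_once(phase, mask, order, median_kernel_px)
    return result
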