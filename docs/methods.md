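# Methods

This note records the physical model, the parameter defaults, and the
numerical design choices behind `holovol`, in the spirit of a methods
section: what the code assumes, what its synthetic data does and does not
emulate, and where genuinely open design questions were settled.

## Imaging model and units

All rasters live in the object plane. The sampling is
`camera_pixel_um / magnification` (default 3.45 / 60 = 0.0575 µm/px); the
vacuum wavelength (default 0.633 µm) and the refractive-index contrast
`n_object − n_medium` govern the phase-to-thickness conversion
h = λ·Δθ / (2π·Δn). Two standard configurations appear throughout:
silica microspheres (n = 1.46) in PBS (n = 1.34, contrast 0.12) and
cells (n = 1.38) in culture medium (n = 1.33, contrast 0.05). Because a
single wavelength cannot separate refractive index from thickness, all
reported volumes are *effective optical volumes* under the assumed
constant intracellular index; no dry-mass or tomographic decoupling is
attempted.

## Synthetic holograms

The simulator renders I = |O + R|² for a pure phase object
O = exp(i·Δθ) and a unit-amplitude plane reference R. Conventions and
defaults:

- **Reference tilt sign.** R = exp(−i2π(f_x x + f_y y)), so the
  object-bearing O·R* sideband sits at +carrier, in the upper half-plane
  that the sideband locator deterministically prefers. The recorded
  intensity is identical under conjugation; fixing the sign fixes which
  demodulated field carries +θ rather than −θ.
- **Carrier.** Default (f_s/8, f_s/8) with f_s the sampling frequency —
  far enough from DC for a 0.5-radius filter, low enough to stay well
  under the Nyquist/2 separability bound, and an exact FFT bin on grids
  divisible by 8 so demodulation by integer spectral shift is exact.
- **Beam ratio.** Object and reference amplitudes are equal (fringe
  contrast ≈ 1); no interferometer aligns worse than its simulation needs.
- **Noise.** Additive Gaussian intensity noise, σ relative to the mean
  intensity, default 0.01; seeded and bit-reproducible. No quantization,
  shot-noise statistics, or fixed-pattern noise is modeled.
- **Defocus.** A defocus of d µm back-propagates the object field by −d,
  so d is exactly the reconstruction distance that refocuses it.
- **Aberrations.** A Zernike phase screen multiplied onto the object wave
  at the detector plane (see conventions below).

Phantoms are thickness maps with analytically known volume: the sphere's
chord profile 2√(r₀²−r²); a spherical cap with height = 0.8 × base radius
(a plausibly rounded adherent cell); and a flattened super-Gaussian
"pancake" body (default height 6 µm) with five tapered radial ridges
(pseudopodia) placed with seeded angular and length jitter, protruding to
1.2× the body radius. Cap and pancake maps are rescaled so the *rendered*
map integrates exactly to the requested volume. Every thickness map gets
a Gaussian edge blur (σ = 2 px) before phase conversion — a hard sphere
edge has unbounded phase gradient and would alias — and the ground-truth
volume is integrated *after* blurring, so the oracle is exact for the
object actually rendered (Gaussian blurring conserves the integral; for
the 10 µm sphere the blurred Riemann sum still matches 4πr³/3 = 523.60 µm³
within 0.5%, with ~0.2% typical). Phantoms must fit their grid with a 10%
margin per side; violations raise with the required grid size.

What the simulator does **not** emulate: partial coherence, the NA-limited
pupil (the real objective is NA 0.75), speckle from out-of-plane
scatterers, camera bit depth, mechanical drift, or multiple cells with
contact — so passing tests demonstrate the numerical chain is unbiased
and stable under its stated model, not that every physical artifact of a
real instrument is handled.

## Reconstruction

Sideband location takes the magnitude-maximal bin outside a DC exclusion
disk (default 10% of Nyquist), restricted to the upper half-plane; an
error is raised when no bin exceeds 3× the median magnitude there. The +1
order is isolated by a hard circular mask of radius 0.5× the DC–sideband
distance with a 3-bin raised-cosine rim (suppresses ringing), then
demodulated by rolling the carrier bin to DC — exactly invertible on the
grid, equivalent to multiplying by an ideal digital reference.

The angular spectrum propagator zeroes evanescent components
((λf)² > 1) rather than letting them blow up; d = 0 is special-cased to
the exact identity. On the propagating band the transfer function is
unitary, so energy is conserved and propagate(d₁)∘propagate(d₂) =
propagate(d₁+d₂) to rounding.

**Autofocus.** The focus metric is the fraction of the amplitude image's
spectral energy outside the DC bin (equivalently its normalized
variance), scanned over the requested range and *minimized*, then refined
by bounded golden-section search within ± one step. For a phase object
the amplitude is maximally flat at focus and defocus converts phase
gradients into amplitude contrast monotonically near focus, so the
minimum marks the reconstruction distance; a metric that instead
maximizes high-frequency amplitude energy diverges to the scan edges on
phase objects. Validated against simulator ground truth: defocus drawn
uniformly in ±100 µm is recovered to well under one 5 µm scan step in
10/10 seeded runs. A featureless field has a constant metric; the range
minimum is returned with a warning.

## Phase processing

Unwrapping is quality-guided: quality = 1/(1 + local 3×3 variance of the
wrapped phase gradients), flood fill from the global quality maximum
(lexicographic tie-break) through a max-priority queue, each pixel offset
by the 2πk nearest its already-unwrapped neighbor. The output is congruent
to the input modulo 2π at every pixel by construction; the inner loop is
numba-compiled (a binary heap over ~10⁶ pixels).

Background flattening subtracts a least-squares Zernike surface (OSA/ANSI
single-index ordering, radial orders ≤ 4 = 15 terms, fit over the
raster's inscribed unit disk with corner pixels evaluated by the same
polynomials) and then a residual background estimated as a wide-kernel
median (default 51 px ≈ 2.9 µm) of the Zernike-subtracted map with object
pixels in-painted from their nearest background neighbor. Numerical
choices:

- **Zernike normalization** is the classical unit-amplitude convention
  (|Z| ≤ 1 on the disk), so a coefficient in radians is that aberration's
  peak phase contribution; simulator and fit share the basis, making
  coefficient recovery exact on clean data. Random backgrounds with
  coefficients U(−3, 3) over all 15 terms span roughly ±10 rad across the
  field — strong but resolvable aberrations whose local fringe
  displacement stays inside the sideband filter's passband.
- **Automatic object exclusion** is the delicate step: an unexcluded
  least-squares fit absorbs a large centered cell almost entirely (a cap
  is nearly a defocus+spherical combination), and a raw median+MAD
  threshold cannot see the object under a strong aberration background.
  The object is therefore exposed against a robust *lower-envelope*
  surface — quantile regression (τ = 0.1, IRLS with Huberized weights,
  pixels above half the peak relief dropped outright) — thresholded at
  background median + max(3·MAD, 1% of peak relief), capped at half the
  peak relief, with the median/MAD re-estimated over background-only
  pixels for three rounds. Detected components are dilated by 15% of
  their own diameter (at least 5 px): a smooth cell's sub-threshold skirt
  scales with the cell, and any skirt left in the "background" biases the
  in-painted median under the whole cell. The mask is then refined up to
  three times against the compensated map, whose flat background exposes
  the faint rim. With this scheme the compensated background rms sits at
  the noise floor and the object's integrated phase is preserved to ~1%.
- **Median on a decimated grid.** The 51-px median is evaluated with
  stride `kernel//9` and a proportionally reduced kernel, then bilinearly
  resized back: the background is smooth at kernel scale by construction
  and the exact large-kernel median is needlessly expensive.
- The median filter is applied to a *background estimate* which is then
  subtracted, not to the phase map itself; filtering the map directly
  would erode the object it is meant to preserve.

Compensation is idempotent to < 0.01 rad rms, and the Zernike fit's rms
residual is non-increasing in fit order.

## Segmentation and morphometry

The thickness map is dual-thresholded: seed = 50% of the maximum
thickness (the cell's thick core), boundary = background median + 3·MAD
(the noise floor; falls back to 1% of peak on noise-free data). Boundary
components not touched by a seed are discarded (morphological
reconstruction), then area opening (64 px) removes specks and a disk
closing (radius 5 px) fills micro-holes. Connectivity is 8-connected
throughout to keep diagonal pseudopodia attached. Touching-cell splitting
is deliberately out of scope; fields are assumed single-cell or
well-separated, and each surviving component is reported separately.

Volume is a plain Riemann sum, pixel-area × Σh over each component
(edge effects < 0.5% at the ≥100 px object diameters used here); negative
compensated phase clips to zero thickness with a logged count.
Circularity = 4πA/P² with the Crofton perimeter (4 directions) — the
pixel-edge perimeter overestimates round objects by ~8%, and cells are
round; the flip side is that axis-aligned squares read ~0.88 rather than
π/4. Sphericity is Wadell's π^(1/3)(6V)^(2/3)/A_surf with the surface
area integrated from the thickness relief (√(1+|∇h|²) over the footprint)
plus the base plane. Components under 16 px get NaN descriptors.

Time series are tracked by nearest-centroid association within 10 µm
(ambiguity raises, listing candidates; a lost track truncates with a
warning). Interval slopes ΔV/Δt are staged *slow*/*rapid* by comparing
|slope| against 1.5× the series' median |slope| — the magnitude form
behaves identically to a signed rule on monotone-increasing series and
remains meaningful on decreasing ones — and slope sign changes mark
troughs and peaks (e.g. a division spike before decline). Per-frame
totals over all components are reported alongside the tracked cell.

## Problem sizes and performance

Validation studies run on 1024² rasters at 0.0575 µm/px (a 59 µm field):
microsphere and phenotype recoveries, and the six-frame death plus
four-frame division series; module-level tests use 256²–512² grids. One
full pipeline pass on a 1024² hologram takes a few seconds on one CPU
(the unwrapper dominates before numba's first-call compilation is
amortized). The headline recoveries land within 0.2% of ground truth,
comfortably inside the 5% acceptance band chosen to absorb the edge-blur
convention and default noise.

## Known limitations

- Sideband filtering band-limits the field to half the carrier distance
  (≈1.5 cycles/µm at defaults); structures steeper than that — notably
  the silica sphere's rim at contrast 0.12 — are smoothed, which is the
  main residual error on the microsphere target.
- The automatic background masking assumes cells are *positive* phase
  relief occupying well under half the field; objects spanning most of
  the raster or index-matched (near-zero contrast) cells will defeat it.
- Zernike compensation assumes the aberration is common-path and static
  per frame; no temporal aberration tracking.
- Volume accuracy inherits the constant-index assumption; mitotic
  rounding or condensation changes the effective index and inflates the
  optical volume, which is a feature for event detection but not a
  geometric measurement.
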