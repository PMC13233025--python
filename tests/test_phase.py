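"""Phase processing: quality map, unwrapping, Zernike/median flattening."""

import numpy as np
import pytest
from scipy import ndimage

import holovol as hv
from holovol.fields import PhaseMap, StateError
from holovol.zernike import (
    InsufficientBackgroundError,
    n_terms,
    osa_index_to_nm,
    zernike_surface,
)

TWO_PI = 2 * np.pi


def _wrap(a):
    return np.angle(np.exp(1j * a))


def _pm(data, px=0.0575, state="wrapped"):
    return PhaseMap(data=np.asarray(data, float), state=state, pixel_um=px)


class TestQualityMap:
    def test_constant_phase_scores_one(self):
        q = hv.quality_map(_pm(np.full((32, 32), 0.7)))
        assert np.allclose(q, 1.0)

    def test_outlier_minimizes_quality_nearby(self):
        data = np.zeros((32, 32))
        data[10, 20] = 2.0
        q = hv.quality_map(_pm(data))
        iy, ix = np.unravel_index(np.argmin(q), q.shape)
        assert abs(iy - 10) <= 1 and abs(ix - 20) <= 1

    def test_linear_ramp_scores_one_off_seam(self):
        # wrapped gradients of a ramp are constant, so variance is zero
        x = np.arange(64)[None, :] * 0.4
        q = hv.quality_map(_pm(_wrap(x * np.ones((64, 1)))))
        assert np.all(q <= 1.0)
        seam_cols = np.unique(np.argwhere(np.abs(np.diff(_wrap(x[0]))) > np.pi))
        off_seam = np.ones(64, bool)
        off_seam[:2] = off_seam[-2:] = False  # edge-replicated gradients
        for c in seam_cols:
            off_seam[max(0, c - 2) : c + 3] = False
        assert np.allclose(q[2:-2, off_seam], 1.0)

    def test_requires_wrapped_state(self):
        with pytest.raises(StateError):
            hv.quality_map(_pm(np.zeros((8, 8)), state="unwrapped"))


class TestUnwrap:
    def test_congruence_mod_two_pi(self, cap_gt, cell_config):
        phase = hv.thickness_to_phase(cap_gt, cell_config)
        rng = np.random.default_rng(0)
        noisy = phase + 0.05 * rng.standard_normal(phase.shape)
        wrapped = _wrap(noisy)
        out = hv.unwrap_quality_guided(_pm(wrapped))
        k = (out.data - wrapped) / TWO_PI
        assert np.abs(k - np.rint(k)).max() < 1e-9

    def test_sphere_phase_recovered(self, sphere_gt, silica_config):
        """The 11.91 rad sphere peak survives wrap/unwrap to < 0.05 rad."""
        phase = hv.thickness_to_phase(sphere_gt, silica_config)
        out = hv.unwrap_quality_guided(_pm(_wrap(phase)))
        offset = TWO_PI * np.rint(np.median(out.data - phase) / TWO_PI)
        assert np.abs(out.data - offset - phase).max() < 0.05

    def test_smooth_in_range_input_unchanged(self):
        y = np.linspace(0, 1, 32)[:, None]
        data = 0.8 * np.sin(2 * np.pi * y) * np.ones((1, 32))
        out = hv.unwrap_quality_guided(_pm(data))
        assert np.allclose(out.data, data, atol=1e-12)

    def test_output_state_is_unwrapped(self):
        out = hv.unwrap_quality_guided(_pm(np.zeros((8, 8))))
        assert out.state == "unwrapped"
        with pytest.raises(StateError):
            hv.unwrap_quality_guided(out)


class TestZernikeBasis:
    def test_osa_single_index_mapping(self):
        assert [osa_index_to_nm(j) for j in range(6)] == [
            (0, 0), (1, -1), (1, 1), (2, -2), (2, 0), (2, 2),
        ]

    def test_term_count(self):
        assert n_terms(4) == 15

    def test_surface_round_trip(self):
        coeffs = np.arange(1.0, 16.0)
        surf = zernike_surface(coeffs, (64, 64))
        fit = hv.fit_zernike_background(_pm(surf, state="unwrapped"), order=4)
        assert np.allclose(fit.coeffs, coeffs, atol=1e-8)
        assert fit.rms_residual < 1e-8

    def test_incomplete_coefficient_vector_rejected(self):
        with pytest.raises(ValueError, match="radial order"):
            zernike_surface(np.ones(7), (32, 32))


class TestFitZernikeBackground:
    def test_pure_tilt_recovers_only_tilt_terms(self):
        xx, yy = np.meshgrid(np.linspace(-1, 1, 64), np.linspace(-1, 1, 64))
        fit = hv.fit_zernike_background(_pm(1.7 * xx, state="unwrapped"), order=4)
        tilt = abs(fit.coeffs[2])  # OSA j=2 is the x tilt
        others = np.delete(np.abs(fit.coeffs), 2)
        assert tilt > 0
        assert others.max() < 1e-8 * tilt
        assert fit.rms_residual < 1e-8

    def test_zero_phase_gives_zero_coeffs(self):
        fit = hv.fit_zernike_background(_pm(np.zeros((32, 32)), state="unwrapped"))
        assert np.abs(fit.coeffs).max() < 1e-10

    def test_defocus_coefficient_recovered(self):
        coeffs = np.zeros(15)
        coeffs[4] = 2.0  # OSA j=4: defocus
        surf = zernike_surface(coeffs, (96, 96))
        fit = hv.fit_zernike_background(_pm(surf, state="unwrapped"), order=4)
        assert fit.coeffs[4] == pytest.approx(2.0, abs=1e-6)

    def test_rms_residual_matches_reconstruction(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((48, 48))
        fit = hv.fit_zernike_background(_pm(data, state="unwrapped"), order=3)
        resid = data - fit.surface()
        assert np.sqrt(np.mean(resid**2)) == pytest.approx(fit.rms_residual, rel=1e-9)

    def test_order_monotonicity(self):
        rng = np.random.default_rng(6)
        data = ndimage.gaussian_filter(rng.standard_normal((64, 64)), 8)
        rms = [
            hv.fit_zernike_background(_pm(data, state="unwrapped"), order=o).rms_residual
            for o in range(6)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rms, rms[1:]))

    def test_insufficient_background_rejected(self):
        mask = np.ones((32, 32), bool)
        mask[:2] = False
        with pytest.raises(InsufficientBackgroundError):
            hv.fit_zernike_background(
                _pm(np.zeros((32, 32)), state="unwrapped"), exclude_mask=mask
            )


class TestCompensateBackground:
    def test_flat_field_plus_aberration_flattened(self):
        coeffs = np.linspace(-1.5, 1.5, 15)
        surf = zernike_surface(coeffs, (128, 128))
        comp = hv.compensate_background(_pm(surf, state="unwrapped"))
        assert np.sqrt(np.mean(comp.data**2)) < 0.02

    def test_object_phase_preserved(self, cap_gt, cell_config):
        """Compensating an aberration-free phantom changes its integrated
        phase by < 2%."""
        phase = hv.thickness_to_phase(cap_gt, cell_config)
        comp = hv.compensate_background(_pm(phase, state="unwrapped"))
        before = phase[cap_gt.mask].sum()
        after = comp.data[cap_gt.mask].sum()
        assert after == pytest.approx(before, rel=0.02)

    def test_zero_in_zero_out(self):
        comp = hv.compensate_background(_pm(np.zeros((64, 64)), state="unwrapped"))
        assert np.allclose(comp.data, 0.0, atol=1e-12)

    def test_idempotent(self, cap_gt, cell_config):
        phase = hv.thickness_to_phase(cap_gt, cell_config)
        rng = np.random.default_rng(2)
        noisy = phase + zernike_surface(rng.uniform(-2, 2, 15), phase.shape)
        once = hv.compensate_background(_pm(noisy, state="unwrapped"))
        twice = hv.compensate_background(
            PhaseMap(once.data, "unwrapped", once.pixel_um)
        )
        assert np.sqrt(np.mean((twice.data - once.data) ** 2)) < 0.01

    def test_kernel_larger_than_raster_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            hv.compensate_background(
                _pm(np.zeros((32, 32)), state="unwrapped"), median_kernel_px=51
            )

    def test_requires_unwrapped_state(self):
        with pytest.raises(StateError):
            hv.compensate_background(_pm(np.zeros((8, 8)), state="wrapped"))

    def test_random_aberrations_flattened_across_seeds(self, cap_gt, cell_config):
        """Ten seeded aberration draws (orders <= 4, coeffs U(-3,3)) all
        compensate to < 0.05 rad background rms with the object preserved."""
        phase = hv.thickness_to_phase(cap_gt, cell_config)
        bg = ~ndimage.binary_dilation(cap_gt.mask, iterations=10)
        rng = np.random.default_rng(42)
        for _ in range(10):
            coeffs = rng.uniform(-3, 3, 15)
            total = phase + zernike_surface(coeffs, phase.shape)
            wrapped = _pm(np.angle(np.exp(1j * total)))
            comp = hv.compensate_background(hv.unwrap_quality_guided(wrapped))
            assert np.sqrt(np.mean(comp.data[bg] ** 2)) < 0.05
            assert comp.data[cap_gt.mask].sum() == pytest.approx(
                phase[cap_gt.mask].sum(), rel=0.02
            )
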