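"""Fourier reconstruction: spectra, sideband filtering, propagation, focus."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import holovol as hv
from holovol.reconstruct import SidebandError, sharpness_metric


def _random_field(cell_config, shape=(128, 128), seed=0, band_frac=0.08):
    """Band-limited random complex field (no evanescent content).

    The propagating band requires lambda * f < 1, i.e. f below
    pixel_um / lambda ~ 0.091 cycles/px at 633 nm and 57.5 nm pixels.
    """
    rng = np.random.default_rng(seed)
    spec = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    spec[np.hypot(fx, fy) > band_frac] = 0
    data = np.fft.ifft2(spec)
    return hv.ComplexField(
        data=data,
        pixel_um=cell_config.object_pixel_um,
        distance_um=0.0,
        config=cell_config,
    )


class TestFourierSpectrum:
    def test_parseval(self, cell_config):
        rng = np.random.default_rng(1)
        raster = rng.random((128, 128))
        holo = hv.Hologram(raster, cell_config.object_pixel_um, cell_config)
        spec = hv.fourier_spectrum(holo)
        lhs = np.sum(raster.astype(np.float64) ** 2)
        rhs = np.sum(np.abs(spec.data) ** 2) / raster.size
        assert rhs == pytest.approx(lhs, rel=1e-9)

    def test_constant_raster_all_energy_at_dc(self, cell_config):
        holo = hv.Hologram(np.full((64, 64), 2.0), cell_config.object_pixel_um, cell_config)
        mag = np.abs(hv.fourier_spectrum(holo).data)
        dc = mag[32, 32]
        mag[32, 32] = 0
        assert dc > 0 and mag.max() < 1e-9 * dc

    def test_cosine_fringe_gives_symmetric_peaks(self, cell_config):
        px = cell_config.object_pixel_um
        n = 128
        x = np.arange(n)[None, :] * px
        f = 8 / (n * px)  # exactly 8 bins
        raster = 1.0 + 0.5 * np.cos(2 * np.pi * f * x) * np.ones((n, 1))
        holo = hv.Hologram(raster, px, cell_config)
        mag = np.abs(hv.fourier_spectrum(holo).data)
        significant = np.argwhere(mag > 1e-6 * mag.max())
        assert {tuple(p) for p in significant} == {(64, 64), (64, 72), (64, 56)}


class TestLocateSideband:
    def test_constant_image_has_no_sideband(self, cell_config):
        holo = hv.Hologram(np.ones((64, 64)), cell_config.object_pixel_um, cell_config)
        with pytest.raises(SidebandError, match="no sideband"):
            hv.locate_sideband(hv.fourier_spectrum(holo))

    def test_upper_half_plane_tiebreak(self, cell_config):
        # a real hologram has conjugate-symmetric +-1 orders; the returned
        # representative must sit in the upper half-plane
        holo = hv.render_hologram(np.zeros((128, 128)), (1.5, 1.5), cell_config)
        fx, fy = hv.locate_sideband(hv.fourier_spectrum(holo))
        assert fy > 0 or (fy == 0 and fx > 0)
        assert (fx, fy) == pytest.approx((1.5, 1.5), abs=0.14)


class TestFilterPlusOne:
    def test_flat_object_demodulates_to_zero_phase(self, cell_config):
        holo = hv.render_hologram(np.zeros((128, 128)), hv.default_carrier(cell_config), cell_config)
        spec = hv.fourier_spectrum(holo)
        field = hv.filter_plus_one(spec, hv.locate_sideband(spec))
        _, phase = hv.extract_amplitude_phase(field)
        assert np.std(phase) < 0.05

    def test_sphere_center_phase_wraps_to_truth(self, sphere_hologram, sphere_gt, silica_config):
        spec = hv.fourier_spectrum(sphere_hologram)
        field = hv.filter_plus_one(spec, hv.locate_sideband(spec))
        _, phase = hv.extract_amplitude_phase(field)
        true_peak = hv.thickness_to_phase(sphere_gt, silica_config).max()
        expected = np.angle(np.exp(1j * true_peak))
        iy, ix = np.unravel_index(np.argmax(sphere_gt.thickness_map), phase.shape)
        assert phase[iy, ix] == pytest.approx(expected, abs=0.1)

    def test_degenerate_radius_rejected(self, sphere_hologram):
        spec = hv.fourier_spectrum(sphere_hologram)
        center = hv.locate_sideband(spec)
        with pytest.raises(ValueError, match="below one frequency bin"):
            hv.filter_plus_one(spec, center, radius_frac=0.0)

    def test_radius_overlapping_dc_rejected(self, sphere_hologram):
        spec = hv.fourier_spectrum(sphere_hologram)
        center = hv.locate_sideband(spec)
        with pytest.raises(ValueError, match="maximum admissible radius"):
            hv.filter_plus_one(spec, center, radius_frac=1.5)


class TestAngularSpectrumPropagate:
    def test_zero_distance_is_identity(self, cap_field):
        out = hv.angular_spectrum_propagate(cap_field, 0.0)
        assert np.allclose(out.data, cap_field.data, rtol=0, atol=1e-12)

    def test_round_trip(self, cell_config):
        field = _random_field(cell_config, seed=2)
        back = hv.angular_spectrum_propagate(
            hv.angular_spectrum_propagate(field, 50.0), -50.0
        )
        err = np.abs(back.data - field.data).max() / np.abs(field.data).max()
        assert err < 1e-8

    def test_energy_conserved_for_bandlimited_field(self, cell_config):
        field = _random_field(cell_config, seed=3)
        out = hv.angular_spectrum_propagate(field, 73.0)
        e0 = np.sum(np.abs(field.data) ** 2)
        e1 = np.sum(np.abs(out.data) ** 2)
        assert e1 == pytest.approx(e0, rel=1e-8)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(
        d1=st.floats(-40, 40, allow_nan=False),
        d2=st.floats(-40, 40, allow_nan=False),
    )
    def test_group_property(self, cell_config, d1, d2):
        """propagate(d1) then propagate(d2) equals propagate(d1 + d2)."""
        field = _random_field(cell_config, shape=(64, 64), seed=4)
        two_step = hv.angular_spectrum_propagate(
            hv.angular_spectrum_propagate(field, d1), d2
        )
        one_step = hv.angular_spectrum_propagate(field, d1 + d2)
        assert np.allclose(two_step.data, one_step.data, atol=1e-8)

    def test_distance_bookkeeping(self, cap_field):
        out = hv.angular_spectrum_propagate(cap_field, 12.5)
        assert out.distance_um == pytest.approx(cap_field.distance_um + 12.5)


class TestAutofocus:
    def test_recovers_simulated_defocus(self, cap_gt, cell_config):
        phase = hv.thickness_to_phase(cap_gt, cell_config)
        holo = hv.render_hologram(
            phase, hv.default_carrier(cell_config), cell_config, defocus_um=30.0
        )
        spec = hv.fourier_spectrum(holo)
        field = hv.filter_plus_one(spec, hv.locate_sideband(spec))
        assert hv.autofocus(field, (0.0, 60.0), 2.0) == pytest.approx(30.0, abs=2.0)

    def test_focused_field_returns_zero(self, cap_field):
        d = hv.autofocus(cap_field, (-10.0, 10.0), 2.0)
        assert abs(d) <= 2.0

    def test_flat_field_warns_and_returns_range_min(self, cell_config, caplog):
        field = hv.ComplexField(
            data=np.ones((64, 64), complex),
            pixel_um=cell_config.object_pixel_um,
            distance_um=0.0,
            config=cell_config,
        )
        with caplog.at_level(logging.WARNING, logger="holovol.reconstruct"):
            d = hv.autofocus(field, (-5.0, 5.0), 1.0)
        assert d == -5.0
        assert any("constant" in r.message for r in caplog.records)

    def test_empty_range_rejected(self, cap_field):
        with pytest.raises(ValueError):
            hv.autofocus(cap_field, (10.0, 0.0), 1.0)
        with pytest.raises(ValueError):
            hv.autofocus(cap_field, (0.0, 10.0), -1.0)

    def test_metric_rises_with_defocus(self, cap_field):
        """Phase-object amplitude flatness degrades monotonically near focus."""
        scores = [
            sharpness_metric(hv.angular_spectrum_propagate(cap_field, d))
            for d in (0.0, 20.0, 40.0)
        ]
        assert scores[0] < scores[1] < scores[2]


class TestExtractAmplitudePhase:
    @pytest.mark.parametrize(
        "value,intensity,phase",
        [(1.0, 1.0, 0.0), (np.exp(1j * np.pi / 3), 1.0, np.pi / 3), (-1.0, 1.0, np.pi)],
    )
    def test_pointwise_values(self, cell_config, value, intensity, phase):
        field = hv.ComplexField(
            data=np.full((8, 8), value, dtype=complex),
            pixel_um=cell_config.object_pixel_um,
            distance_um=0.0,
            config=cell_config,
        )
        inten, ph = hv.extract_amplitude_phase(field)
        assert np.allclose(inten, intensity)
        assert np.allclose(ph, phase)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_phase_always_in_principal_branch(self, cell_config, seed):
        field = _random_field(cell_config, shape=(32, 32), seed=seed, band_frac=0.5)
        _, ph = hv.extract_amplitude_phase(field)
        assert ph.min() >= -np.pi and ph.max() <= np.pi
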