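"""Spectral stage: transforms vs brute-force DFT, sideband logic, propagation."""

import numpy as np
import pytest

from holorbc.config import SimulationConfig
from holorbc.reconstruct import (
    ComplexField,
    SidebandDetectionError,
    angular_spectrum_propagate,
    autofocus_distance,
    detect_sideband,
    filter_and_center,
    forward_spectrum,
    intensity_map,
    inverse_spectrum,
)
from holorbc.simulate import simulate_off_axis_hologram
from holorbc.unwrap import PhaseMap, wrapped_phase


def brute_force_dft(x):
    """O(N^4) direct evaluation of the forward transform (oracle)."""
    m, n = x.shape
    out = np.zeros((m, n), dtype=complex)
    for k in range(m):
        for l in range(n):
            acc = 0.0 + 0.0j
            for i in range(m):
                for j in range(n):
                    acc += x[i, j] * np.exp(-2j * np.pi * (k * i / m + l * j / n))
            out[k, l] = acc
    return out


def brute_force_idft(x):
    m, n = x.shape
    out = np.zeros((m, n), dtype=complex)
    for i in range(m):
        for j in range(n):
            acc = 0.0 + 0.0j
            for k in range(m):
                for l in range(n):
                    acc += x[k, l] * np.exp(2j * np.pi * (k * i / m + l * j / n))
            out[i, j] = acc / (m * n)
    return out


def make_field(values, sampling=0.05):
    return ComplexField(values=values, sampling_um_per_px=sampling, wavelength_um=0.6328)


class TestTransforms:
    def test_forward_matches_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        spec = forward_spectrum(make_field(x))
        expected = np.fft.fftshift(brute_force_dft(x))
        err = np.abs(spec.values - expected).max() / np.abs(expected).max()
        assert err < 1e-10

    def test_inverse_matches_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        spec = forward_spectrum(make_field(x))
        back = inverse_spectrum(spec)
        expected = brute_force_idft(np.fft.ifftshift(spec.values))
        err = np.abs(back.values - expected).max() / np.abs(expected).max()
        assert err < 1e-10

    def test_round_trip_identity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        back = inverse_spectrum(forward_spectrum(make_field(x)))
        err = np.abs(back.values - x).max() / np.abs(x).max()
        assert err < 1e-10

    def test_constant_field_all_energy_at_dc(self):
        spec = forward_spectrum(make_field(np.full((16, 16), 3.0 + 0j)))
        dc = spec.values[8, 8]
        assert dc == pytest.approx(3.0 * 256)  # c * N_pixels, unnormalized forward
        off_dc = np.abs(spec.values).sum() - np.abs(dc)
        assert off_dc < 1e-9 * np.abs(dc)

    def test_plane_wave_single_bin(self):
        n = 32
        x = np.arange(n)[None, :] * np.ones((n, 1))
        field = np.exp(2j * np.pi * 4 * x / n)  # on-bin frequency
        spec = forward_spectrum(make_field(field))
        mag = np.abs(spec.values)
        peak = np.unravel_index(np.argmax(mag), mag.shape)
        assert peak == (16, 16 + 4)
        assert mag.sum() == pytest.approx(mag[peak], rel=1e-9)

    def test_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        spec = forward_spectrum(make_field(x))
        field_energy = (np.abs(x) ** 2).sum()
        spec_energy = (np.abs(spec.values) ** 2).sum() / x.size
        assert spec_energy == pytest.approx(field_energy, rel=1e-10)

    def test_frequency_bin_spacing(self):
        spec = forward_spectrum(make_field(np.ones((64, 128)), sampling=0.05))
        assert spec.dfreq_x == pytest.approx(1 / (128 * 0.05))
        assert spec.dfreq_y == pytest.approx(1 / (64 * 0.05))


class TestSidebandDetection:
    def _hologram_spectrum(self, fx=-0.25, fy=0.0, n=64):
        sim = SimulationConfig(
            grid_shape=(n, n), fringe_freq_cyc_per_px=(fx, fy), noise_sigma=0.0
        )
        phase = PhaseMap(np.zeros((n, n)), "unwrapped", sim.sampling_um_per_px)
        holo = simulate_off_axis_hologram(phase, sim)
        return forward_spectrum(make_field(holo.pixels.astype(float)))

    def test_peak_on_carrier_bin(self):
        spec = self._hologram_spectrum()
        sel = detect_sideband(spec, dc_exclusion_bins=4)
        assert sel.peak_bin == (32, 32 + 16)  # positive-xi sideband of 0.25 cyc/px

    def test_constant_hologram_raises(self):
        spec = forward_spectrum(make_field(np.full((64, 64), 100.0)))
        with pytest.raises(SidebandDetectionError):
            detect_sideband(spec, dc_exclusion_bins=4)

    def test_half_plane_flip_mirrors_bin(self):
        spec = self._hologram_spectrum()
        pos = detect_sideband(spec, 4, negative_half_plane=False)
        neg = detect_sideband(spec, 4, negative_half_plane=True)
        ic, jc = spec.dc_bin
        assert neg.peak_bin == (2 * ic - pos.peak_bin[0], 2 * jc - pos.peak_bin[1])

    def test_default_mask_radius_half_distance(self):
        spec = self._hologram_spectrum()
        sel = detect_sideband(spec, 4)
        assert sel.mask_radius_bins == pytest.approx(16 / 2)


class TestFilterAndCenter:
    def test_single_bin_moves_to_dc(self):
        values = np.zeros((32, 32), dtype=complex)
        values[16, 20] = 5.0
        spec = forward_spectrum(make_field(np.ones((32, 32))))
        spec.values = values
        sel = detect_sideband(spec, dc_exclusion_bins=2)
        out = filter_and_center(spec, sel)
        assert out.values[16, 16] == pytest.approx(5.0)
        assert np.abs(out.values).sum() == pytest.approx(5.0)

    def test_energy_outside_mask_zeroed(self):
        spec = self._noisy_spectrum()
        sel = detect_sideband(spec, dc_exclusion_bins=4)
        out = filter_and_center(spec, sel)
        shifted_mask = np.roll(
            sel.mask,
            (spec.dc_bin[0] - sel.peak_bin[0], spec.dc_bin[1] - sel.peak_bin[1]),
            axis=(0, 1),
        )
        assert np.abs(out.values[~shifted_mask]).max() == 0.0

    def test_mask_covering_dc_warns(self):
        spec = self._noisy_spectrum()
        sel = detect_sideband(spec, dc_exclusion_bins=4, mask_radius_bins=40.0)
        with pytest.warns(UserWarning, match="zero-order"):
            filter_and_center(spec, sel)

    def test_flat_phase_reconstructs_constant(self):
        """On-bin carrier, no noise, pre-quantization interference: the
        demodulated phase is constant to 1e-6 rad."""
        from holorbc.simulate import interference_intensity

        n = 256
        sim = SimulationConfig(
            grid_shape=(n, n), fringe_freq_cyc_per_px=(-0.25, 0.125), noise_sigma=0.0
        )
        phase = PhaseMap(np.zeros((n, n)), "unwrapped", sim.sampling_um_per_px)
        intensity = interference_intensity(phase, sim)
        spec = forward_spectrum(make_field(intensity))
        sel = detect_sideband(spec, dc_exclusion_bins=8)
        out = wrapped_phase(inverse_spectrum(filter_and_center(spec, sel)))
        spread = out.values.max() - out.values.min()
        assert spread < 1e-6

    def _noisy_spectrum(self):
        sim = SimulationConfig(
            grid_shape=(64, 64), fringe_freq_cyc_per_px=(-0.25, 0.0), noise_sigma=1.0,
            rng_seed=4,
        )
        phase = PhaseMap(np.zeros((64, 64)), "unwrapped", sim.sampling_um_per_px)
        holo = simulate_off_axis_hologram(phase, sim)
        return forward_spectrum(make_field(holo.pixels.astype(float)))


class TestPropagation:
    def _random_field(self, n=64, seed=5, band_limit=None):
        rng = np.random.default_rng(seed)
        spec = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        if band_limit is not None:
            fx = np.fft.fftfreq(n, d=0.05)
            fxx, fyy = np.meshgrid(fx, fx)
            spec = np.where(
                (0.6328 * np.hypot(fxx, fyy)) < band_limit, spec, 0.0
            )
        return make_field(np.fft.ifft2(spec))

    def test_zero_distance_identity(self):
        field = self._random_field()
        out = angular_spectrum_propagate(field, 0.0)
        np.testing.assert_allclose(out.values, field.values, atol=1e-12)

    def test_forward_backward_inverse(self):
        field = self._random_field(band_limit=0.9)
        out = angular_spectrum_propagate(angular_spectrum_propagate(field, 17.3), -17.3)
        err = np.abs(out.values - field.values).max() / np.abs(field.values).max()
        assert err < 1e-10

    def test_semigroup_composition(self):
        field = self._random_field()
        a = angular_spectrum_propagate(angular_spectrum_propagate(field, 11.0), 6.5)
        b = angular_spectrum_propagate(field, 17.5)
        err = np.abs(a.values - b.values).max() / np.abs(b.values).max()
        assert err < 1e-10

    def test_energy_conserved_for_propagating_band(self):
        field = self._random_field(band_limit=0.9)
        out = angular_spectrum_propagate(field, 42.0)
        e_in = (np.abs(field.values) ** 2).sum()
        e_out = (np.abs(out.values) ** 2).sum()
        assert e_out == pytest.approx(e_in, rel=1e-10)

    def test_z_bookkeeping(self):
        field = self._random_field()
        out = angular_spectrum_propagate(field, 12.5)
        assert out.z_um == pytest.approx(12.5)


class TestAutofocus:
    def _amplitude_object(self, n=128):
        yy, xx = np.mgrid[0:n, 0:n]
        disc = (np.hypot(yy - n / 2, xx - n / 2) < n / 8).astype(float)
        return make_field(disc, sampling=0.5)

    def test_recovers_known_defocus(self):
        d0 = 30.0
        defocused = angular_spectrum_propagate(self._amplitude_object(), d0)
        d = autofocus_distance(defocused, -60.0, 0.0, n_steps=13)
        assert d == pytest.approx(-d0, abs=2.0)

    def test_focused_field_near_zero(self):
        field = self._amplitude_object()
        d = autofocus_distance(field, -20.0, 20.0, n_steps=11)
        assert abs(d) <= 4.0  # one coarse grid step

    def test_constant_field_warns_midrange(self):
        field = make_field(np.ones((64, 64)))
        with pytest.warns(UserWarning, match="flat"):
            d = autofocus_distance(field, -10.0, 30.0, n_steps=5)
        assert d == pytest.approx(10.0)


class TestIntensity:
    def test_values(self):
        field = make_field(np.array([[3 + 4j] * 8] * 8))
        np.testing.assert_allclose(intensity_map(field), 25.0)

    def test_matches_conjugate_product(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        np.testing.assert_allclose(intensity_map(make_field(x)), (x * x.conj()).real)
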