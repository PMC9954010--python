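"""Angular-spectrum engine: transfer function and propagation contracts."""
import numpy as np
import pytest

import gaborscope as g
from gaborscope.exceptions import InvalidInputError, InvalidParameterError

from conftest import random_bandlimited_field

PITCH = 0.46
LAM = 0.45


def dft_matrix_propagate(values, pitch, wavelength, distance):
    """Independent oracle: angular-spectrum propagation evaluated by explicit
    summation (DFT as matrix products, no FFT), with the closed-form kernel
    written out element-wise."""
    n0, n1 = values.shape
    u = np.fft.fftfreq(n0, d=pitch)
    v = np.fft.fftfreq(n1, d=pitch)
    x = np.arange(n0)
    y = np.arange(n1)
    F0 = np.exp(-2j * np.pi * np.outer(u * pitch, x))      # forward DFT rows
    F1 = np.exp(-2j * np.pi * np.outer(v * pitch, y))
    spec = F0 @ values @ F1.T
    H = np.empty((n0, n1), dtype=complex)
    for i in range(n0):
        for j in range(n1):
            s2 = (wavelength * u[i]) ** 2 + (wavelength * v[j]) ** 2
            if s2 <= 1.0:
                H[i, j] = np.exp(1j * 2 * np.pi * distance / wavelength * np.sqrt(1 - s2))
            else:
                H[i, j] = np.exp(-2 * np.pi * abs(distance) / wavelength * np.sqrt(s2 - 1))
    spec *= H
    B0 = np.exp(2j * np.pi * np.outer(x, u * pitch)) / n0   # inverse DFT
    B1 = np.exp(2j * np.pi * np.outer(y, v * pitch)) / n1
    return B0 @ spec @ B1.T


class TestTransferFunction:
    def test_zero_distance_is_identity(self):
        H = g.transfer_function((16, 16), PITCH, LAM, 0.0)
        assert np.allclose(H.values, 1.0)

    def test_unit_modulus_on_propagating_frequencies(self):
        H = g.transfer_function((64, 64), PITCH, LAM, 137.0)
        u = np.fft.fftfreq(64, d=PITCH)
        s2 = (LAM * u[:, None]) ** 2 + (LAM * u[None, :]) ** 2
        prop = s2 <= 1.0
        assert np.allclose(np.abs(H.values[prop]), 1.0)
        assert np.all(np.abs(H.values) <= 1.0 + 1e-12)
        assert abs(abs(H.values[0, 0]) - 1.0) < 1e-12

    def test_closed_form_entry(self):
        # element-wise closed form at a chosen frequency, scalar arithmetic
        d = 100.0
        H = g.transfer_function((64, 64), PITCH, LAM, d)
        i, j = 5, 11
        u = np.fft.fftfreq(64, d=PITCH)
        expected = np.exp(1j * (2 * np.pi * d / LAM)
                          * np.sqrt(1 - (LAM * u[i]) ** 2 - (LAM * u[j]) ** 2))
        assert abs(H.values[i, j] - expected) < 1e-12

    def test_conjugate_relation_for_negated_distance(self):
        Hp = g.transfer_function((32, 32), PITCH, LAM, 250.0)
        Hm = g.transfer_function((32, 32), PITCH, LAM, -250.0)
        u = np.fft.fftfreq(32, d=PITCH)
        s2 = (LAM * u[:, None]) ** 2 + (LAM * u[None, :]) ** 2
        prop = s2 <= 1.0
        assert np.allclose(Hm.values[prop], np.conj(Hp.values[prop]))

    def test_evanescent_zero_policy(self):
        H = g.transfer_function((64, 64), 0.2, LAM, 50.0, evanescent="zero")
        u = np.fft.fftfreq(64, d=0.2)
        s2 = (LAM * u[:, None]) ** 2 + (LAM * u[None, :]) ** 2
        assert np.all(H.values[s2 > 1.0] == 0.0)

    @pytest.mark.parametrize("pitch,wavelength", [(0.0, LAM), (-1.0, LAM), (PITCH, 0.0)])
    def test_invalid_parameters(self, pitch, wavelength):
        with pytest.raises(InvalidParameterError):
            g.transfer_function((16, 16), pitch, wavelength, 10.0)


class TestPropagate:
    def test_plane_wave_is_eigenfunction(self):
        f = g.ComplexField(np.ones((32, 32)), PITCH, LAM)
        out = g.propagate(f, 500.0)
        assert np.allclose(np.abs(out.values), 1.0, atol=1e-12)

    def test_round_trip(self):
        f = random_bandlimited_field((64, 64), PITCH, LAM, seed=1)
        back = g.propagate(g.propagate(f, 80.0), -80.0)
        rms = np.sqrt(np.mean(np.abs(back.values - f.values) ** 2))
        ref = np.sqrt(np.mean(np.abs(f.values) ** 2))
        assert rms < 1e-10 * ref

    @pytest.mark.parametrize("seed,d1,d2", [(0, 30.0, 50.0), (1, -40.0, 95.0),
                                            (2, 12.5, -60.0)])
    def test_group_property(self, seed, d1, d2):
        f = random_bandlimited_field((64, 64), PITCH, LAM, seed=seed)
        two_step = g.propagate(g.propagate(f, d1), d2)
        one_step = g.propagate(f, d1 + d2)
        rms = np.sqrt(np.mean(np.abs(two_step.values - one_step.values) ** 2))
        assert rms < 1e-10

    @pytest.mark.parametrize("seed", [0, 3])
    def test_energy_conservation(self, seed):
        f = random_bandlimited_field((48, 48), PITCH, LAM, seed=seed)
        out = g.propagate(f, 777.0)
        assert out.energy == pytest.approx(f.energy, rel=1e-10)

    def test_single_pixel_matches_explicit_summation_oracle(self):
        vals = np.zeros((64, 64), dtype=complex)
        vals[30, 33] = 1.0
        f = g.ComplexField(vals, PITCH, LAM)
        out = g.propagate(f, 50.0)
        oracle = dft_matrix_propagate(vals, PITCH, LAM, 50.0)
        rms = np.sqrt(np.mean(np.abs(out.values - oracle) ** 2))
        assert rms < 1e-8

    def test_random_field_matches_explicit_summation_oracle(self):
        f = random_bandlimited_field((32, 32), PITCH, LAM, seed=7)
        out = g.propagate(f, 120.0)
        oracle = dft_matrix_propagate(f.values, PITCH, LAM, 120.0)
        rms = np.sqrt(np.mean(np.abs(out.values - oracle) ** 2))
        assert rms < 1e-8

    def test_field_validation(self):
        with pytest.raises(InvalidParameterError):
            g.ComplexField(np.ones((1, 8)), PITCH, LAM)
        with pytest.raises(InvalidParameterError):
            g.ComplexField(np.ones((8, 8)), -0.1, LAM)


class TestHologramToAmplitude:
    def _holo(self, intensity, optics):
        return g.Hologram(intensity, config=optics, recorded_defocus=0.0)

    def test_uniform_unit_intensity(self, ideal_optics):
        amp = g.hologram_to_amplitude(self._holo(np.ones((16, 16)), ideal_optics))
        assert np.allclose(amp.values, 1.0)

    def test_square_root_contract(self, ideal_optics):
        amp = g.hologram_to_amplitude(self._holo(np.full((16, 16), 4.0), ideal_optics))
        assert np.allclose(amp.values, 2.0)

    def test_simulator_round_trip_modulus(self, ideal_optics):
        f = random_bandlimited_field((64, 64), ideal_optics.object_pitch_um,
                                     ideal_optics.wavelength_um, seed=5)
        holo = self._holo(np.abs(f.values) ** 2, ideal_optics)
        amp = g.hologram_to_amplitude(holo)
        assert np.allclose(np.abs(amp.values), np.abs(f.values), atol=1e-12)

    def test_negative_intensity_rejected(self, ideal_optics):
        # bypass Hologram construction validation via direct mutation
        holo = self._holo(np.ones((8, 8)), ideal_optics)
        holo.intensity[0, 0] = -1.0
        with pytest.raises(InvalidInputError):
            g.hologram_to_amplitude(holo)

    def test_background_normalisation(self, ideal_optics):
        holo = self._holo(np.full((32, 32), 5.0), ideal_optics)
        amp = g.hologram_to_amplitude(holo, background_region=(0, 8, 0, 8))
        assert np.allclose(amp.values, 1.0)


class TestRefocus:
    def test_zero_distance_returns_recorded_amplitude(self, ideal_optics):
        rng = np.random.default_rng(0)
        intensity = rng.uniform(0.5, 2.0, (32, 32))
        holo = g.Hologram(intensity, config=ideal_optics)
        out = g.refocus(holo, 0.0)
        assert np.allclose(out.values, np.sqrt(intensity), atol=1e-12)

    def test_uniform_hologram_stays_uniform(self, ideal_optics):
        holo = g.Hologram(np.ones((32, 32)), config=ideal_optics)
        out = g.refocus(holo, 321.0)
        assert np.allclose(np.abs(out.values), 1.0, atol=1e-9)
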