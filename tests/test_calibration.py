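"""Defocus calibration: conversions, USAF arithmetic, contrast, autofocus."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaborscope as g
from gaborscope.calibration import element_profile
from gaborscope.exceptions import InvalidParameterError


class TestDefocusConversion:
    def test_paper_geometry_value(self):
        # M = 10, dz = 1100 um -> dz' = -110,000 um, i.e. an 11 cm camera shift
        dzp = g.object_to_image_defocus(1100.0, 10.0)
        assert dzp == -110_000.0
        assert abs(dzp) / 1e4 == pytest.approx(11.0)  # cm

    def test_trivial_cases(self):
        assert g.object_to_image_defocus(0.0, 10.0) == 0.0
        assert g.object_to_image_defocus(5.0, 1.0) == -5.0

    @given(dz=st.floats(-1e4, 1e4), m=st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_odd_in_dz_quadratic_in_m(self, dz, m):
        assert g.object_to_image_defocus(-dz, m) == -g.object_to_image_defocus(dz, m)
        assert g.object_to_image_defocus(dz, 2 * m) == pytest.approx(
            4 * g.object_to_image_defocus(dz, m), rel=1e-12)
        assert g.image_to_object_defocus(
            g.object_to_image_defocus(dz, m), m) == pytest.approx(dz, abs=1e-9)


class TestGeometricMagnification:
    def test_collimated_is_unity(self):
        assert g.geometric_magnification(math.inf, math.inf) == 1.0

    @pytest.mark.parametrize("d,z,expected", [(2000.0, 1000.0, 2.0),
                                              (1500.0, 1500.0, 1.0)])
    def test_finite_source(self, d, z, expected):
        assert g.geometric_magnification(d, z) == pytest.approx(expected)

    def test_mixed_infinite_rejected(self):
        with pytest.raises(InvalidParameterError):
            g.geometric_magnification(math.inf, 1000.0)


class TestUsafResolution:
    def test_group9_element2(self):
        assert g.usaf_resolution((9, 2)) == pytest.approx(1.74, abs=0.005)

    def test_group0_element1_is_one_lp_per_mm(self):
        assert g.usaf_resolution((0, 1)) == pytest.approx(1000.0)

    def test_group8_element6(self):
        assert g.usaf_resolution((8, 6)) == pytest.approx(1000.0 / 2 ** (8 + 5 / 6))

    @given(group=st.integers(0, 9), element=st.integers(1, 6))
    @settings(max_examples=60, deadline=None)
    def test_halving_every_group(self, group, element):
        assert g.usaf_resolution((group, element)) == pytest.approx(
            2 * g.usaf_resolution((group + 1, element)), rel=1e-12)

    def test_element_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            g.usaf_resolution((7, 0))


class TestContrastParameter:
    def test_constant_profile(self):
        assert g.contrast_parameter(np.full(100, 0.7)) == 0.0

    def test_alternating_square(self):
        prof = np.tile([0.0, 1.0], 50)
        assert g.contrast_parameter(prof) == pytest.approx(1.0)

    def test_sampled_sinusoid(self):
        x = np.arange(1000)
        prof = 0.5 + 0.42 * np.sin(2 * np.pi * 10 * x / 1000)
        assert g.contrast_parameter(prof) == pytest.approx(0.84, abs=0.01)

    @given(offset=st.floats(-5, 5), scale=st.floats(0.1, 10), seed=st.integers(0, 100))
    @settings(max_examples=40, deadline=None)
    def test_offset_invariance_and_linear_scaling(self, offset, scale, seed):
        rng = np.random.default_rng(seed)
        prof = rng.standard_normal(200)
        base = g.contrast_parameter(prof)
        assert g.contrast_parameter(prof + offset) == pytest.approx(base, abs=1e-9)
        assert g.contrast_parameter(prof * scale) == pytest.approx(scale * base,
                                                                   rel=1e-9)


class TestResolutionFromReconstruction:
    def test_noiseless_target_resolves_finest_sampled_element(self, optics):
        ph = g.make_usaf_phase_target(150.0, optics.n_test, optics.n_medium,
                                      optics.wavelength_um, [7],
                                      optics.object_pitch_um, (512, 512))
        res = g.resolution_from_reconstruction(ph.true_phase, ph.layout, ph.pitch)
        assert res.element == g.UsafElement(7, 6)

    def test_lowpass_degradation_bounds_resolution(self, optics):
        ph = g.make_usaf_phase_target(150.0, optics.n_test, optics.n_medium,
                                      optics.wavelength_um, [7],
                                      optics.object_pitch_um, (512, 512))
        cut_period = 6.0  # um: remove all structure finer than this
        spec = np.fft.fft2(ph.true_phase)
        u = np.fft.fftfreq(512, d=ph.pitch)
        r2 = u[:, None] ** 2 + u[None, :] ** 2
        blurred = np.real(np.fft.ifft2(spec * (r2 <= (1 / cut_period) ** 2)))
        res = g.resolution_from_reconstruction(blurred, ph.layout, ph.pitch)
        assert res.period_um >= cut_period - 0.5

    def test_pure_noise_resolves_nothing(self, optics):
        ph = g.make_usaf_phase_target(150.0, optics.n_test, optics.n_medium,
                                      optics.wavelength_um, [7],
                                      optics.object_pitch_um, (512, 512))
        rng = np.random.default_rng(0)
        noise = 0.05 * rng.standard_normal((512, 512))
        res = g.resolution_from_reconstruction(noise, ph.layout, ph.pitch)
        assert res.element is None
        assert np.isinf(res.period_um)


class TestAutofocus:
    def test_recovers_known_defocus(self, optics, usaf_150):
        holo = g.simulate_gabor_hologram(usaf_150, 1100.0, optics,
                                         noise_sigma=0.02, seed=4)
        af = g.autofocus(holo, (300.0, 1800.0), 50.0)
        assert af.reliable
        assert abs(af.distance_um - 1100.0) <= 50.0

    def test_uniform_hologram_flagged_unreliable(self, ideal_optics):
        holo = g.Hologram(np.ones((64, 64)), config=ideal_optics)
        af = g.autofocus(holo, (-100.0, 100.0), 25.0)
        assert not af.reliable
        assert abs(af.distance_um) <= 25.0

    def test_empty_range_rejected(self, ideal_optics):
        holo = g.Hologram(np.ones((64, 64)), config=ideal_optics)
        with pytest.raises(InvalidParameterError):
            g.autofocus(holo, (500.0, 100.0), 50.0)
        with pytest.raises(InvalidParameterError):
            g.autofocus(holo, (100.0, 500.0), 0.0)


class TestDefocusSweep:
    def test_paper_grid_has_31_entries(self, optics):
        # 300..1800 um inclusive, step 50 -> 31 rows in every output list
        ph = g.make_usaf_phase_target(150.0, optics.n_test, optics.n_medium,
                                      optics.wavelength_um, [9],
                                      optics.object_pitch_um, (128, 128))
        values = np.arange(300.0, 1801.0, 50.0)
        assert len(values) == 31
        res = g.defocus_sweep(ph, values, optics, noise_sigma=0.0, seed=0,
                              af_halfwidth=30.0, af_coarse=30.0, af_fine=30.0)
        assert len(res.defocus_um) == len(res.best_refocus_um) == 31
        assert len(res.resolution_um) == len(res.contrast_rad) == 31
        assert len(list(res.rows())) == 31

    def test_defocus_values_must_increase(self, optics, usaf_150):
        with pytest.raises(InvalidParameterError):
            g.defocus_sweep(usaf_150, [500.0, 400.0], optics)

    def test_optimum_is_plateau_median(self):
        from gaborscope.calibration import _select_optimum
        defocus = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        periods = np.array([4.0, 2.0, 2.0, 2.0, 4.0])
        contrast = np.array([0.1, 0.5, 0.6, 0.4, 0.1])
        assert _select_optimum(defocus, periods, contrast) == 300.0
        # tied runs resolved toward the contrast maximum
        periods = np.array([2.0, 4.0, 4.0, 2.0, 2.0])
        contrast = np.array([0.2, 0.1, 0.1, 0.9, 0.8])
        assert _select_optimum(defocus, periods, contrast) == 450.0
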