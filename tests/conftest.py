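import numpy as np
import pytest

import gaborscope as g


@pytest.fixture(scope="session")
def optics():
    """Study optical layout: 10x/0.28NA, 450 nm, 4.6 um camera pixels."""
    return g.study_optics()


@pytest.fixture(scope="session")
def ideal_optics():
    """Same layout without the objective pupil (ideal coherent system)."""
    return g.OpticalConfig(numerical_aperture=None)


@pytest.fixture(scope="session")
def usaf_150(optics):
    """150 nm USAF phase target, groups 7-9 plus chart furniture (the
    standard calibration scene)."""
    return g.sweep_phantom(optics)


@pytest.fixture(scope="session")
def qpi_target_150(optics):
    """150 nm group-6 target on a large grid for quantitative phase work."""
    return g.make_usaf_phase_target(
        150.0, optics.n_test, optics.n_medium, optics.wavelength_um,
        [6], optics.object_pitch_um, (1024, 1024))


def random_bandlimited_field(shape, pitch, wavelength, seed, cutoff_frac=0.5):
    """Random complex field low-passed well inside the propagating band."""
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    u = np.fft.fftfreq(shape[0], d=pitch)
    v = np.fft.fftfreq(shape[1], d=pitch)
    r2 = u[:, None] ** 2 + v[None, :] ** 2
    cutoff = cutoff_frac / wavelength
    spec = np.fft.fft2(vals) * (r2 <= cutoff ** 2)
    return g.ComplexField(np.fft.ifft2(spec), pitch, wavelength)


def pytest_configure(config):
    try:
        import hypothesis
        hypothesis.settings.register_profile("det", derandomize=True)
        hypothesis.settings.load_profile("det")
    except ImportError:
        pass
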