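"""Forward models: Gabor hologram recording and fluorescence frames.

Holograms are simulated in object space at the effective pitch
(camera pitch / M); propagating the transmission over the object-space
defocus dz there is mathematically identical to propagating the magnified
image over dz' = -M^2 dz at the camera pitch, with fewer unit conversions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import OpticalConfig
from .exceptions import InvalidParameterError, InvalidSceneError
from .phantoms import PhasePhantom
from .wave_optics import ComplexField, Hologram, propagate

__all__ = ["simulate_gabor_hologram", "make_fluorescence_frame", "FluorFrame",
           "apply_pupil"]


def apply_pupil(field: ComplexField, numerical_aperture: float) -> ComplexField:
    """Hard coherent pupil: zero all spatial frequencies beyond NA / lambda."""
    if not 0 < numerical_aperture <= 1:
        raise InvalidParameterError("numerical_aperture must lie in (0, 1]")
    u = np.fft.fftfreq(field.shape[0], d=field.pixel_pitch)
    v = np.fft.fftfreq(field.shape[1], d=field.pixel_pitch)
    cutoff2 = (numerical_aperture / field.wavelength) ** 2
    mask = (u[:, None] ** 2 + v[None, :] ** 2) <= cutoff2
    out = np.fft.ifft2(np.fft.fft2(field.values) * mask)
    return ComplexField(out, field.pixel_pitch, field.wavelength)


def simulate_gabor_hologram(phantom: PhasePhantom, defocus_um: float,
                            config: OpticalConfig, noise_sigma: float = 0.02,
                            seed: Optional[int] = None,
                            allow_negative_defocus: bool = False) -> Hologram:
    """Record an in-line Gabor hologram of a phase phantom.

    The transmission is low-pass filtered by the objective pupil (if the
    configuration carries a numerical aperture), propagated over the
    object-space defocus, and detected as intensity with multiplicative
    Gaussian noise of relative scale ``noise_sigma`` (a laser/shot-noise
    proxy), clipped at zero.  Deterministic for a fixed seed.

    Negative defocus is rejected by default (it performs worse for in-line
    phase reconstruction); pass ``allow_negative_defocus=True`` to override.
    """
    if defocus_um < 0 and not allow_negative_defocus:
        raise InvalidParameterError(
            "negative defocus rejected by default (worse in-line phase reconstruction); "
            "set allow_negative_defocus=True to override")
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be >= 0")
    if abs(phantom.pitch - config.object_pitch_um) > 1e-9:
        raise InvalidParameterError(
            f"phantom pitch {phantom.pitch} um does not match the configuration's "
            f"effective object pitch {config.object_pitch_um} um")

    field = ComplexField(phantom.transmission, phantom.pitch, config.wavelength_um)
    if config.numerical_aperture is not None:
        field = apply_pupil(field, config.numerical_aperture)
    out = propagate(field, defocus_um, pad=True, pad_value=1.0)
    intensity = out.intensity
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + noise_sigma * rng.standard_normal(intensity.shape))
    intensity = np.clip(intensity, 0.0, None)
    return Hologram(intensity, config=config, recorded_defocus=defocus_um,
                    meta={"noise_sigma": noise_sigma, "seed": seed})


@dataclass
class FluorFrame:
    """A synthetic fluorescence frame with ground-truth emitter/background
    masks and the generating parameters."""

    intensity: np.ndarray
    signal_mask: np.ndarray
    bg_mask: np.ndarray
    pitch: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal_mask.dtype != bool or self.bg_mask.dtype != bool:
            raise InvalidParameterError("masks must be boolean")
        if np.any(self.signal_mask & self.bg_mask):
            raise InvalidSceneError("signal and background masks overlap")


def make_fluorescence_frame(centers: Sequence[tuple[float, float]],
                            bead_diameter_um: float, signal: float,
                            background: float, noise_sigma: float,
                            seed: Optional[int], pitch_um: float,
                            shape: tuple[int, int],
                            mask_margin_um: float = 2.0,
                            clip_negative: bool = False) -> FluorFrame:
    """Fluorescent beads: disks at ``signal`` counts over a ``background``
    level, with additive Gaussian noise.

    By default the frame represents dark-subtracted counts, so negative noise
    excursions are kept and the sample statistics match the generating
    parameters exactly; ``clip_negative=True`` clips at zero (raw camera
    counts), which biases the background mean and STD when
    ``noise_sigma ~ background``.

    The signal mask contains pixels whose centres fall inside a bead; the
    background mask excludes a guard margin around every bead so the two
    populations are clean.  Deterministic for a fixed seed.
    """
    if not signal > background or background < 0:
        raise InvalidParameterError("require signal > background >= 0")
    if bead_diameter_um <= 0:
        raise InvalidParameterError("bead diameter must be > 0")
    ny, nx = shape
    ys = (np.arange(ny) + 0.5) * pitch_um
    xs = (np.arange(nx) + 0.5) * pitch_um
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    R = bead_diameter_um / 2
    inside = np.zeros(shape, dtype=bool)
    near = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        r2 = (Y - cy) ** 2 + (X - cx) ** 2
        inside |= r2 < R ** 2
        near |= r2 < (R + mask_margin_um) ** 2
    intensity = np.where(inside, float(signal), float(background))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + noise_sigma * rng.standard_normal(shape)
    if clip_negative:
        intensity = np.clip(intensity, 0.0, None)
    return FluorFrame(
        intensity=intensity, signal_mask=inside, bg_mask=~near, pitch=pitch_um,
        truth={"signal": signal, "background": background,
               "noise_sigma": noise_sigma, "seed": seed,
               "bead_diameter_um": bead_diameter_um, "centers": list(map(tuple, centers))})
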