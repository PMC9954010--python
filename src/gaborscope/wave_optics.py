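"""Scalar free-space propagation by the angular-spectrum transfer function.

The propagation of a sampled complex field U over a distance d is computed
with three discrete Fourier transforms,

    U_d = IFFT[ FFT[U] * H(u, v; d) ],

where the transfer function is the exact spectral form of the
Rayleigh-Sommerfeld (first) solution,

    H(u, v; d) = exp( i (2 pi d / lambda) sqrt(1 - (lambda u)^2 - (lambda v)^2) )

for propagating frequencies (lambda^2 (u^2 + v^2) <= 1).  Evanescent
frequencies decay as exp(-(2 pi |d| / lambda) sqrt((lambda u)^2 + (lambda v)^2 - 1))
by default, or may be zeroed.

Sign/time convention: a time dependence exp(-i omega t) is assumed, so a
positive distance propagates the field along the optical axis away from the
source and H(u, v; -d) = conj(H(u, v; d)) on propagating frequencies.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .config import OpticalConfig
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "ComplexField", "TransferFunction", "Hologram",
    "transfer_function", "propagate", "hologram_to_amplitude", "refocus",
]

EvanescentPolicy = Literal["decay", "zero"]


@dataclass
class ComplexField:
    """A 2-D sampled complex wave amplitude with physical metadata.

    ``values`` is dimensionless complex amplitude; ``pixel_pitch`` (um) is the
    sampling interval, identical along both axes; ``wavelength`` (um) is the
    vacuum wavelength of the light the field represents.
    """

    values: np.ndarray
    pixel_pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise InvalidParameterError(
                f"field must be 2-D with both dimensions >= 2, got shape {self.values.shape}")
        if not self.pixel_pitch > 0:
            raise InvalidParameterError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")
        if not self.wavelength > 0:
            raise InvalidParameterError(f"wavelength must be > 0, got {self.wavelength}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def energy(self) -> float:
        """Total power Sum |U|^2 (conserved by lossless propagation)."""
        return float(np.sum(self.intensity))


@dataclass
class TransferFunction:
    """Free-space transfer function H(u, v; d) on a discrete frequency grid."""

    values: np.ndarray
    distance: float
    wavelength: float
    pixel_pitch: float


@dataclass
class Hologram:
    """A recorded in-line (Gabor) hologram: non-negative intensity plus the
    optical configuration and the object-space defocus it was recorded at."""

    intensity: np.ndarray
    config: OpticalConfig
    recorded_defocus: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise InvalidInputError("hologram intensity must be a 2-D image")
        if np.any(self.intensity < 0):
            raise InvalidInputError("hologram intensity must be non-negative")

    @property
    def pitch(self) -> float:
        """Object-space sampling interval of the recording (um)."""
        return self.config.object_pitch_um


def transfer_function(shape: tuple[int, int], pixel_pitch: float, wavelength: float,
                      distance: float, evanescent: EvanescentPolicy = "decay",
                      ) -> TransferFunction:
    """Angular-spectrum transfer function for the given grid and distance.

    The frequency grid matches ``numpy.fft.fft2`` of an array of the stated
    shape sampled at ``pixel_pitch``.  ``H(u, v; 0) == 1`` identically.
    """
    if not pixel_pitch > 0 or not wavelength > 0:
        raise InvalidParameterError("pixel_pitch and wavelength must be positive")
    if len(shape) != 2 or min(shape) < 2:
        raise InvalidParameterError(f"shape must be 2-D with dims >= 2, got {shape}")
    u = np.fft.fftfreq(shape[0], d=pixel_pitch)
    v = np.fft.fftfreq(shape[1], d=pixel_pitch)
    lu2 = (wavelength * u[:, None]) ** 2 + (wavelength * v[None, :]) ** 2
    arg = 1.0 - lu2
    H = np.empty(shape, dtype=np.complex128)
    prop = arg >= 0
    H[prop] = np.exp(1j * (2 * np.pi * distance / wavelength) * np.sqrt(arg[prop]))
    if evanescent == "decay":
        H[~prop] = np.exp(-(2 * np.pi * abs(distance) / wavelength) * np.sqrt(-arg[~prop]))
    elif evanescent == "zero":
        H[~prop] = 0.0 if distance != 0 else 1.0
    else:
        raise InvalidParameterError(f"unknown evanescent policy {evanescent!r}")
    return TransferFunction(H, distance, wavelength, pixel_pitch)


def _padded(values: np.ndarray, pad_value: float) -> tuple[np.ndarray, tuple[int, int]]:
    n0, n1 = values.shape
    p0, p1 = n0 // 2, n1 // 2
    out = np.pad(values, ((p0, p0), (p1, p1)), constant_values=pad_value)
    return out, (p0, p1)


def propagate(field: ComplexField, distance: float, *, pad: bool = False,
              pad_value: complex = 0.0, evanescent: EvanescentPolicy = "decay",
              ) -> ComplexField:
    """Propagate a field over ``distance`` (um; negative = back-propagation).

    With ``pad=True`` the array is symmetrically zero-padded (or padded with
    ``pad_value``) to twice its linear size around the transform pair, which
    suppresses wrap-around of the circular convolution at large distances;
    the returned field is cropped back to the input grid.  Padding is off by
    default so that the operator is exactly unitary on the periodic grid
    (energy conservation, group property, invertibility).
    """
    vals = field.values
    if pad:
        vals, (p0, p1) = _padded(vals, pad_value)
    H = transfer_function(vals.shape, field.pixel_pitch, field.wavelength,
                          distance, evanescent=evanescent)
    out = np.fft.ifft2(np.fft.fft2(vals) * H.values)
    if pad:
        n0, n1 = field.values.shape
        out = out[p0:p0 + n0, p1:p1 + n1]
    return ComplexField(out, field.pixel_pitch, field.wavelength)


def hologram_to_amplitude(holo: Hologram,
                          background_region: Optional[tuple[int, int, int, int]] = None,
                          ) -> ComplexField:
    """Real amplitude field sqrt(I) with zero phase at the recording plane.

    If ``background_region`` (r0, r1, c0, c1; half-open pixel rectangle) is
    given, the intensity is first normalised by the median over that region,
    so the empty background has unit amplitude; otherwise raw counts are used.
    """
    intensity = holo.intensity
    if np.any(intensity < 0):
        raise InvalidInputError("hologram intensity must be non-negative")
    if background_region is not None:
        r0, r1, c0, c1 = background_region
        ref = float(np.median(intensity[r0:r1, c0:c1]))
        if not ref > 0:
            raise InvalidInputError("background region has non-positive median intensity")
        intensity = intensity / ref
    amp = np.sqrt(intensity)
    return ComplexField(amp.astype(np.complex128), holo.pitch, holo.config.wavelength_um)


def refocus(holo: Hologram, distance: float, *, pad: bool = True,
            background_region: Optional[tuple[int, int, int, int]] = None,
            ) -> ComplexField:
    """Reconstruct the complex field at ``distance`` from a recorded hologram.

    Composition of :func:`hologram_to_amplitude` and :func:`propagate`.  The
    sign convention follows :func:`propagate`: reconstruction back toward the
    object plane of a hologram recorded at object-space defocus dz uses
    ``distance = -dz``.  Padding (with the median amplitude, so the field
    continues smoothly) is on by default for reconstruction.
    """
    amp = hologram_to_amplitude(holo, background_region=background_region)
    pad_value = float(np.median(amp.values.real)) if pad else 0.0
    return propagate(amp, distance, pad=pad, pad_value=pad_value)
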