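"""Numerical reconstruction of in-line holograms.

Two reconstruction inputs are supported:

``amplitude``
    The square root of the recorded intensity (zero phase), the textbook
    reading of "the amplitude at the recording plane".  For a weak object
    |1 + O| ~ 1 + Re O, so the reconstructed scattered wave carries only
    half the object contrast.

``intensity``
    The background-normalised intensity itself.  Since
    I = 1 + 2 Re O + |O|^2, back-propagation returns 1 + o + (twin) + ...,
    whose direct term reproduces exp(i phi) of a thin phase object at full
    strength; this is the mode used for quantitative phase work.

Either way the unscattered reference reconstructs together with the
conjugate (twin) wave, which no single-shot in-line reconstruction can
remove; see the methods note for the accuracy this implies.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .exceptions import InvalidParameterError
from .wave_optics import ComplexField, Hologram, hologram_to_amplitude, propagate

__all__ = ["gabor_reconstruct", "reference_to_background"]


def gabor_reconstruct(holo: Hologram, defocus_um: float, mode: str = "intensity",
                      background_region: Optional[tuple[int, int, int, int]] = None,
                      ) -> ComplexField:
    """Reconstruct the object-plane field of a hologram recorded at
    object-space defocus ``defocus_um`` (back-propagation by that distance)."""
    if mode == "amplitude":
        field = hologram_to_amplitude(holo, background_region=background_region)
    elif mode == "intensity":
        I = holo.intensity
        if background_region is not None:
            r0, r1, c0, c1 = background_region
            ref = float(np.median(I[r0:r1, c0:c1]))
        else:
            ref = float(np.median(I))
        if not ref > 0:
            raise InvalidParameterError("hologram has non-positive reference intensity")
        field = ComplexField((I / ref).astype(np.complex128), holo.pitch,
                             holo.config.wavelength_um)
    else:
        raise InvalidParameterError(f"unknown reconstruction mode {mode!r}")
    pad_value = float(np.median(field.values.real))
    out = propagate(field, -defocus_um, pad=True, pad_value=pad_value)
    return out


def reference_to_background(field: ComplexField,
                            background_region: tuple[int, int, int, int],
                            ) -> ComplexField:
    """Remove the global piston phase by rotating the field so the complex
    mean over a structure-free background region is real positive.

    Without this the propagation piston exp(i 2 pi d / lambda) can park the
    background anywhere on the unit circle and object phases wrap spuriously.
    """
    r0, r1, c0, c1 = background_region
    ref = field.values[r0:r1, c0:c1].mean()
    if abs(ref) == 0:
        raise InvalidParameterError("background region has zero complex mean")
    return ComplexField(field.values * (np.conj(ref) / abs(ref)),
                        field.pixel_pitch, field.wavelength)
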