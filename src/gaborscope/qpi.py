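"""Quantitative phase imaging: phase extraction, unwrapping, phase-step
measurement and thickness retrieval.

The optical thickness of a feature follows from its phase step through

    dt = lambda * dphi / (2 pi (n_test - n_medium)),

so a phase accuracy of sigma_phi rad translates into a height accuracy of
lambda * sigma_phi / (2 pi dn).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from skimage.restoration import unwrap_phase as _skimage_unwrap

from .config import OpticalConfig
from .exceptions import InvalidParameterError, InvalidRegionError
from .phantoms import UsafLayout
from .reconstruct import gabor_reconstruct, reference_to_background
from .wave_optics import ComplexField, Hologram

__all__ = [
    "PhaseMap", "PhaseStep", "ThicknessResult",
    "extract_phase", "unwrap_phase", "phase_step", "thickness_from_phase",
    "background_phase_std", "measure_target_thickness", "plateau_step",
]


@dataclass
class PhaseMap:
    """2-D phase image in radians.  ``wrapped`` means all values lie in
    (-pi, pi]; ``mask`` marks valid pixels (all valid when None)."""

    values: np.ndarray
    pitch: float
    wrapped: bool = True
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidParameterError("phase map must be 2-D")
        if self.wrapped and (self.values.min() <= -np.pi - 1e-12
                             or self.values.max() > np.pi + 1e-12):
            raise InvalidParameterError("wrapped phase must lie in (-pi, pi]")


@dataclass
class PhaseStep:
    value_rad: float
    uncertainty_rad: float


@dataclass
class ThicknessResult:
    phase_step_rad: float
    phase_uncertainty_rad: float
    thickness_nm: float
    thickness_uncertainty_nm: float
    details: dict = field(default_factory=dict)


def extract_phase(fld: ComplexField,
                  background_region: Optional[tuple[int, int, int, int]] = None,
                  ) -> PhaseMap:
    """Wrapped phase (argument) of a complex field, in (-pi, pi].

    If a background region is given, the global piston is removed first by
    rotating the field so that region's complex mean is real positive.
    """
    if background_region is not None:
        fld = reference_to_background(fld, background_region)
    return PhaseMap(np.angle(fld.values), fld.pixel_pitch, wrapped=True)


def unwrap_phase(pm: PhaseMap) -> PhaseMap:
    """2-D phase unwrapping (reliability-ordered, via scikit-image).

    The output is congruent to the input modulo 2 pi at every valid pixel.
    """
    if pm.mask is not None:
        marr = np.ma.MaskedArray(pm.values, mask=~pm.mask)
        out = np.asarray(_skimage_unwrap(marr).filled(0.0))
    else:
        out = np.asarray(_skimage_unwrap(pm.values))
    return PhaseMap(out, pm.pitch, wrapped=False, mask=pm.mask)


def _region_profile(values: np.ndarray, region: tuple[int, int, int, int]) -> np.ndarray:
    r0, r1, c0, c1 = region
    if not (0 <= r0 < r1 <= values.shape[0] and 0 <= c0 < c1 <= values.shape[1]):
        raise InvalidRegionError(f"region {region} out of bounds for shape {values.shape}")
    sub = values[r0:r1, c0:c1]
    # profile runs along the longer side; average across the short axis
    if sub.shape[1] >= sub.shape[0]:
        return sub.mean(axis=0)
    return sub.mean(axis=1)


def phase_step(pm: PhaseMap, region: tuple[int, int, int, int],
               period_um: Optional[float] = None) -> PhaseStep:
    """Phase step of a periodic bar profile inside ``region``
    (r0, r1, c0, c1; 0-based, half-open).

    The region is averaged across its short axis; peaks and troughs of the
    (lightly smoothed) profile are located, each extremum is read as the
    local mean of the raw profile, and the step is the mean of the maxima
    minus the mean of the minima.  The uncertainty combines the standard
    deviations of the two peak populations in quadrature.  Returns 0 +- 0
    for a profile without interior extrema.
    """
    prof = _region_profile(pm.values, region)
    if prof.size < 3:
        raise InvalidRegionError("profile too short (need at least 3 samples)")
    if period_um is not None:
        period_px = max(1, int(round(period_um / pm.pitch)))
        win = max(1, period_px // 4)
        sep = max(1, int(0.6 * period_px))
    else:
        win = max(1, prof.size // 16)
        sep = max(1, prof.size // 8)
    smooth = uniform_filter1d(prof, win) if win > 1 else prof
    mx, _ = find_peaks(smooth, plateau_size=1, distance=sep)
    mn, _ = find_peaks(-smooth, plateau_size=1, distance=sep)
    # keep only extrema on the correct side of the midline, so noise bumps on
    # ramps or on the opposite plateau cannot join the wrong population
    mid = 0.5 * (smooth.max() + smooth.min())
    mx = mx[smooth[mx] > mid]
    mn = mn[smooth[mn] < mid]
    if len(mx) == 0 or len(mn) == 0:
        return PhaseStep(0.0, 0.0)

    def local_means(idx: np.ndarray) -> np.ndarray:
        half = max(1, win // 2)
        return np.array([prof[max(0, i - half):i + half + 1].mean() for i in idx])

    highs = local_means(mx)
    lows = local_means(mn)
    step = float(highs.mean() - lows.mean())
    unc = float(np.sqrt(highs.std() ** 2 + lows.std() ** 2))
    return PhaseStep(step, unc)


def plateau_step(profile: np.ndarray) -> float:
    """Robust two-level step of a bar profile: median of the samples above
    the mid-range minus median of those below.  Insensitive to band-limit
    ringing on the plateaus."""
    profile = np.asarray(profile, dtype=float)
    mid = 0.5 * (profile.max() + profile.min())
    hi = profile[profile > mid]
    lo = profile[profile < mid]
    if hi.size == 0 or lo.size == 0:
        return 0.0
    return float(np.median(hi) - np.median(lo))


def thickness_from_phase(phase_step_rad: float, wavelength_um: float,
                         n_test: float, n_medium: float,
                         uncertainty_rad: float = 0.0) -> ThicknessResult:
    """Feature height (nm) from its optical phase step:
    dt = lambda * dphi / (2 pi (n_test - n_medium)); linear in both dphi and
    lambda, with the uncertainty propagated by the same factor."""
    if n_test <= n_medium:
        raise InvalidParameterError("n_test must exceed n_medium")
    scale_nm = 1000.0 * wavelength_um / (2 * np.pi * (n_test - n_medium))
    return ThicknessResult(
        phase_step_rad=phase_step_rad,
        phase_uncertainty_rad=uncertainty_rad,
        thickness_nm=scale_nm * phase_step_rad,
        thickness_uncertainty_nm=scale_nm * uncertainty_rad)


def background_phase_std(pm: PhaseMap, region: tuple[int, int, int, int]) -> float:
    """Standard deviation (rad) of the phase over a clear background region
    after removing its mean — the empirical phase-accuracy metric."""
    r0, r1, c0, c1 = region
    if (r1 - r0) * (c1 - c0) < 100:
        raise InvalidRegionError("background region must contain at least 100 pixels")
    sub = pm.values[r0:r1, c0:c1]
    if sub.size < 100:
        raise InvalidRegionError("background region must contain at least 100 pixels")
    return float(sub.std())


def measure_target_thickness(holo: Hologram, layout: UsafLayout,
                             bg_region: tuple[int, int, int, int],
                             defocus_um: Optional[float] = None,
                             group: Optional[int] = None,
                             elements: Sequence[int] = (2, 3, 4, 5, 6),
                             mode: str = "intensity") -> ThicknessResult:
    """End-to-end thickness measurement of a USAF phase target hologram.

    Reconstructs at the recorded defocus (or ``defocus_um`` if given),
    references the phase to the background region, reads the robust plateau
    step of every requested element in both orientations, and converts the
    pooled step to a physical height.
    """
    from .calibration import element_profile  # local import to avoid a cycle

    d = defocus_um if defocus_um is not None else holo.recorded_defocus
    rec = gabor_reconstruct(holo, d, mode=mode, background_region=bg_region)
    rec = reference_to_background(rec, bg_region)
    phase = np.angle(rec.values)
    phase = phase - phase[bg_region[0]:bg_region[1], bg_region[2]:bg_region[3]].mean()

    if group is None:
        group = sorted(layout.groups)[0]
    steps = []
    for e in elements:
        for orient in ("v", "h"):
            prof = element_profile(phase, layout.region(group, e, orient),
                                   holo.pitch)
            steps.append(plateau_step(prof))
    steps = np.asarray(steps)
    step = float(steps.mean())
    unc = float(steps.std())
    cfg: OpticalConfig = holo.config
    result = thickness_from_phase(step, cfg.wavelength_um, cfg.n_test, cfg.n_medium,
                                  uncertainty_rad=unc)
    result.details = {"group": group, "elements": list(elements),
                      "per_element_steps_rad": steps.tolist(),
                      "reconstruction_mode": mode, "defocus_um": d}
    return result
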