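"""Defocus-distance calibration: geometric conversions, USAF resolution
arithmetic, contrast parameter, autofocus, and the defocus sweep.

The calibration answers one experimental question: how far from the image
plane should the hologram camera sit?  A USAF-style phase target is recorded
over a range of object-space defocus distances; each hologram is numerically
refocused, the finest resolved element and a phase-contrast parameter are
scored, and the optimum is the centre of the plateau of best resolution.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .config import OpticalConfig
from .exceptions import InvalidParameterError, InvalidRegionError
from .phantoms import (PhasePhantom, UsafLayout, make_usaf_phase_target,
                       quiet_region)
from .reconstruct import gabor_reconstruct, reference_to_background
from .simulate import simulate_gabor_hologram
from .wave_optics import Hologram, hologram_to_amplitude, propagate

__all__ = [
    "UsafElement", "SweepResult", "AutofocusResult", "ResolutionResult",
    "object_to_image_defocus", "image_to_object_defocus",
    "geometric_magnification", "usaf_resolution", "contrast_parameter",
    "element_profile", "element_dip_contrast", "resolution_from_reconstruction",
    "autofocus", "defocus_sweep", "sweep_phantom", "FOCUS_METRICS",
]


# --------------------------------------------------------------------------
# geometric conversions

def object_to_image_defocus(dz_object_um: float, magnification: float) -> float:
    """Image-space camera shift corresponding to an object-space defocus:
    dz' = -M^2 dz (signed; the camera moves opposite to the object)."""
    if not magnification > 0:
        raise InvalidParameterError("magnification must be > 0")
    return -(magnification ** 2) * dz_object_um


def image_to_object_defocus(dz_image_um: float, magnification: float) -> float:
    """Inverse of :func:`object_to_image_defocus`."""
    if not magnification > 0:
        raise InvalidParameterError("magnification must be > 0")
    return -dz_image_um / magnification ** 2


def geometric_magnification(source_to_camera_um: float,
                            source_to_object_um: float) -> float:
    """Projection magnification MG = d/z of an in-line hologram recorded with
    a point source at distance z from the object and d from the camera.
    Exactly 1 for collimated illumination (both distances infinite)."""
    d_inf = math.isinf(source_to_camera_um)
    z_inf = math.isinf(source_to_object_um)
    if d_inf != z_inf:
        raise InvalidParameterError(
            "source distances must be both finite or both infinite")
    if d_inf and z_inf:
        return 1.0
    if source_to_camera_um <= 0 or source_to_object_um <= 0:
        raise InvalidParameterError("source distances must be positive")
    return source_to_camera_um / source_to_object_um


@dataclass(frozen=True)
class UsafElement:
    group: int
    element: int

    def __post_init__(self) -> None:
        if not 1 <= self.element <= 6:
            raise InvalidParameterError("USAF element index must be in 1..6")


def usaf_resolution(element: UsafElement | tuple[int, int]) -> float:
    """Line-pair period (um) of a USAF-1951 element: the spatial frequency is
    2^(group + (element-1)/6) line pairs per millimetre."""
    if not isinstance(element, UsafElement):
        element = UsafElement(*element)
    freq_lp_mm = 2.0 ** (element.group + (element.element - 1) / 6.0)
    return 1000.0 / freq_lp_mm


# --------------------------------------------------------------------------
# contrast parameter and resolution scoring

def contrast_parameter(profile: np.ndarray, min_separation: Optional[int] = None,
                       ) -> float:
    """Phase-amplitude contrast of a 1-D profile:
    mean of the local maxima minus mean of the local minima.

    Plateau-aware (a flat-topped bar counts as one extremum); returns 0 when
    the profile has no interior extrema.  ``min_separation`` (samples)
    optionally enforces a minimum distance between detected peaks.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 3:
        raise InvalidParameterError("profile must be 1-D with at least 3 samples")
    kw = {"distance": min_separation} if min_separation else {}
    mx, _ = find_peaks(profile, plateau_size=1, **kw)
    mn, _ = find_peaks(-profile, plateau_size=1, **kw)
    if len(mx) == 0 or len(mn) == 0:
        return 0.0
    return float(profile[mx].mean() - profile[mn].mean())


def element_profile(phase: np.ndarray, region, pitch: float,
                    central_frac: float = 0.6) -> np.ndarray:
    """1-D phase profile across the three bars of a USAF element, averaged
    over the central fraction of the bar length."""
    if region.orientation == "v":
        yc, L = (region.y0 + region.y1) / 2, region.y1 - region.y0
        i0 = max(0, int((yc - central_frac * L / 2) / pitch))
        i1 = int(np.ceil((yc + central_frac * L / 2) / pitch))
        j0 = max(0, int(region.x0 / pitch))
        j1 = int(np.ceil(region.x1 / pitch))
        sub = phase[i0:i1, j0:j1]
        return sub.mean(axis=0)
    xc, L = (region.x0 + region.x1) / 2, region.x1 - region.x0
    j0 = max(0, int((xc - central_frac * L / 2) / pitch))
    j1 = int(np.ceil((xc + central_frac * L / 2) / pitch))
    i0 = max(0, int(region.y0 / pitch))
    i1 = int(np.ceil(region.y1 / pitch))
    sub = phase[i0:i1, j0:j1]
    return sub.mean(axis=1)


def element_dip_contrast(phase: np.ndarray, region, pitch: float) -> float:
    """Rayleigh-dip contrast of one element: mean phase at the three bar
    centres minus mean phase at the two gap centres."""
    prof = element_profile(phase, region, pitch)
    if region.orientation == "v":
        origin = region.x0
    else:
        origin = region.y0
    try:
        bars = [prof[int(round((c - origin) / pitch))] for c in region.bar_centers_um()]
        gaps = [prof[int(round((c - origin) / pitch))] for c in region.gap_centers_um()]
    except IndexError:
        return 0.0
    return float(np.mean(bars) - np.mean(gaps))


@dataclass
class ResolutionResult:
    element: Optional[UsafElement]
    period_um: float            # inf when nothing resolved
    contrasts: dict = field(default_factory=dict)


def resolution_from_reconstruction(phase: np.ndarray, layout: UsafLayout,
                                   pitch: float, threshold: float = 0.264,
                                   ) -> ResolutionResult:
    """Finest resolved element of a reconstructed phase image.

    Elements are walked from coarse to fine; an element is resolved when its
    Rayleigh-dip contrast exceeds ``threshold`` times the target's nominal
    phase step in *both* bar orientations.  The walk stops at the first
    unresolved element, mirroring the way a resolution chart is read.
    """
    if layout.nominal_step_rad <= 0:
        raise InvalidParameterError("layout carries no nominal phase step")
    floor = threshold * layout.nominal_step_rad
    best: Optional[UsafElement] = None
    contrasts: dict = {}
    for g in sorted(layout.groups):
        for e in range(1, 7):
            c = min(element_dip_contrast(phase, layout.region(g, e, o), pitch)
                    for o in ("v", "h"))
            contrasts[(g, e)] = c
            if c >= floor:
                best = UsafElement(g, e)
            else:
                period = usaf_resolution(best) if best else np.inf
                return ResolutionResult(best, period, contrasts)
    period = usaf_resolution(best) if best else np.inf
    return ResolutionResult(best, period, contrasts)


# --------------------------------------------------------------------------
# autofocus

def _metric_amplitude_variance(amplitude: np.ndarray) -> float:
    m = amplitude.mean()
    return float(amplitude.var() / (m * m + 1e-300))


def _metric_tenengrad(amplitude: np.ndarray) -> float:
    gy, gx = np.gradient(amplitude)
    m = amplitude.mean()
    return float(np.mean(gy ** 2 + gx ** 2) / (m * m + 1e-300))


#: name -> (function of reconstructed amplitude, "min"/"max" at focus)
FOCUS_METRICS: dict[str, tuple[Callable[[np.ndarray], float], str]] = {
    # a pure phase object shows minimal amplitude contrast in focus
    "amplitude_variance": (_metric_amplitude_variance, "min"),
    # gradient sharpness; maximal at focus for amplitude-contrast objects
    "tenengrad": (_metric_tenengrad, "max"),
}


@dataclass
class AutofocusResult:
    distance_um: float
    distances_um: np.ndarray
    scores: np.ndarray
    reliable: bool


def autofocus(holo: Hologram, search_range: tuple[float, float], step: float,
              metric: str = "amplitude_variance", refine_step: Optional[float] = None,
              ) -> AutofocusResult:
    """Best refocus distance (object space, um) of a recorded hologram.

    The hologram amplitude is back-propagated over a coarse grid of candidate
    distances and a scalar focus metric is evaluated on the reconstructed
    amplitude.  The coarse curve is normalised by a wide median filter before
    taking the arg-best, so that slow monotone trends (energy drifting out of
    the window at large distances) cannot outvote the genuine focus dip; a
    fine pass at ``refine_step`` (default step/5) brackets the coarse pick.

    A flat metric curve (e.g. an empty hologram) is flagged unreliable and
    the candidate closest to zero is returned.
    """
    lo, hi = search_range
    if not step > 0:
        raise InvalidParameterError("step must be > 0")
    if hi < lo:
        raise InvalidParameterError("empty search range")
    try:
        metric_fn, mode = FOCUS_METRICS[metric]
    except KeyError:
        raise InvalidParameterError(
            f"unknown focus metric {metric!r}; available: {sorted(FOCUS_METRICS)}")

    amp = hologram_to_amplitude(holo)
    pad_value = float(np.median(amp.values.real))

    def score(d: float) -> float:
        rec = propagate(amp, -d, pad=True, pad_value=pad_value)
        return metric_fn(np.abs(rec.values))

    ds = np.arange(lo, hi + step / 2, step, dtype=float)
    sc = np.array([score(d) for d in ds])

    spread = sc.max() - sc.min()
    reliable = bool(spread > 1e-9 * max(abs(sc).max(), 1e-300))
    if not reliable:
        best = float(ds[np.argmin(np.abs(ds))])
        return AutofocusResult(best, ds, sc, False)

    if len(ds) >= 5:
        base = median_filter(sc, size=min(9, len(ds) // 2 * 2 + 1), mode="nearest")
        resid = sc / np.where(base > 0, base, 1.0)
    else:
        resid = sc
    idx = int(np.argmin(resid) if mode == "min" else np.argmax(resid))
    d0 = float(ds[idx])

    fine = refine_step if refine_step is not None else step / 5
    if fine < step:
        ds2 = np.arange(max(lo, d0 - step), min(hi, d0 + step) + 1e-9, fine)
        sc2 = np.array([score(d) for d in ds2])
        idx2 = int(np.argmin(sc2) if mode == "min" else np.argmax(sc2))
        best = float(ds2[idx2])
    else:
        best = d0
    return AutofocusResult(best, ds, sc, True)


# --------------------------------------------------------------------------
# defocus sweep

@dataclass
class SweepResult:
    defocus_um: np.ndarray
    best_refocus_um: np.ndarray
    resolved: list                     # UsafElement or None, per defocus
    resolution_um: np.ndarray          # line-pair period; inf = none resolved
    contrast_rad: np.ndarray           # contrast parameter on the designated group
    optimum_um: float

    def rows(self):
        for i in range(len(self.defocus_um)):
            el = self.resolved[i]
            yield {
                "defocus_um": float(self.defocus_um[i]),
                "best_refocus_um": float(self.best_refocus_um[i]),
                "group": el.group if el else "",
                "element": el.element if el else "",
                "resolution_um": float(self.resolution_um[i]),
                "contrast_rad": float(self.contrast_rad[i]),
            }


def sweep_phantom(config: OpticalConfig, height_nm: float = 150.0,
                  groups: Sequence[int] = (7, 8, 9), shape: tuple[int, int] = (512, 512),
                  chart_furniture: bool = True) -> PhasePhantom:
    """The standard calibration target for sweep studies: fine USAF groups
    with the surrounding chart furniture of a commercial target."""
    return make_usaf_phase_target(
        height_nm=height_nm, n_test=config.n_test, n_medium=config.n_medium,
        wavelength_um=config.wavelength_um, groups=list(groups),
        pitch_um=config.object_pitch_um, shape=shape,
        chart_furniture=chart_furniture)


def _select_optimum(defocus: np.ndarray, periods: np.ndarray,
                    contrast: np.ndarray) -> float:
    """Centre (median defocus) of the contiguous run of best resolution;
    among tied runs the one holding the largest contrast wins."""
    finite = np.isfinite(periods)
    if not finite.any():
        return float("nan")
    best_p = periods[finite].min()
    runs = []
    i = 0
    n = len(periods)
    while i < n:
        if periods[i] == best_p:
            j = i
            while j + 1 < n and periods[j + 1] == best_p:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    def run_key(run):
        i, j = run
        vals = contrast[i:j + 1]
        return float(np.nanmax(vals)) if np.any(np.isfinite(vals)) else -np.inf
    i, j = max(runs, key=run_key)
    return float(np.median(defocus[i:j + 1]))


def defocus_sweep(phantom: PhasePhantom, defocus_values: Sequence[float],
                  config: OpticalConfig, noise_sigma: float = 0.02,
                  seed: int = 0, group_under_test: int = 8,
                  threshold: float = 0.264, af_halfwidth: float = 100.0,
                  af_coarse: float = 25.0, af_fine: float = 8.0,
                  bg_region: Optional[tuple[int, int, int, int]] = None,
                  ) -> SweepResult:
    """Simulate-and-score a defocus calibration sweep.

    For each recording defocus: simulate a hologram (independently seeded),
    autofocus in a bracket around the nominal stage position, reconstruct
    the phase (intensity mode), score the finest resolved element and the
    contrast parameter on ``group_under_test``.  The optimum defocus is the
    centre of the plateau of best resolution, ties broken toward the
    contrast maximum.
    """
    defocus_values = np.asarray(list(defocus_values), dtype=float)
    if len(defocus_values) == 0 or np.any(np.diff(defocus_values) <= 0):
        raise InvalidParameterError("defocus values must be strictly increasing")
    if phantom.layout is None:
        raise InvalidParameterError("sweep phantom must carry a USAF layout")
    layout = phantom.layout
    if bg_region is None:
        bg_region = quiet_region(phantom)

    rng = np.random.default_rng(seed)
    best_d = np.empty_like(defocus_values)
    periods = np.empty_like(defocus_values)
    resolved: list = []
    contrast = np.empty_like(defocus_values)

    for i, dz in enumerate(defocus_values):
        holo = simulate_gabor_hologram(phantom, dz, config, noise_sigma=noise_sigma,
                                       seed=int(rng.integers(2 ** 31)))
        lo = max(0.0, dz - af_halfwidth)
        af = autofocus(holo, (lo, dz + af_halfwidth), af_coarse, refine_step=af_fine)
        best_d[i] = af.distance_um
        rec = gabor_reconstruct(holo, af.distance_um, mode="intensity")
        rec = reference_to_background(rec, bg_region)
        phase = np.angle(rec.values)
        phase = phase - phase[bg_region[0]:bg_region[1], bg_region[2]:bg_region[3]].mean()
        res = resolution_from_reconstruction(phase, layout, phantom.pitch,
                                             threshold=threshold)
        resolved.append(res.element)
        periods[i] = res.period_um
        if group_under_test in layout.groups:
            vals = []
            for e in range(1, 7):
                reg = layout.region(group_under_test, e, "v")
                sep = max(1, int(0.6 * reg.period_um / phantom.pitch))
                vals.append(contrast_parameter(
                    element_profile(phase, reg, phantom.pitch), min_separation=sep))
            contrast[i] = float(np.mean(vals))
        else:
            contrast[i] = np.nan

    optimum = _select_optimum(defocus_values, periods, contrast)
    return SweepResult(defocus_values, best_d, resolved, periods, contrast, optimum)
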