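"""Synthetic phase objects: USAF-style resolution targets, spherical beads,
and microorganism-like blobs.

All phantoms are pure phase objects: ``transmission = exp(i * true_phase)``
with unit modulus, plus the ground-truth phase map and the occupancy (the
fraction of pixels carrying non-background phase), which is what the Gabor
weak-object condition constrains.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import InvalidParameterError, InvalidSceneError, UnresolvableGeometryError

__all__ = [
    "PhasePhantom", "UsafLayout", "ElementRegion", "DensityCheck",
    "make_usaf_phase_target", "make_bead_phantom", "make_organism_phantom",
    "check_gabor_density", "usaf_phase_step", "quiet_region",
]

OCCUPANCY_PHASE_FLOOR = 0.01  # rad; pixels above this count as occupied


def usaf_phase_step(height_nm: float, n_test: float, n_medium: float,
                    wavelength_um: float) -> float:
    """Optical phase step (rad) of a feature of the given physical height:
    2 pi (n_test - n_medium) h / lambda."""
    return 2 * np.pi * (n_test - n_medium) * (height_nm / 1000.0) / wavelength_um


@dataclass
class ElementRegion:
    """Bounding box (um, half-open) of one three-bar block plus margin.

    ``orientation`` is "v" for vertical bars (profile runs along x) or "h"
    for horizontal bars (profile runs along y).  ``bar_start`` is the
    coordinate (um) of the leading edge of the first bar along the profile
    axis; ``period_um`` is the line-pair period (2x bar width).
    """
    y0: float
    y1: float
    x0: float
    x1: float
    period_um: float
    orientation: str
    bar_start: float

    def pixel_box(self, pitch: float) -> tuple[int, int, int, int]:
        return (max(0, int(self.y0 / pitch)), int(np.ceil(self.y1 / pitch)),
                max(0, int(self.x0 / pitch)), int(np.ceil(self.x1 / pitch)))

    def bar_centers_um(self) -> list[float]:
        w = self.period_um / 2
        return [self.bar_start + (2 * k + 0.5) * w for k in range(3)]

    def gap_centers_um(self) -> list[float]:
        w = self.period_um / 2
        return [self.bar_start + (2 * k + 1.5) * w for k in range(2)]


@dataclass
class UsafLayout:
    """Pixel-free geometric description of a rendered USAF-style target."""

    elements: dict = field(default_factory=dict)  # (group, element, orientation) -> ElementRegion
    groups: tuple = ()
    nominal_step_rad: float = 0.0

    def region(self, group: int, element: int, orientation: str) -> ElementRegion:
        return self.elements[(group, element, orientation)]


@dataclass
class PhasePhantom:
    """A synthetic pure-phase object sampled at ``pitch`` um per pixel."""

    transmission: np.ndarray
    true_phase: np.ndarray
    occupancy: float
    pitch: float
    layout: Optional[UsafLayout] = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mod = np.abs(self.transmission)
        if np.any(mod > 1 + 1e-9):
            raise InvalidParameterError("phantom transmission modulus must be <= 1")


@dataclass
class DensityCheck:
    passed: bool
    occupancy: float
    limit: float


def _usaf_period_um(group: int, element: int) -> float:
    return 1000.0 / 2 ** (group + (element - 1) / 6.0)


def _render_rect(img: np.ndarray, y0: float, y1: float, x0: float, x1: float,
                 pitch: float) -> None:
    """Accumulate the area coverage of an axis-aligned rectangle given in um.

    Separable exact pixel coverage; edge pixels carry fractional values, a
    reasonable raster of a lithographically sharp feature.
    """
    ny, nx = img.shape
    ys = np.arange(ny) * pitch
    xs = np.arange(nx) * pitch
    cov_y = np.clip((np.minimum(ys + pitch, y1) - np.maximum(ys, y0)) / pitch, 0.0, 1.0)
    cov_x = np.clip((np.minimum(xs + pitch, x1) - np.maximum(xs, x0)) / pitch, 0.0, 1.0)
    img += np.outer(cov_y, cov_x)


def _render_furniture(cov: np.ndarray, pitch: float) -> None:
    """Reference squares and coarse bars that surround the fine groups on a
    real resolution chart; placed at fixed window fractions."""
    ny, nx = cov.shape
    H, W = ny * pitch, nx * pitch

    def rect(fy0, fy1, fx0, fx1):
        _render_rect(cov, fy0 * H, fy1 * H, fx0 * W, fx1 * W, pitch)

    rect(0.13, 0.21, 0.13, 0.21)     # solid square, top left
    rect(0.13, 0.21, 0.645, 0.725)   # solid square, top right
    rect(0.775, 0.855, 0.18, 0.26)   # solid square, bottom left
    rect(0.80, 0.845, 0.60, 0.82)    # wide bar, bottom
    rect(0.425, 0.66, 0.115, 0.16)   # tall bar, left
    np.clip(cov, 0.0, 1.0, out=cov)


def make_usaf_phase_target(height_nm: float, n_test: float, n_medium: float,
                           wavelength_um: float, groups: Sequence[int],
                           pitch_um: float, shape: tuple[int, int],
                           chart_furniture: bool = False,
                           margin_frac: float = 0.30) -> PhasePhantom:
    """Render a USAF-1951-style phase resolution target.

    Each requested group is one column of six elements; every element is a
    pair of three-bar blocks (vertical bars, then horizontal bars to the
    right).  Bars are ``period/2`` wide and five bar-widths long, and carry a
    uniform optical phase ``2 pi (n_test - n_medium) h / lambda`` over a
    zero-phase background.  Optionally the coarse reference marks of a real
    chart are added around the groups (``chart_furniture``).
    """
    if height_nm < 0:
        raise InvalidParameterError("height must be >= 0")
    if n_test <= n_medium:
        raise InvalidParameterError("n_test must exceed n_medium")
    for g in groups:
        for e in range(1, 7):
            if _usaf_period_um(g, e) < 2 * pitch_um:
                raise UnresolvableGeometryError(
                    f"group {g} element {e}: bar period {_usaf_period_um(g, e):.3f} um "
                    f"is below 2 pixels at pitch {pitch_um} um")

    phi0 = usaf_phase_step(height_nm, n_test, n_medium, wavelength_um)
    ny, nx = shape
    H, W = ny * pitch_um, nx * pitch_um
    cov = np.zeros(shape)
    layout = UsafLayout(groups=tuple(groups), nominal_step_rad=phi0)

    x = margin_frac * W
    for g in groups:
        y = margin_frac * H
        w1 = _usaf_period_um(g, 1) / 2
        for e in range(1, 7):
            p = _usaf_period_um(g, e)
            w = p / 2
            L = 5 * w
            if y + L > H or x + 8 * w1 + L > W:
                raise UnresolvableGeometryError(
                    f"group {g} element {e} does not fit inside the {H:.0f}x{W:.0f} um grid")
            for k in range(3):
                _render_rect(cov, y, y + L, x + 2 * k * w, x + (2 * k + 1) * w, pitch_um)
            layout.elements[(g, e, "v")] = ElementRegion(
                y0=y, y1=y + L, x0=x - w, x1=x + 5 * w + w,
                period_um=p, orientation="v", bar_start=x)
            hx = x + 5 * w1 + 3 * w1
            for k in range(3):
                _render_rect(cov, y + 2 * k * w, y + (2 * k + 1) * w, hx, hx + L, pitch_um)
            layout.elements[(g, e, "h")] = ElementRegion(
                y0=y - w, y1=y + 5 * w + w, x0=hx, x1=hx + L,
                period_um=p, orientation="h", bar_start=y)
            y += L + 4 * w
        x += 13 * w1

    if chart_furniture:
        _render_furniture(cov, pitch_um)
    np.clip(cov, 0.0, 1.0, out=cov)

    phase = cov * phi0
    occupancy = float(np.mean(phase > OCCUPANCY_PHASE_FLOOR)) if phi0 > 0 else 0.0
    return PhasePhantom(
        transmission=np.exp(1j * phase), true_phase=phase, occupancy=occupancy,
        pitch=pitch_um, layout=layout,
        truth={"height_nm": height_nm, "phase_step_rad": phi0, "groups": list(groups)})


def make_bead_phantom(diameter_um: float, n_bead: float, n_medium: float,
                      wavelength_um: float, centers: Sequence[tuple[float, float]],
                      pitch_um: float, shape: tuple[int, int]) -> PhasePhantom:
    """Spherical beads under the chord-length model.

    Each bead adds phase (2 pi / lambda) (n_bead - n_medium) * 2 sqrt(R^2 - r^2)
    inside radius R and zero outside.  Beads must lie fully inside the grid
    and must not overlap (dilute counting-chamber preparation).
    """
    if diameter_um <= 0:
        raise InvalidParameterError("bead diameter must be > 0")
    if n_bead <= n_medium:
        raise InvalidParameterError("n_bead must exceed n_medium")
    R = diameter_um / 2
    ny, nx = shape
    H, W = ny * pitch_um, nx * pitch_um
    centers = [tuple(map(float, c)) for c in centers]
    for cy, cx in centers:
        if not (R <= cy <= H - R and R <= cx <= W - R):
            raise InvalidSceneError(f"bead at ({cy}, {cx}) um extends outside the grid")
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d < diameter_um:
                raise InvalidSceneError(
                    f"beads {i} and {j} overlap (centre distance {d:.2f} um < {diameter_um} um)")

    ys = (np.arange(ny) + 0.5) * pitch_um
    xs = (np.arange(nx) + 0.5) * pitch_um
    phase = np.zeros(shape)
    k_dn = (2 * np.pi / wavelength_um) * (n_bead - n_medium)
    for cy, cx in centers:
        r2 = (ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2
        inside = r2 < R ** 2
        phase[inside] += k_dn * 2 * np.sqrt(R ** 2 - r2[inside])
    occupancy = float(np.mean(phase > OCCUPANCY_PHASE_FLOOR))
    return PhasePhantom(
        transmission=np.exp(1j * phase), true_phase=phase, occupancy=occupancy,
        pitch=pitch_um,
        truth={"diameter_um": diameter_um, "centers": centers,
               "peak_phase_rad": k_dn * diameter_um})


def make_organism_phantom(seed: int, count: int, pitch_um: float,
                          shape: tuple[int, int], max_phase_rad: float = 2.0,
                          ) -> PhasePhantom:
    """Microorganism-like scene: smooth elliptical blobs with internal
    sub-structure, deterministic for a given seed."""
    if count < 0:
        raise InvalidParameterError("count must be >= 0")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    H, W = ny * pitch_um, nx * pitch_um
    ys = (np.arange(ny) + 0.5) * pitch_um
    xs = (np.arange(nx) + 0.5) * pitch_um
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    phase = np.zeros(shape)
    for _ in range(count):
        a = rng.uniform(0.03, 0.08) * min(H, W)       # semi-axes, um
        b = a * rng.uniform(0.5, 0.95)
        cy = rng.uniform(a, H - a)
        cx = rng.uniform(a, W - a)
        th = rng.uniform(0, np.pi)
        dy, dx = Y - cy, X - cx
        u = (np.cos(th) * dy + np.sin(th) * dx) / a
        v = (-np.sin(th) * dy + np.cos(th) * dx) / b
        r2 = u ** 2 + v ** 2
        body = np.where(r2 < 1, np.cos(np.sqrt(np.clip(r2, 0, 1)) * np.pi / 2) ** 2, 0.0)
        # internal structure: a couple of gaussian organelles
        for _ in range(rng.integers(1, 4)):
            gy = cy + rng.uniform(-0.4, 0.4) * a
            gx = cx + rng.uniform(-0.4, 0.4) * b
            gs = rng.uniform(0.1, 0.25) * a
            body += 0.5 * np.exp(-((Y - gy) ** 2 + (X - gx) ** 2) / (2 * gs ** 2)) * (r2 < 1)
        phase += rng.uniform(0.5, 1.0) * body
    peak = phase.max()
    if peak > max_phase_rad:
        phase *= max_phase_rad / peak
    occupancy = float(np.mean(phase > OCCUPANCY_PHASE_FLOOR))
    return PhasePhantom(
        transmission=np.exp(1j * phase), true_phase=phase, occupancy=occupancy,
        pitch=pitch_um, truth={"seed": seed, "count": count, "max_phase_rad": max_phase_rad})


def check_gabor_density(phantom: PhasePhantom, limit: float = 0.1) -> DensityCheck:
    """Weak-diffraction (Gabor) density check: passes when the occupied
    fraction of the field does not exceed ``limit`` (boundary inclusive)."""
    return DensityCheck(passed=phantom.occupancy <= limit,
                        occupancy=phantom.occupancy, limit=limit)


def quiet_region(phantom: PhasePhantom, size_px: int = 50) -> tuple[int, int, int, int]:
    """A structure-free square pixel region (r0, r1, c0, c1), searched over
    the corners and edge midpoints of the field; used as phase-reference
    background in reconstructions."""
    ny, nx = phantom.true_phase.shape
    s = min(size_px, ny // 4, nx // 4)
    anchors = [(8, 8), (8, nx - s - 8), (ny - s - 8, 8), (ny - s - 8, nx - s - 8),
               (8, (nx - s) // 2), (ny - s - 8, (nx - s) // 2),
               ((ny - s) // 2, 8), ((ny - s) // 2, nx - s - 8)]
    best, best_occ = None, np.inf
    for r0, c0 in anchors:
        occ = float(np.mean(phantom.true_phase[r0:r0 + s, c0:c0 + s] > OCCUPANCY_PHASE_FLOOR))
        if occ < best_occ:
            best, best_occ = (r0, r0 + s, c0, c0 + s), occ
    return best
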