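"""Optical system description and run configuration.

Units convention: all lengths are micrometres (um) unless the key carries an
explicit ``_nm`` suffix (feature heights / thicknesses, matching the usual
way phase-target heights are quoted).
"""
from __future__ import annotations

import math
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .exceptions import InvalidParameterError

__all__ = ["OpticalConfig", "RunConfig", "SimulationConfig", "SweepConfig",
           "OutputConfig", "load_config", "dump_config", "study_optics"]


class OpticalConfig(BaseModel):
    """Parameters of the microscope layout.

    ``wavelength_um``
        Illumination (laser) wavelength in vacuum.
    ``magnification``
        Objective magnification M.  Object-space and image-space axial
        displacements relate through dz' = -M^2 dz.
    ``camera_pitch_um``
        Physical camera pixel size.  The effective object-space sampling is
        ``camera_pitch_um / magnification``.
    ``n_test`` / ``n_medium``
        Refractive index of the phase-target (or bead) material and of the
        surrounding medium.
    ``numerical_aperture``
        NA of the objective; used as a hard coherent pupil cut-off in the
        forward model.  ``None`` disables the pupil (ideal system).
    ``source_to_camera_um`` / ``source_to_object_um``
        Distances d and z defining the geometric hologram magnification
        MG = d/z; both infinite means collimated illumination (MG = 1).
    """

    model_config = ConfigDict(extra="forbid")

    wavelength_um: float = 0.45
    magnification: float = 10.0
    camera_pitch_um: float = 4.6
    n_test: float = 1.5185
    n_medium: float = 1.0
    numerical_aperture: Optional[float] = 0.28
    source_to_camera_um: float = math.inf
    source_to_object_um: float = math.inf

    @field_validator("wavelength_um", "magnification", "camera_pitch_um")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise InvalidParameterError(f"expected a positive value, got {v}")
        return v

    @model_validator(mode="after")
    def _check_indices(self) -> "OpticalConfig":
        if self.n_medium < 1:
            raise InvalidParameterError("n_medium must be >= 1")
        if self.n_test <= self.n_medium:
            raise InvalidParameterError(
                f"n_test ({self.n_test}) must exceed n_medium ({self.n_medium})")
        if self.numerical_aperture is not None and not 0 < self.numerical_aperture <= 1:
            raise InvalidParameterError("numerical_aperture must lie in (0, 1]")
        return self

    @property
    def object_pitch_um(self) -> float:
        """Effective object-space sampling interval (camera pitch / M)."""
        return self.camera_pitch_um / self.magnification


def study_optics() -> OpticalConfig:
    """The default optical layout used throughout the package's studies.

    10x / 0.28 NA objective, 450 nm laser, 4.6 um camera pixels (0.46 um
    effective object-space pitch), collimated illumination, phase targets of
    Corning Eagle XG glass (n = 1.5185) in air.
    """
    return OpticalConfig()


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["usaf", "beads", "organisms", "fluorescence"] = "usaf"
    shape: tuple[int, int] = (512, 512)
    height_nm: float = 150.0
    groups: list[int] = [7, 8, 9]
    chart_furniture: bool = True
    bead_diameter_um: float = 10.0
    n_bead: float = 1.59
    bead_medium: float = 1.33
    count: int = 5
    max_phase_rad: float = 2.0
    defocus_um: float = 1100.0
    noise_sigma: float = 0.02
    seed: int = 0
    # fluorescence frame parameters
    signal: float = 100.0
    background: float = 10.0
    fluor_noise_sigma: float = 9.78


class SweepConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    start_um: float = 300.0
    stop_um: float = 1800.0
    step_um: float = 50.0
    log_spaced: bool = False
    n_points: int = 18          # used when log_spaced
    group_under_test: int = 8
    threshold: float = 0.264
    seed: int = 0


class OutputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    directory: str = "out"


class RunConfig(BaseModel):
    """Top-level structured configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    optics: OpticalConfig = OpticalConfig()
    simulation: SimulationConfig = SimulationConfig()
    sweep: SweepConfig = SweepConfig()
    regions: dict[str, tuple[int, int, int, int]] = {}
    output: OutputConfig = OutputConfig()


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
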