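"""Pipeline runner tying configuration, simulation, reconstruction and
measurement together; every command writes its artifacts plus one structured
log line, and reruns with identical configuration and seed are bit-identical.
"""
from __future__ import annotations

import hashlib
import json
import os
import sys
import time
from typing import Optional

import numpy as np

from . import __version__
from .calibration import autofocus, defocus_sweep, sweep_phantom
from .config import RunConfig
from .exceptions import InvalidParameterError
from .io import write_complex_field, write_image, write_sidecar, write_table
from .phantoms import (check_gabor_density, make_bead_phantom,
                       make_organism_phantom, make_usaf_phase_target,
                       quiet_region)
from .qpi import background_phase_std, extract_phase, measure_target_thickness, unwrap_phase
from .reconstruct import gabor_reconstruct
from .fluor_metrics import metric_report
from .simulate import make_fluorescence_frame, simulate_gabor_hologram
from .wave_optics import Hologram

__all__ = ["run_pipeline", "build_phantom"]

COMMANDS = ("simulate", "reconstruct", "sweep", "qpi", "metrics")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _log(out_dir: str, command: str, config: RunConfig, **summary) -> None:
    record = {
        "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "command": command,
        "config_hash": _config_hash(config),
        "seed": config.simulation.seed,
        "versions": {"gaborscope": __version__, "numpy": np.__version__,
                     "python": sys.version.split()[0]},
        **summary,
    }
    with open(os.path.join(out_dir, "run_log.jsonl"), "a") as fh:
        fh.write(json.dumps(record, sort_keys=True, default=str) + "\n")


def build_phantom(config: RunConfig):
    sim = config.simulation
    optics = config.optics
    pitch = optics.object_pitch_um
    if sim.kind == "usaf":
        return make_usaf_phase_target(
            height_nm=sim.height_nm, n_test=optics.n_test, n_medium=optics.n_medium,
            wavelength_um=optics.wavelength_um, groups=sim.groups,
            pitch_um=pitch, shape=tuple(sim.shape),
            chart_furniture=sim.chart_furniture)
    if sim.kind == "beads":
        ny, nx = sim.shape
        H, W = ny * pitch, nx * pitch
        rng = np.random.default_rng(sim.seed)
        centers = []
        R = sim.bead_diameter_um / 2
        while len(centers) < sim.count:
            c = (rng.uniform(R, H - R), rng.uniform(R, W - R))
            if all(np.hypot(c[0] - o[0], c[1] - o[1]) >= sim.bead_diameter_um
                   for o in centers):
                centers.append(c)
        return make_bead_phantom(sim.bead_diameter_um, sim.n_bead, sim.bead_medium,
                                 optics.wavelength_um, centers, pitch, tuple(sim.shape))
    if sim.kind == "organisms":
        return make_organism_phantom(sim.seed, sim.count, pitch, tuple(sim.shape),
                                     sim.max_phase_rad)
    raise InvalidParameterError(f"cannot build a phase phantom of kind {sim.kind!r}")


def _cmd_simulate(config: RunConfig, out_dir: str) -> dict:
    sim = config.simulation
    if sim.kind == "fluorescence":
        ny, nx = sim.shape
        pitch = config.optics.object_pitch_um
        H, W = ny * pitch, nx * pitch
        centers = [(H * fy, W * fx) for fy, fx in
                   ((0.3, 0.3), (0.3, 0.7), (0.7, 0.35), (0.65, 0.75))]
        frame = make_fluorescence_frame(
            centers, sim.bead_diameter_um, sim.signal, sim.background,
            sim.fluor_noise_sigma, sim.seed, pitch, tuple(sim.shape))
        write_image(os.path.join(out_dir, "fluorescence.tif"),
                    frame.intensity.astype(np.float32))
        write_image(os.path.join(out_dir, "signal_mask.tif"),
                    frame.signal_mask.astype(np.uint8))
        write_image(os.path.join(out_dir, "bg_mask.tif"),
                    frame.bg_mask.astype(np.uint8))
        write_sidecar(os.path.join(out_dir, "truth.json"), frame.truth)
        return {"artifact": "fluorescence.tif"}
    phantom = build_phantom(config)
    density = check_gabor_density(phantom)
    holo = simulate_gabor_hologram(phantom, sim.defocus_um, config.optics,
                                   noise_sigma=sim.noise_sigma, seed=sim.seed)
    write_image(os.path.join(out_dir, "hologram.tif"),
                holo.intensity.astype(np.float32))
    write_image(os.path.join(out_dir, "true_phase.tif"),
                phantom.true_phase.astype(np.float32))
    write_sidecar(os.path.join(out_dir, "truth.json"),
                  {**phantom.truth, "defocus_um": sim.defocus_um,
                   "noise_sigma": sim.noise_sigma, "seed": sim.seed,
                   "occupancy": phantom.occupancy,
                   "gabor_density_ok": density.passed})
    return {"artifact": "hologram.tif", "occupancy": phantom.occupancy}


def _load_hologram(config: RunConfig, out_dir: str, hologram_path: Optional[str]):
    from .io import read_image
    path = hologram_path or os.path.join(out_dir, "hologram.tif")
    intensity = np.asarray(read_image(path), dtype=float)
    return Hologram(intensity, config=config.optics,
                    recorded_defocus=config.simulation.defocus_um)


def _cmd_reconstruct(config: RunConfig, out_dir: str,
                     hologram_path: Optional[str]) -> dict:
    holo = _load_hologram(config, out_dir, hologram_path)
    sim = config.simulation
    af = autofocus(holo, (max(0.0, sim.defocus_um - 200), sim.defocus_um + 200), 25.0)
    rec = gabor_reconstruct(holo, af.distance_um, mode="intensity")
    write_complex_field(os.path.join(out_dir, "reconstruction"), rec)
    return {"best_refocus_um": af.distance_um, "reliable": af.reliable}


def _cmd_sweep(config: RunConfig, out_dir: str) -> dict:
    sw = config.sweep
    if sw.log_spaced:
        values = np.geomspace(max(sw.start_um, 1.0), sw.stop_um, sw.n_points)
        values = np.unique(np.round(values, 1))
    else:
        values = np.arange(sw.start_um, sw.stop_um + sw.step_um / 2, sw.step_um)
    phantom = build_phantom(config)
    result = defocus_sweep(phantom, values, config.optics,
                           noise_sigma=config.simulation.noise_sigma,
                           seed=sw.seed, group_under_test=sw.group_under_test,
                           threshold=sw.threshold)
    n = write_table(os.path.join(out_dir, "sweep.tsv"), result.rows())
    write_sidecar(os.path.join(out_dir, "sweep_summary.json"),
                  {"optimum_um": result.optimum_um, "n_points": n})
    return {"optimum_um": result.optimum_um, "rows": n}


def _cmd_qpi(config: RunConfig, out_dir: str, hologram_path: Optional[str]) -> dict:
    phantom = build_phantom(config)
    if phantom.layout is None:
        raise InvalidParameterError("qpi command requires a USAF simulation")
    holo = _load_hologram(config, out_dir, hologram_path)
    bg = config.regions.get("background") or quiet_region(phantom)
    result = measure_target_thickness(holo, phantom.layout, bg,
                                      group=min(phantom.layout.groups))
    rec = gabor_reconstruct(holo, holo.recorded_defocus, mode="intensity")
    wrapped = extract_phase(rec, background_region=bg)
    unwrapped = unwrap_phase(wrapped)
    write_image(os.path.join(out_dir, "phase_wrapped.tif"),
                wrapped.values.astype(np.float32))
    write_image(os.path.join(out_dir, "phase_unwrapped.tif"),
                unwrapped.values.astype(np.float32))
    bg_std = background_phase_std(unwrapped, bg)
    report = {
        "phase_step_rad": result.phase_step_rad,
        "phase_uncertainty_rad": result.phase_uncertainty_rad,
        "thickness_nm": result.thickness_nm,
        "thickness_uncertainty_nm": result.thickness_uncertainty_nm,
        "background_phase_std_rad": bg_std,
        "details": result.details,
    }
    write_sidecar(os.path.join(out_dir, "qpi_report.json"), report)
    return {"thickness_nm": result.thickness_nm,
            "background_phase_std_rad": bg_std}


def _cmd_metrics(config: RunConfig, out_dir: str, image_path: Optional[str],
                 signal_mask_path: Optional[str], bg_mask_path: Optional[str]) -> dict:
    from .io import read_image
    image = np.asarray(read_image(image_path or os.path.join(out_dir, "fluorescence.tif")),
                       dtype=float)
    smask = read_image(signal_mask_path or os.path.join(out_dir, "signal_mask.tif")) != 0
    bmask = read_image(bg_mask_path or os.path.join(out_dir, "bg_mask.tif")) != 0
    rep = metric_report(image, smask, bmask, seed=config.simulation.seed)
    payload = {"snr": rep.snr, "snr_uncertainty": rep.snr_uncertainty,
               "sbr": rep.sbr, "sbr_uncertainty": rep.sbr_uncertainty,
               "n_signal": rep.n_signal, "n_background": rep.n_background}
    write_sidecar(os.path.join(out_dir, "metrics.json"), payload)
    return payload


def run_pipeline(config: RunConfig, command: str,
                 hologram: Optional[str] = None, image: Optional[str] = None,
                 signal_mask: Optional[str] = None, bg_mask: Optional[str] = None,
                 ) -> dict:
    """Execute one pipeline command; returns its summary dict.

    Artifacts land in ``config.output.directory``; a structured line per run
    is appended to ``run_log.jsonl`` recording the config hash, seed and
    package versions.
    """
    if command not in COMMANDS:
        raise InvalidParameterError(f"unknown command {command!r}; choose from {COMMANDS}")
    out_dir = config.output.directory
    os.makedirs(out_dir, exist_ok=True)
    if command == "simulate":
        summary = _cmd_simulate(config, out_dir)
    elif command == "reconstruct":
        summary = _cmd_reconstruct(config, out_dir, hologram)
    elif command == "sweep":
        summary = _cmd_sweep(config, out_dir)
    elif command == "qpi":
        summary = _cmd_qpi(config, out_dir, hologram)
    else:
        summary = _cmd_metrics(config, out_dir, image, signal_mask, bg_mask)
    _log(out_dir, command, config, **summary)
    return summary
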