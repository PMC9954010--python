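# gaborscope

Simulation, reconstruction and calibration toolkit for a **combined
fluorescence + in-line (Gabor) holographic microscope** — a dual-mode
instrument that records, in one snapshot, a fluorescence image and an
in-line hologram of the same specimen using a single illumination
wavelength.

The package covers the computational side of such an instrument, for
microscopists and instrument builders who want to prototype, calibrate, or
quantify this kind of layout without hardware:

* **Scalar wave optics** — free-space propagation by the angular-spectrum
  transfer function `H(u,ν;d) = exp(i·(2πd/λ)·√(1−(λu)²−(λν)²))`, the exact
  spectral form of the Rayleigh–Sommerfeld diffraction solution, computed
  with three FFTs: `U_d = IFFT[FFT[U]·H]`.
* **Synthetic scenes** — USAF-1951-style phase resolution targets, spherical
  bead phantoms (chord-length phase model), microorganism-like blobs, and
  fluorescence bead frames, all with ground truth attached.
* **Hologram forward model** — coherent pupil cut-off at the objective NA,
  object-space propagation over the recording defocus Δz, intensity
  detection with multiplicative noise.
* **Defocus calibration** — autofocus, finest-resolved-element scoring, the
  phase contrast parameter Δφ = mean(maxima) − mean(minima), and the defocus
  sweep that locates the optimal recording distance (related to the camera
  shift by Δz′ = −M²Δz).
* **Quantitative phase imaging (QPI)** — phase extraction, 2-D unwrapping,
  phase-step measurement, and thickness retrieval via
  `Δt = λ·Δφ / (2π·(n_test − n_medium))`.
* **Fluorescence metrics** — SNR = (mean signal − mean background)/STD(background)
  and SBR = mean signal / mean background, with bootstrap uncertainties.

## Worked example

Calibrate the recording defocus on a synthetic 150 nm phase target, then
measure a target's height end to end:

```python
import numpy as np
import gaborscope as g

optics = g.study_optics()          # 10x/0.28NA, 450 nm, 4.6 um camera pixels

# --- defocus calibration sweep
target = g.sweep_phantom(optics)   # USAF groups 7-9 + chart furniture, 512^2
sweep = g.defocus_sweep(target, [5, 15, 30, 50, 80, 120, 170, 230, 300,
                                 400, 500, 650, 800, 1000, 1200, 1500, 1800],
                        optics, noise_sigma=0.02, seed=3)
best = np.nanmin(sweep.resolution_um[np.isfinite(sweep.resolution_um)])
print(f"best resolution {best:.2f} um at optimum defocus {sweep.optimum_um:.0f} um")

# --- quantitative phase measurement of a 150 nm target
qpi_target = g.make_usaf_phase_target(150, optics.n_test, optics.n_medium,
                                      optics.wavelength_um, [6],
                                      optics.object_pitch_um, (1024, 1024))
holo = g.simulate_gabor_hologram(qpi_target, 1100.0, optics, noise_sigma=0.02, seed=1)
bg = g.quiet_region(qpi_target, 100)
res = g.measure_target_thickness(holo, qpi_target.layout, bg)
print(f"phase step {res.phase_step_rad:.2f} rad -> "
      f"thickness {res.thickness_nm:.0f} +- {res.thickness_uncertainty_nm:.0f} nm")
```

Output:

```
best resolution 1.74 um at optimum defocus 500 um
phase step 0.75 rad -> thickness 103 +- 14 nm
```

The sweep's best resolution, 1.74 µm, is the coherent limit of the 0.28 NA
objective (λ/NA ≈ 1.6 µm; the finest element whose period exceeds it).  The
measured height of the 150 nm target comes out low (~103 nm): a single-shot
in-line reconstruction carries the out-of-focus conjugate (twin) image,
whose low-spatial-frequency residue overlaps the bars and systematically
suppresses the measured step.  This bias is intrinsic to the Gabor geometry
(twin-image suppression is a separate problem outside this package's scope);
`docs/methods.md` quantifies it.

## Command line

```bash
gaborscope simulate    -c config.yaml   # phantom + hologram (or fluorescence frame)
gaborscope reconstruct -c config.yaml   # autofocus + amplitude/phase TIFFs
gaborscope sweep       -c config.yaml   # defocus calibration table
gaborscope qpi         -c config.yaml   # phase step, thickness, background STD
gaborscope metrics     -c config.yaml   # fluorescence SNR / SBR report
```

The YAML configuration schema is defined (and strictly validated — unknown
keys are rejected) in `gaborscope.config.RunConfig`.  All lengths are in
micrometres except feature heights, which carry a `_nm` suffix.  Pixel
regions are 0-based, row-major, half-open rectangles `(r0, r1, c0, c1)`.

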