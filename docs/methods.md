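# Methods

This note documents the physical models, numerical choices, and known
limitations of the package.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Propagation model

Free-space propagation is the angular-spectrum / Rayleigh–Sommerfeld
transfer function

    H(u, ν; d) = exp( i (2π d / λ) √(1 − (λu)² − (λν)²) ),

applied between two FFTs.  This is the exact spectral form of the first
Rayleigh–Sommerfeld solution — no Fresnel or Fraunhofer approximation — and
is valid at the sub-millimetre distances and ~0.5 µm pitches the instrument
works at.  Conventions:

* time dependence `exp(−iωt)`; positive `d` propagates away from the source,
  so `H(−d) = conj(H(d))` on propagating frequencies and back-propagation is
  the exact inverse;
* evanescent frequencies (`λ²(u²+ν²) > 1`) decay as
  `exp(−(2π|d|/λ)√((λu)²+(λν)²−1))` by default (physically correct and
  numerically stable); a `zero` policy is available;
* without padding the operator is exactly unitary on the periodic grid, so
  energy conservation, the group property `P(d₁)∘P(d₂) = P(d₁+d₂)`, and
  invertibility hold to machine precision and are asserted as tests;
* for reconstruction and simulation the grid is symmetrically padded to 2×
  its linear size (with the background level, so the field continues
  smoothly) to suppress wrap-around of the circular convolution, then
  cropped.  Oracle tests run unpadded on small grids against an explicit
  non-FFT spectral summation.

All simulation happens in object space at the effective pitch
(camera pitch / M = 4.6/10 = 0.46 µm by default).  Propagating the object
over Δz there is mathematically identical to propagating the magnified image
over Δz′ = −M²Δz at the camera; the conversion functions live in the
calibration module and are only used for reporting.

## Study conditions and scaling

The default optical layout (`study_optics()`) is a 10×/0.28 NA objective,
450 nm laser, 4.6 µm camera pixels, collimated illumination
(geometric hologram magnification MG = d/z = 1), and a phase-target material
of n = 1.5185 in air.

Simulated fields are 512×512 (calibration sweeps) or 1024×1024 (quantitative
phase), i.e. windows of 236 µm and 471 µm in object space, versus ~590 µm
for the physical 1280-pixel camera.  The window acts as an aperture: a
hologram half-window `W/2` at defocus `d` only captures rays up to
`NA_w ≈ (W/2)/d`.  Consequently the defocus range over which a given USAF
group stays resolvable scales with the window, and the optimal-defocus
plateau of the scaled sweep sits at a few hundred µm rather than at the
~1 mm of the full-size instrument.  The *shape* of the calibration curve and
the best achievable resolution (NA-limited) are window-independent; the
numeric location of the plateau is not, and no test asserts it.

Hologram noise is multiplicative Gaussian on intensity with relative scale
0.02 — a plain proxy for laser power fluctuation and shot noise on an 8-bit
camera.  Real in-line recordings additionally carry structured coherent
noise (parasitic interference, dust diffraction), which this model does not
emulate; simulated background-phase STD is accordingly ~0.01 rad where a
physical instrument shows ~0.1–0.2 rad.  Fluorescence frames use additive
Gaussian noise on dark-subtracted counts (negative excursions retained, so
sample statistics match the generating parameters; a clip-at-zero option
models raw counts).

The Gabor (weak-diffraction) condition is tracked as pixel occupancy: the
density check passes at ≤ 10% occupied area (boundary inclusive).  The
10% limit is this package's documented default; "low density" is otherwise a
qualitative notion.

## Synthetic targets

USAF-style targets follow the 1951 geometry: element (g, e) has spatial
frequency 2^(g+(e−1)/6) lp/mm; bars are period/2 wide and 5 bar-widths long,
three per orientation, rendered by exact area-weighted rasterisation with
uniform phase 2π(n_test−n_medium)h/λ.  Each rendered target carries its
layout (bounding boxes, bar/gap centre coordinates, periods), so scoring
never needs registration.  `chart_furniture=True` adds the solid reference
squares and coarse bars that surround the fine groups of a commercial chart;
they matter because their twin-image artifacts are what degrade small-defocus
reconstructions in a realistic scene.

Beads use the chord-length model φ(r) = (2π/λ)Δn·2√(R²−r²); overlapping
beads are rejected rather than summed (dilute counting-chamber preparation).
A 10 µm polystyrene bead in water at 450 nm carries a 36.3 rad peak —
deliberately several wraps, to exercise unwrapping.

## Reconstruction and the twin image

`refocus` implements the textbook composition: amplitude = √intensity, then
propagation.  For quantitative phase the package instead back-propagates the
*background-normalised intensity* (`gabor_reconstruct(..., mode="intensity")`).
The reason: with I = |1+O|² = 1 + 2 Re O + |O|², back-propagating I yields
1 + o + twin + junk whose direct term is exactly `exp(iφ)` for a thin phase
object, while √I ≈ 1 + Re O halves the scattered wave and returns ~φ/2.

No single-shot in-line reconstruction removes the conjugate (twin) term
P₋₂d[o*].  Its high-frequency content walks off the object by ~2dλ/p and
dilutes, but frequencies below ~1/√(2λd) never leave the object footprint.
This low-frequency twin residue adds a background-level offset around the
bars that systematically *suppresses* the measured phase step — by roughly
5–15% at 50 nm heights and 15–25% at 150 nm under the default conditions
(the acceptance script prints the measured values).  Averaging
reconstructions over several recording distances does not remove it (the
residue is defocus-insensitive), and deterministic twin suppression is out
of scope here.  End-to-end thickness numbers from this package therefore
carry a known negative bias of that order, comparable to the accuracy a
physical Gabor layout achieves; treat them as lower bounds.

The global propagation piston is removed by rotating the field so a
structure-free background region has real-positive complex mean
(`reference_to_background`); without it the background can sit near ±π and
wrap spuriously.

## Autofocus

The focus metric is the normalised variance of the reconstructed amplitude,
*minimised* at focus: a weak phase object is invisible in focus, so
amplitude contrast dips exactly at the object plane.  (Gradient-energy
metrics such as Tenengrad are kept as options but are unreliable here: the
hologram's own fringes are sharp, so gradient energy can peak at the search
floor.)  Two protections make the dip detection robust:

* the coarse metric curve is normalised by a wide median filter before
  taking the arg-min, so slow monotone trends — energy drifting out of the
  window at large distances — cannot outvote the genuine dip;
* a fine pass (default step/5) brackets the coarse pick; resolving the
  finest elements needs focus accuracy of order p²/λ ≈ 10–20 µm, which the
  default fine step of the sweep (8 µm) provides.

A flat metric curve (empty hologram) is flagged unreliable and the candidate
closest to zero is returned.  In sweeps, autofocus searches a ±100 µm
bracket around the nominal stage position, which is always approximately
known to the experimenter.

## Resolution criterion and contrast parameter

The reported contrast parameter is the field definition
Δφ = mean(maximum peaks) − mean(minimum peaks), computed plateau-aware on
the bar-orthogonal profile.

Resolvedness uses a stricter Rayleigh-dip reading: an element counts as
resolved when the mean reconstructed phase at its three bar centres exceeds
the mean at its two gap centres by at least 26.4% of the target's nominal
phase step, in both orientations.  Peak detection alone can report spurious
"resolution" below the diffraction limit (ringing of the unresolved block
envelope produces peaks); sampling at the known bar/gap centres cannot.
The 26.4% threshold is a documented stand-in for the visual
"last resolved element" judgement; the walk proceeds coarse → fine and stops
at the first unresolved element, as a chart is read.

The sweep's resolution-vs-defocus curve is U-shaped: at very small defocus
no phase contrast develops (the contrast transfer of coarse elements
vanishes as d → 0, and twin artifacts of the chart furniture sit right on
the bars), and at large defocus the window aperture bounds the capturable
diffraction angle.  The optimum is the median defocus of the contiguous run
of best resolution, ties broken toward the run holding the contrast maximum.
Quadratic fits to sweep curves are a presentation device only; optimum
selection always uses the raw plateau rule.

## Phase-step measurement

`phase_step` averages the region across its short axis, lightly smooths
(quarter-period window), finds extrema with a minimum separation of 0.6
periods, classifies them against the profile mid-range (so noise bumps on
ramps cannot join the wrong population), reads each extremum as a local mean
of the raw profile, and reports mean(maxima) − mean(minima) with the two
population STDs combined in quadrature as the uncertainty — the latter
because the ± on a measured step is otherwise undefined.

`measure_target_thickness` uses a robust variant (median of the
above-mid-range samples minus median of the below-mid-range samples over the
central 60% of the bar length), which is insensitive to band-limit ringing
on the plateaus, then converts through Δt = λΔφ/(2πΔn).

2-D unwrapping is delegated to scikit-image's reliability-ordered algorithm;
the package asserts the algorithm-independent contract (congruence mod 2π at
every pixel, monotone unwrapped bead profiles over the central 60% of the
radius — bead edges are unrecoverable at 0.28 NA, so only the central cap is
meaningful).

## Fluorescence metrics

SNR and SBR follow the stated definitions on pooled pixels of explicit
masks; masks are inputs, never segmented automatically.  Uncertainties are
seeded bootstrap (200 resamples) over pixels.  The synthetic frame for SNR
work uses signal 100, background 10, σ = 9.78 counts — levels at which the
measured SNR sits near 9; the SBR scene uses a 29.5/10 ratio.  Whether means
should be per-bead or pooled is a convention choice; pooled is implemented.

## What passing tests do and do not show

The simulator exercises the full reconstruction chain under controlled
truth, so the tests demonstrate correctness of the numerics (propagation,
unwrapping congruence, metric formulas, geometry) and the *behaviour* of the
calibration procedure (U-shaped sweep, autofocus recovery, parameter
recovery envelopes).  They do not demonstrate instrument-level accuracy on
real data: partial coherence, aberrations, camera MTF, divergence of the
illumination (MG ≠ 1) and structured coherent noise are all outside the
forward model, and the twin-image bias bounds any single-shot quantitative
claim as described above.
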