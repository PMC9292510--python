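# Methods

This note records how `thex` constructs and evaluates mono-planar
tilted-hexagonal (T-Hex) trajectories. All symbols below are in SI units.

## Tilted-hexagonal cross-section lattice

The target sampling pattern in the (k1, kz) cross-section of a stack
trajectory is a hexagonal lattice with basis `e1 = dk (1, 0)` and
`e2 = dk (1/2, √3/2)`, tilted so that one lattice vector
`v = M1 e1 + M2 e2` lies along the in-plane axis k1. The integer *tilt
index* `(M1, M2)` with `M1 ≥ M2 ≥ 0`, `(M1, M2) ≠ (0, 0)` selects one
representative per dodecant of the lattice symmetry group.

From the tilt follow the shot-level quantities (`thex.hexlattice.shot_geometry`):

- per-shot radial increment `d = dk √(M1² + M1·M2 + M2²)` — the spacing of
  lattice columns along k1;
- plane spacing `h = dk² √3 / (2d)` — the spacing of lattice rows along kz
  (so `d·h = dk² √3/2`, the hexagonal cell area, independent of tilt);
- in-plane offset increment `c`, with the offset of shot j being
  `frac(j·c/d)·d`;
- repetition length `L = 2(M1² + M2² + M1·M2) / gcd(2M2 + M1, 2M1 + M2)`,
  the period of the offset sequence. For tilt (2, 1), `c/d = 5/14` and
  `L = 14`.

For non-primitive tilts (`g = gcd(M1, M2) > 1`) the rows sit at spacing
`g·h` and each kz plane carries `g` interleaved shots at within-row spacing
`d/g`; the offset sequence is periodic modulo `d/g`. The closed-form `L` is
verified in the tests against a brute-force period oracle for all tilts with
`M1 ≤ 7`.

The cross-section point set equals the hexagonal lattice mapped by the
orthogonal reflection `T = [[vx, vy], [vy, −vx]]/d`, and all points embed in
the fine rectangular grid `(d/L) × h` — both properties are asserted
exactly in the tests, as is uniform Voronoi cell area (CV < 1e-9).

## Protocol rescaling and undersampling

A protocol is specified by FOV, voxel size, undersampling factor R, and
optional TE / TR / shot count (`thex.spiral.SequenceGeometry`). The unit
lattice is rescaled anisotropically so that the *encoded* density matches
the fully sampled lattice constants `Δi = 1/FOVi` diluted by a factor whose
product is R: the cell-area identity `s1·s2·√3/2 = R·gain·Δ1·Δ2` fixes the
per-axis scales (isotropic split by default, optional anisotropy override,
elliptical-FOV gain 2/√3). Because R enters only as a continuous rescale,
any real R ≥ 1 is admissible — there is no integer-interleave constraint.

Shots are assigned one kz plane each, symmetric about kz = 0 with spacing
`h` covering ±kmax_z; plane j's spiral (or EPI train) is offset in-plane by
`frac(j·c/d)·d` and, for spirals, rotated by `j·2π·c/d`.

## Gradient design

Waveforms are designed time-optimally along the geometric path
(`thex.gradients.design_waveform`): a forward/backward speed sweep under
the amplitude limit `γ̄·|G| ≤ v` and the curvature-aware slew limit, then
raster resampling at 10 µs with exact endpoint closure. Validation
(`validate_waveform`) checks peak |G|, peak vector slew including the
first/last raster steps, and the maximum deviation of the integrated k-path
from the analytic path (tests require < Δk/100).

EPI trains (`epi_train`) use trapezoidal flat-tops with blipped
turnarounds. With ramp sampling (the default) the line coverage closes at
the turnaround apex: the flat amplitude G is sized so that
`γ̄·G·(t_flat + t_turn/2) = 2·kmax` holds exactly on the raster, and line
handover happens at the apex so every line sweeps monotonically across the
full kx range. Per-shot TE shifts `esp·frac(j·c/d)` stagger the echo trains
so the acquisition-time map over the cross-section is an affine function of
(k1, kz) — the `epi_time_affinity` residual is ~1e-16·esp for the
whole-brain protocol.

## Acquisition-time smoothness

Because every kz plane is visited exactly once, the spread of absolute
acquisition times within any plane is at most one readout duration
(`thex.analysis.plane_time_spread`); T2* then acts as a smooth, benign
filter over k-space. An integer-N interleaved comparator revisits each
plane N times and spreads a plane's weighting over ≈ N·TR
(`cartesian_plane_time_spread`), which is the negative control in the tests.

## Scan-time study

`scan_time_study` tabulates minimum total scan time (shots × TR, TR =
readout + fixed per-shot overhead) for all tilts up to a given `d/dk` and
for Cartesian comparator stacks with integer interleave N, at matched
encoded ellipse and matched R. The hexagonal family admits a dense set of
per-shot increments `d/dk ∈ {1, √3, 2, √7, 3, …}` versus the integers for
the comparator, and wins at every resolution studied (0.4/0.6/0.8 mm).

## Simulation and reconstruction

The NUFFT (`thex.nufft.GriddingNufft`) is a hand-written Kaiser–Bessel
gridding interpolator (oversampling 2, kernel width 10) with deapodization, tested
against brute-force DFT oracles to 1e-6 and adjoint-consistent to 1e-12.
`thex.synthsim` provides a deterministic smooth ellipsoid phantom, smoothly
varying coil sensitivities normalized to unit sum-of-squares, signal
simulation with optional mono-exponential T2* decay and seeded complex
noise, and CG-SENSE reconstruction (conjugate gradients on the normal
equations, optional T2* modelling).

## Known discrepancy: EPI readout duration

An external published figure quotes ≈ 14 ms per-shot readout for the
whole-brain EPI protocol (0.7 mm in-plane, 24 cm FOV, R = 8, tilt (2, 1),
86 shots, 31 mT/m / 200 T/m/s). The faithful design yields 32.76 ms: at
matched encoded density the train must cover 26 lines per shot at an echo
spacing of 1.26 ms, which is already within ~1.2× of the amplitude-limited
ideal — no raster or ramp-sampling dialect recovers a factor ~2.3. The
corresponding acceptance test is left failing at its stated tolerance, and
`scripts/acceptance.py` reports the honest value (33 ms rounded). See the
design notes ledger for the full arithmetic.
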