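# Methods

## Transport model

Tracer spread along the neuraxis is reduced to one spatial dimension:

    ∂C/∂t = ∂/∂x( D_eff ∂C/∂x ) − U_fsi ∂C/∂x + n_inj(x, t) − R(C)

* **Domain.** Closed (zero-flux) interval of 48 cm on the bench ruler,
  default [6, 54] cm, with x increasing caudally. The lumbar injection site
  defaults to x = 50 cm, i.e. 4 cm from the caudal end — the asymmetry that
  produces the caudocranial drift (below). Cranial motion is toward
  decreasing x; reported caudocranial velocities (CCV) are sign-flipped to
  be positive craniad.
* **Source.** n_inj is a top-hat over one needle inner diameter (floored at
  two grid cells), constant in rate over the infusion phase (phase-1,
  default 1 min). The source shape is a modelling choice; at the grid
  scales used it is effectively a point release.
* **Convection.** U_fsi models the injection-impulse drift arising from
  fluid–structure interaction of the infusate with the deformable dura. It
  has no published functional form; we close the model with a constant
  craniad speed active only during phase-1. When not supplied explicitly,
  `pkmodel.calibrate_ufsi` bisects it so that the simulated 10-min cranial
  front advance equals half the DD₁₀ guideline prediction for the
  configured needle and flow rate (the moving front advances at least half
  the dispersion width).
* **Dispersion.** D_eff [cm²/min] is scalar by default; a per-position
  profile (e.g. increasing craniad, mimicking the graded CSF pulse
  amplitude) is accepted. In scenario runs D_eff comes from the pulsation
  dispersion law evaluated at the configured stroke volume and frequency.
* **Sink.** First-order elimination R = k·C, default k = 0 (inert tracer);
  available for drug half-life/clearance exploration.

### Discretization

Conservative finite volume on a uniform grid (default 480 cells, 0.1 cm):
harmonic-mean diffusive fluxes, first-order upwind advection, backward-
Euler (implicit) time stepping (default dt = 0.01 min), zero-flux at both
ends. Step edges are aligned with the injection window and requested output
times, so injected mass is accounted exactly; with zero sink the discrete
total mass is conserved to direct-solver precision (~1e−13 relative,
audited by `pkmodel.mass_balance`). The scheme is unconditionally stable;
an advective Courant number above 2 is nevertheless rejected with a
suggested dt, because first-order upwinding at such steps would be
inaccurate. Validation against closed forms (Gaussian variance growth
2·D·t, centroid advection u·t) and a brute-force explicit oracle
(diffusion-limited dt, same fluxes) holds to <0.5 % in L2; halving the
cell size changes the standard 10-min profile by <0.5 % in L2.

## Optical model and inversion

The renderer (`synthetic_data.render_frames`) is the forward model of the
bench videography: concentration maps linearly to a white→blue colour ramp
(R = G = 255·(1 − C/C_sat), B = 255), so the white-offset grayscale
intensity (Rec. 601 luma weights 0.299/0.587/0.114) is proportional to
concentration. Frames are 64×960 px at 0.05 cm/px (declared defaults — the
bench camera geometry is not published); the dyed tube occupies the central
rows, with 8 dye-free background rows at top and bottom. Stressors:

* additive Gaussian pixel noise, default sd 2 (8-bit counts), seeded;
* a multiplicative linear lighting ramp, default 10 % darkening across the
  frame — the simplest stand-in for uneven illumination;
* uniform dither before 8-bit rounding, so quantization error is not
  spatially correlated with the smooth profile (undithered rounding biases
  the profile centroid by ~0.02 cm).

The inversion (`imaging.frames_to_profiles`) divides each tube column by a
white reference interpolated from the background rows of the same column,
which cancels any multiplicative lighting field exactly; columns below
1.5 % of the frame maximum are zeroed before AUC scaling. This noise floor
matters: clipping intensities at zero rectifies pixel noise into a positive
background that drags moments toward the frame center. The 1.5 % default
balances that floor against tail truncation; with it, the render→invert
round trip preserves the first moment within half a pixel (0.025 cm) and
recovers generating dispersion coefficients to ~3–5 % at the default noise
scale (10 % is the acceptance bound).

## Moment estimation

Moments use trapezoidal quadrature on the native grid (profiles are smooth
and densely sampled). CCV and D_exp are OLS slopes of x̄(t) and σ²(t) over
a configurable window, default 1–10 min (phase-2); the snapshot cadence is
1/min. The window must end before the closed-domain boundaries bias the
variance slope: for recovery benchmarks with the release centered in the
domain we fit 1–8 min, which keeps the caudal/cranial walls beyond ~3σ for
the largest dispersion tested (4.7 cm²/min). Negative fitted slopes
(possible under noise) are flagged, not clamped, preserving the estimator's
sampling distribution. Confidence intervals are t-based on the OLS
standard error.

## CSF pulsation kinematics

The volume waveform V(t) = V₀ + v_c/2 − (v_c/2)·cos ωt gives the
cross-section-average velocity u = (dV/dt)/A and the closed form
U_rms = v_c·ω/(2√2·A). (The waveform-squared expression sometimes written
as (V/A)² is dimensionally a velocity only when V is read as dV/dt; we
implement the RMS of dV/dt over A.) The hydraulic cross-section A of the
spinal subarachnoid space is not directly published; the default
A ≈ 4.78 cm² is back-solved so that the pump endpoint (v_c = 1 mL,
f = 120 bpm) reproduces the top of the published physiological velocity
range, 0.93 cm/s. Dimensionless groups use the published constants
D₀ = 1.938×10⁻⁶ cm²/min (trypan blue), D_H = 0.5 cm, ν = 7×10⁻³ cm²/s;
the Peclet length scale defaults to D_H, and U_rms enters Pe in cm/min for
unit consistency with D₀. The Womersley number uses the radius D_H/2
(standard definition).

## Correlations and presets

All logarithms are base 10. The published coefficient sets are shipped as
a versioned JSON resource (`itdisp/data/paper_model.json`) and every fit
operation (`fit_dd10`, `fit_logD`, `fit_dimensionless`) is the exact OLS
inverse of its predictor on noiseless data — a fixed-point property the
tests enforce at 1e−8. Design-rank checks name unidentifiable terms (e.g.
the quadratic frequency offset at a single frequency). Plain OLS with
t-intervals is used throughout; no multiple-testing correction is applied.

Two readings exist for the published CCV line constants (0.3014, 0.0012):
slope/intercept or intercept/slope. The slope reading would make CCV
strongly frequency-dependent, contradicting the reported near-flat
behaviour, so the default is CCV = 0.3014 + 0.0012·f [cm/min], with the
literal reading available behind a flag.

### Guideline tables

* The DD₁₀ table (6 diameters × 5 flow rates) regenerates the published
  grid to ≤0.05 cm in 29 of 30 cells; the (0.50 mL/min, 0.2 mm) cell is
  printed as 20.06 where the regression gives ≈21.02 and its own
  row/column trend demands a value between 20.34 and 20.63 — a suspected
  typo, flagged and excluded from assertions.
* The clinical dispersion table (4 frequencies × 5 stroke volumes) cannot
  be regenerated without the unpublished hydraulic area and U_rms unit
  convention. We calibrate A analytically on the single printed anchor
  cell (40 bpm, 0.5 mL/beat) = 1.63 cm²/min — giving A ≈ 1.35 cm², which
  differs from the velocity-calibrated 4.78 cm²; the inconsistency is
  inherent to the published numbers. The regenerated grid then matches the
  print to <0.5 % at 40 and 60 bpm but runs ~9 % low at 80 bpm and ~21 %
  low at 100 bpm: under U_rms ∝ f the dispersion law is non-monotone in f
  beyond ~93 bpm (vertex of κ·log₁₀ U_rms + λ(f)), while the printed grid
  increases monotonically. Deviations are therefore reported
  (`compare_table2`), not asserted.

### Taylor–Aris comparison

`taylor_divergence_report` evaluates, over the experimental condition grid
(stroke volumes 0.5/1.0 mL at 40–127 bpm), the theoretical enhancement
1 + λ·Peᵏ for a chosen shear-dispersion variant against the experimental
dispersion law's D_exp/D₀. With Watson's oscillatory coefficients the
theory overshoots by ~10⁴–10⁵ (asserted ≥10³). The dimensionless-law
(φ-preset) ΔD is also tabulated for reference; its ratio to theory is
smaller (~10²–10³) because the published φ set is not numerically
consistent with the dimensional law under any single unit convention —
both presets are kept verbatim and the gap is surfaced in the report
rather than hidden.

## Synthetic-data generator: scope

The generator emulates (i) RGB frame stacks whose blue-dye intensity
encodes a 1D advection–diffusion concentration field with pixel noise and
uneven lighting, and (ii) the N = 54 factorial infusion campaign (3 needle
diameters × 3 flow rates × 2 stroke volumes × 3 frequencies), drawing
DD₁₀, CCV and D_exp from the correlation presets with seeded Gaussian
scatter. Default noise levels are the study conditions: the DD₁₀ sd is
derived from the published fit R² = 0.7916 at the 54-run design (≈1.3 cm),
and the D_exp sd is the published between-repeat variability 0.29 cm²/min.
Everything is bit-reproducible under a fixed seed.

Not emulated: 2D/3D flow structure, the injection jet, nerve-root-resolved
mixing, photorealistic optics (scattering, refraction, calibration-curve
nonlinearity), cardiac-gated acquisition, and pressure. Passing round-trip
tests therefore demonstrates the correctness and robustness of the
*analysis chain* — inversion, moments, fits — under the modelled
disturbances, not the fidelity of any particular bench optic.

## Known limitations

* The 1D model collapses cross-sectional structure into D_eff and U_fsi;
  it cannot represent the injection jet or eccentric catheter placement.
* The U_fsi closure (constant during phase-1, calibrated to the DD₁₀
  guideline) is one of several defensible choices; front-advance
  predictions inherit its uncertainty.
* The dispersion law is an empirical fit over U_rms ≈ 5–56 cm/min and
  f ≤ 127 bpm; extrapolation beyond that range (including the f > 93 bpm
  roll-off) reflects the quadratic offset, not physics.
* Problem sizes in the test suite (480-cell grids, 1-min snapshots,
  100-seed Monte-Carlo loops) are chosen to exercise every code path at
  desk scale; they are smaller than what one would use for production
  simulation studies.
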