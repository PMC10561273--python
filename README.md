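# itdisp — intrathecal tracer dispersion analysis

`itdisp` quantifies how a tracer (or drug) injected into the spinal
subarachnoid space spreads along the neuraxis under pulsating cerebrospinal
fluid (CSF). It is aimed at researchers studying intrathecal (IT) drug
delivery with bench phantoms or reduced-order models: it turns tracer
videography into calibrated 1D concentration profiles, estimates transport
parameters by the method of moments, evaluates empirical dosing guidelines,
and predicts spatiotemporal drug distribution with a 1D
convection–diffusion model.

## The science in brief

**Optical inversion.** Video frames of a transparent spine phantom encode
dye concentration as a white→blue colour change. Frames are converted to
grayscale (Rec. 601 luma), intensities inferred by white offset
(white = no dye), column-averaged across the tube, lighting-corrected
against dye-free background rows, and AUC-scaled so each profile integrates
to the injected amount, giving C(x, t) along the neuraxis.

**Method of moments (MoM).** For a profile C(x, t) on x ∈ [x₀, xₘ]:

    x̄(t)  = ∫ C·x dx / ∫ C dx                 (center of gravity)
    σ²(t) = ∫ (x − x̄)²·C dx / ∫ C dx          (spread)

The caudocranial velocity is CCV = −d x̄/dt (x increases caudally; cranial
motion is positive), and the apparent dispersion coefficient is
D_exp = ½ · dσ²/dt, both taken as ordinary-least-squares slopes over the
post-infusion window. Because moments are invariant to rescaling C, the
estimates are robust to uneven lighting and intensity mis-calibration.

**Empirical correlations.** Three published regression families ship as a
versioned preset:

* DD₁₀ = a·ND + b·IVF + c — dispersion width 10 min after injection vs
  needle inner diameter ND [mm] and infusion flow rate IVF [mL/min], with
  (a, b, c) = (−1.4150, 2.8786, 19.8668);
* log₁₀ D_exp = λ(f) + κ·log₁₀ U_rms with κ = 0.7419 and a quadratic
  frequency offset λ(f) — dispersion driven by CSF pulsation, where
  U_rms = v_c·ω/(2√2·A) is the RMS oscillatory CSF velocity set by the
  cervical stroke volume v_c and pulse frequency f;
* log₁₀ ΔD = φ₀ + φ₁α + φ₂α² + K·log₁₀ Pe — the dimensionless form in
  Peclet (Pe = U_rms·h/D₀) and Womersley (α = (D_H/2)·√(ω/ν)) coordinates.

Classical Taylor–Aris shear dispersion, D_exp/D₀ = 1 + λ·Peᵏ (κ = 2 steady,
κ = 1.88 oscillatory per Watson), predicts dispersion orders of magnitude
faster than these correlations at spinal Pe (~10⁶–10⁷): geometry-induced
mixing around nerve roots follows a much shallower power law.

**Reduced-order transport model.** Tracer biodistribution obeys

    ∂C/∂t = ∂/∂x(D_eff ∂C/∂x) − U_fsi ∂C/∂x + n_inj(x, t) − R(C)

in a closed 48-cm domain: an injection-driven convection U_fsi during the
1-min infusion (phase-1), effective dispersion D_eff thereafter (phase-2),
and an optional first-order sink. The solver is a conservative implicit
finite-volume scheme; it doubles as the ground-truth generator for the
synthetic videography, so the whole pipeline is testable without lab data.

## Worked example

```python
import numpy as np
from itdisp import correlations, csf_dynamics, imaging, moments, synthetic_data

# clinical guideline: initial spread for a thin catheter at 2 mL/min
dd10 = correlations.predict_dd10(nd=0.2, ivf=2.0)
print(f"DD10 = {dd10:.2f} cm")

# pulsation setting -> kinematics and dimensionless numbers
state = csf_dynamics.CSFState(vc=0.5, f=40.0)
u = csf_dynamics.urms(state, units="cm/min")
print(f"Urms = {u:.2f} cm/min, Pe = {csf_dynamics.peclet(u):.3g}, "
      f"alpha = {csf_dynamics.womersley(40.0):.2f}")
print(f"Dexp (dispersion law) = {correlations.predict_logD(u, 40.0):.3f} cm2/min")

# synthetic bench run: simulate, film, invert, estimate back
config = synthetic_data.ExperimentConfig()          # 2 mL over 1 min, 0.2 mm needle
truth = synthetic_data.SyntheticTruth(true_Deff=2.5, true_Ufsi=5.0,
                                      caudal_offset=24.0, seed=7)
series = synthetic_data.simulate_truth(config, truth, np.arange(1.0, 11.0))
stack = synthetic_data.render_frames(series, truth)  # noisy RGB video frames
recovered = imaging.frames_to_profiles(stack, injected_amount=1.0)
est = moments.estimate_dispersion(moments.compute_moments(recovered),
                                  window=(1.0, 8.0))
print(f"Dexp recovered from video = {est.Dexp:.3f} cm2/min "
      f"(truth 2.5, r2 = {est.r_squared:.4f})")
```

Output:

```
DD10 = 25.34 cm
Urms = 9.30 cm/min, Pe = 2.4e+06, alpha = 6.12
Dexp (dispersion law) = 0.639 cm2/min
Dexp recovered from video = 2.417 cm2/min (truth 2.5, r2 = 1.0000)
```

A 2-mL/min infusion through a 0.2-mm needle doses about 25 cm of neuraxis
within 10 minutes; at a 0.5 mL/beat, 40 bpm pulsation the flow corresponds
to Pe ≈ 2×10⁶; and the full render→invert→MoM round trip recovers the
generating dispersion coefficient to a few percent despite pixel noise and
a 10% lighting ramp.

A command-line interface mirrors the library:

```bash
itdisp synth table --n 54 --seed 7 --out runs.csv
itdisp fit dd10 --table runs.csv --out model.json
itdisp tables --which 1 --out table1.csv
itdisp csf --vc 1.0 --f 120
```

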