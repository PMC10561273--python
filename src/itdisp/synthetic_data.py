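"""Synthetic bench data: rendered tracer videography and experiment tables.

No public dataset accompanies the bench study, so this module generates
every input the pipeline consumes, with known ground truth:

* :func:`simulate_truth` produces concentration fields C(x, t) from the
  reduced-order transport model (one transport core serves both synthesis
  and prediction, cross-validated against closed forms in the tests);
* :func:`render_frames` converts profiles into white-to-blue RGB frame
  stacks with seeded pixel noise and a multiplicative lighting ramp — the
  inverse of the optical inference that :mod:`itdisp.imaging` performs;
* :func:`generate_experiment_table` emulates the N = 54 infusion campaign,
  drawing DD10, CCV and Dexp from the published correlations plus seeded
  Gaussian noise, so the fitting routines can be tested for exact noiseless
  recovery and noisy coefficient coverage.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import correlations, csf_dynamics, pkmodel
from .correlations import CorrelationModel, PAPER_MODEL
from .imaging import FrameStack
from .series import ProfileSeries

__all__ = [
    "ExperimentConfig",
    "SyntheticTruth",
    "FrameStack",
    "simulate_truth",
    "render_frames",
    "generate_experiment_table",
    "default_design",
    "dd10_noise_for_r2",
]

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Settings of one bench infusion experiment.

    Defaults reproduce the study's high-volume bolus condition: a 1-min
    infusion through the thin (0.2 mm) catheter at 2 mL/min into the lumbar
    site, observed supine for 10 min under 0.5 mL/beat, 40 bpm pulsation.
    """

    infusion_volume: float = 2.0       # mL
    ivf: float = 2.0                   # mL/min
    needle_diameter: float = 0.2       # mm, inner
    injection_position: float = 50.0   # cm on the neuraxial ruler
    stroke_volume: float = 0.5         # mL/beat
    frequency: float = 40.0            # beats/min
    phase1_duration: float = 1.0       # min
    total_duration: float = 10.0       # min
    orientation: str = "supine"

    def __post_init__(self):
        for name in ("infusion_volume", "ivf", "needle_diameter",
                     "stroke_volume", "frequency", "phase1_duration",
                     "total_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.phase1_duration >= self.total_duration:
            raise ValueError("phase1_duration must be < total_duration")
        if self.orientation != "supine":
            raise ValueError("only the supine orientation is modelled")

    def csf_state(self, A: float | None = None) -> csf_dynamics.CSFState:
        kw = {} if A is None else {"A": A}
        return csf_dynamics.CSFState(vc=self.stroke_volume, f=self.frequency,
                                     **kw)


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a synthetic run.

    true_Deff : effective dispersion [cm²/min] driving phase-2 spread.
    true_Ufsi : craniad-positive phase-1 convection [cm/min].
    lighting_gradient : fractional darkening of the multiplicative lighting
        ramp across the frame (0 = even lighting).
    noise_sd : additive Gaussian pixel noise, 8-bit counts.
    """

    true_Deff: float = 2.5
    true_Ufsi: float = 5.0
    domain_length: float = 48.0
    injected_amount: float = 1.0
    noise_sd: float = 2.0
    lighting_gradient: float = 0.1
    seed: int = 0
    caudal_offset: float = 4.0  # cm from injection site to the caudal end

    def __post_init__(self):
        if self.true_Deff <= 0:
            raise ValueError("true_Deff must be positive")
        if self.domain_length <= 0:
            raise ValueError("domain_length must be positive")
        if self.noise_sd < 0 or not 0 <= self.lighting_gradient < 1:
            raise ValueError("noise_sd >= 0 and lighting_gradient in [0, 1) "
                             "required")


def simulate_truth(config: ExperimentConfig, truth: SyntheticTruth,
                   times, n_cells: int = 480, dt: float = 0.01,
                   sink: float = 0.0) -> ProfileSeries:
    """Ground-truth concentration field from the transport model.

    The injection is a top-hat over one needle width at the configured
    position, running at constant rate over phase-1; convection
    ``true_Ufsi`` acts only during phase-1.  The closed domain spans
    ``domain_length`` cm with the injection site ``caudal_offset`` cm from
    the caudal end.
    """
    times = np.asarray(times, dtype=float)
    if times.max(initial=0.0) > config.total_duration + 1e-9:
        raise ValueError("requested times exceed total_duration")
    caudal_end = config.injection_position + truth.caudal_offset
    domain = (caudal_end - truth.domain_length, caudal_end)
    params = pkmodel.PKParams(
        Deff=truth.true_Deff,
        ufsi=truth.true_Ufsi,
        injection=pkmodel.Injection(
            position=config.injection_position,
            rate=truth.injected_amount / config.phase1_duration,
            start=0.0,
            stop=config.phase1_duration,
            width=config.needle_diameter / 10.0,
        ),
        sink=sink,
        domain=domain,
        n_cells=n_cells,
        dt=dt,
    )
    return pkmodel.solve(params, times)


# ---------------------------------------------------------------------------
# frame rendering

FRAME_HEIGHT = 64
FRAME_MARGIN_ROWS = 8
CM_PER_PIXEL = 0.05


def render_frames(series: ProfileSeries, truth: SyntheticTruth,
                  cm_per_pixel: float = CM_PER_PIXEL,
                  height: int = FRAME_HEIGHT,
                  margin_rows: int = FRAME_MARGIN_ROWS,
                  saturation: float | None = None) -> FrameStack:
    """Render profiles as white-to-blue RGB frames with noise and lighting.

    Pixel colour interpolates from white (no dye) to saturated blue along
    s = C/saturation, so the white-offset grayscale intensity is
    proportional to concentration.  A linear multiplicative lighting ramp
    darkens the frame by ``truth.lighting_gradient`` across its width, and
    seeded Gaussian pixel noise (sd ``truth.noise_sd`` counts) is added.
    The tube occupies the central rows; ``margin_rows`` dye-free background
    rows at top and bottom carry the white reference.
    """
    if np.any(series.C < 0):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(truth.seed)
    dx = float(np.diff(series.x).mean())
    roi = (float(series.x[0]) - dx / 2.0, float(series.x[-1]) + dx / 2.0)
    width = int(round((roi[1] - roi[0]) / cm_per_pixel))
    x_px = roi[0] + (np.arange(width) + 0.5) * cm_per_pixel

    cmax = float(series.C.max())
    if saturation is None:
        saturation = 1.05 * cmax if cmax > 0 else 1.0
    frames = np.empty((series.nt, height, width, 3), dtype=np.uint8)
    r0, r1 = margin_rows, height - margin_rows
    lighting = 1.0 - truth.lighting_gradient * (np.arange(width) / max(width - 1, 1))

    for i in range(series.nt):
        s = np.interp(x_px, series.x, series.C[i]) / saturation
        if np.any(s > 1.0):
            warnings.warn("concentration exceeds colour-map saturation; "
                          "clipping", stacklevel=2)
            s = np.clip(s, 0.0, 1.0)
        img = np.full((height, width, 3), 255.0)
        img[r0:r1, :, 0] = 255.0 * (1.0 - s)   # red fades with dye
        img[r0:r1, :, 1] = 255.0 * (1.0 - s)   # green fades with dye
        # blue channel stays at 255: white -> pure blue interpolation
        img *= lighting[None, :, None]
        if truth.noise_sd > 0:
            img += rng.normal(0.0, truth.noise_sd, size=img.shape)
        # dither before 8-bit rounding: quantization error would otherwise be
        # spatially correlated with the smooth profile and bias the moments
        img += rng.uniform(-0.5, 0.5, size=img.shape)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return FrameStack(frames=frames, timestamps=series.times,
                      cm_per_pixel=cm_per_pixel, roi=roi,
                      tube_rows=(r0, r1),
                      meta={"saturation": saturation, "seed": truth.seed})


# ---------------------------------------------------------------------------
# experiment tables

DESIGN_NEEDLES_MM = (0.2, 1.0, 3.2)
DESIGN_IVF_ML_MIN = (0.5, 1.0, 2.0)
DESIGN_STROKE_ML = (0.5, 1.0)
DESIGN_FREQ_BPM = (40.0, 72.0, 76.0)

#: Between-repeat variability of the dispersion estimate [cm²/min]; the
#: published repeatability of the variance-slope measurement, used as the
#: generator's Dexp noise scale.
DEXP_NOISE_SD = 0.29
#: Realistic run-to-run scatter of the caudocranial velocity [cm/min].
CCV_NOISE_SD = 0.05


def default_design() -> list[tuple[float, float, float, float]]:
    """The 54-run factorial: needle × IVF × stroke volume × frequency."""
    return [(nd, ivf, vc, f)
            for nd in DESIGN_NEEDLES_MM
            for ivf in DESIGN_IVF_ML_MIN
            for vc in DESIGN_STROKE_ML
            for f in DESIGN_FREQ_BPM]


def dd10_noise_for_r2(design, model: CorrelationModel = PAPER_MODEL,
                      r2: float | None = None) -> float:
    """DD10 noise sd [cm] that yields the target regression R² on a design.

    With additive noise of variance σ², the population R² of the linear
    guideline fit is Var(model)/(Var(model) + σ²); inverting it at the
    published R² makes the generator's scatter match the study's.
    """
    if r2 is None:
        r2 = PAPER_MODEL.r_squared["dd10"]
    preds = np.array([correlations.predict_dd10(nd, ivf, model)
                      for nd, ivf, _, _ in design])
    var_model = preds.var()
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    return float(np.sqrt(var_model * (1.0 - r2) / r2))


def generate_experiment_table(coeffs: CorrelationModel = PAPER_MODEL,
                              design=None,
                              noise_sd: float | dict | None = None,
                              seed: int = 0,
                              A: float | None = None) -> pd.DataFrame:
    """Tabular experiment records from the published correlations.

    Columns: needle diameter, IVF, stroke volume, frequency, the derived
    Urms [cm/min], and noisy DD10 [cm], CCV [cm/min], Dexp [cm²/min] drawn
    from the guideline, CCV and dispersion laws.  ``noise_sd`` may be a
    scalar (applied to every column), a dict with keys ``dd10``, ``ccv``,
    ``dexp``, or None for the study-calibrated defaults.  ``noise_sd = 0``
    reproduces the correlations exactly.  Dexp values pushed below the
    molecular diffusivity by noise are floored there and logged.
    """
    if design is None:
        design = default_design()
    design = list(design)
    if not design:
        raise ValueError("design must be non-empty")
    if noise_sd is None:
        sd = {"dd10": dd10_noise_for_r2(design, coeffs),
              "ccv": CCV_NOISE_SD, "dexp": DEXP_NOISE_SD}
    elif isinstance(noise_sd, dict):
        sd = {"dd10": 0.0, "ccv": 0.0, "dexp": 0.0, **noise_sd}
    else:
        sd = {"dd10": float(noise_sd), "ccv": float(noise_sd),
              "dexp": float(noise_sd)}

    rng = np.random.default_rng(seed)
    rows = []
    floored = 0
    for nd, ivf, vc, f in design:
        state = csf_dynamics.CSFState(vc=vc, f=f,
                                      **({} if A is None else {"A": A}))
        u = csf_dynamics.urms(state, units="cm/min")
        dd10 = correlations.predict_dd10(nd, ivf, coeffs) \
            + rng.normal(0.0, sd["dd10"]) * (sd["dd10"] > 0)
        ccv = correlations.predict_ccv(f, coeffs, against="f") \
            + rng.normal(0.0, sd["ccv"]) * (sd["ccv"] > 0)
        dexp = correlations.predict_logD(u, f, coeffs) \
            + rng.normal(0.0, sd["dexp"]) * (sd["dexp"] > 0)
        if dexp <= 0:
            dexp = csf_dynamics.D0_TRYPAN_BLUE
            floored += 1
        rows.append({"nd_mm": nd, "ivf_ml_min": ivf, "stroke_volume_ml": vc,
                     "frequency_bpm": f, "urms_cm_min": u,
                     "dd10_cm": dd10, "ccv_cm_min": ccv,
                     "dexp_cm2_min": dexp})
    if floored:
        log.warning("generate_experiment_table: floored %d noisy Dexp values "
                    "at the molecular diffusivity", floored)
    return pd.DataFrame(rows)
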