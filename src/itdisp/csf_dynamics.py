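"""CSF pulsation kinematics and dimensionless transport numbers.

Natural CSF oscillation is parameterised the way it is measured clinically:
a cervical stroke volume ``vc`` [mL/beat] and a pulse frequency ``f``
[beats/min].  Under a cosine volume waveform

    V(t) = V0 + vc/2 − (vc/2)·cos(ω t),        ω = 2π f / 60  [rad/s],

the cross-section-averaged velocity is u(t) = (dV/dt)/A and its
root-mean-square over one period has the closed form

    U_rms = vc·ω / (2√2·A)                      [cm/s].

The hydraulic cross-section A of the spinal subarachnoid space is not a
directly printed quantity; the default is back-solved so that the pump
setting (vc = 1 mL, f = 120 bpm) lands on the top of the physiological
velocity range, U_rms = 0.93 cm/s, giving A ≈ 4.78 cm².

Dimensionless groups:

* Peclet number  Pe = U_rms·h / D0 (convective vs molecular transport),
  with h defaulting to the hydraulic diameter and U_rms in cm/min for unit
  consistency with D0 [cm²/min];
* Womersley number  α = (D_H/2)·√(ω/ν) (oscillatory inertia vs viscosity);
* dimensionless dispersion increase  ΔD = (D_exp − D0)/D0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CSFState",
    "DimensionlessPoint",
    "volume_waveform",
    "urms",
    "womersley",
    "peclet",
    "delta_d",
    "needle_exit_velocity",
    "D0_TRYPAN_BLUE",
    "HYDRAULIC_DIAMETER_CM",
    "KINEMATIC_VISCOSITY_CM2_S",
    "DEFAULT_HYDRAULIC_AREA_CM2",
    "URMS_PHYSIOLOGICAL_RANGE_CM_S",
]

#: Molecular diffusivity of trypan blue [cm²/min].
D0_TRYPAN_BLUE = 1.938e-6
#: Hydraulic diameter of the spinal subarachnoid space [cm].
HYDRAULIC_DIAMETER_CM = 0.5
#: Kinematic viscosity of CSF (water-like), 7e-7 m²/s in cm²/s.
KINEMATIC_VISCOSITY_CM2_S = 7.0e-3
#: Physiological range of U_rms spanned by the pump settings [cm/s].
URMS_PHYSIOLOGICAL_RANGE_CM_S = (0.09, 0.93)

def _calibrated_area() -> float:
    # vc = 1 mL at 120 bpm must give the upper physiological U_rms endpoint
    omega = 2.0 * math.pi * 120.0 / 60.0
    return 1.0 * omega / (2.0 * math.sqrt(2.0) * URMS_PHYSIOLOGICAL_RANGE_CM_S[1])

#: Hydraulic cross-section of the spinal CSF space [cm²], velocity-calibrated.
DEFAULT_HYDRAULIC_AREA_CM2 = _calibrated_area()


@dataclass
class CSFState:
    """Pulsation state: stroke volume, frequency and derived kinematics.

    vc : cervical stroke volume [mL/beat], >= 0.
    f : pulse frequency [beats/min], >= 0.
    V0 : initial CSF volume [mL] (only the waveform baseline).
    A : hydraulic cross-section [cm²]; defaults to the calibrated value.
    """

    vc: float = 0.5
    f: float = 40.0
    V0: float = 100.0
    A: float = DEFAULT_HYDRAULIC_AREA_CM2
    L: float | None = None

    def __post_init__(self):
        if self.vc < 0 or self.f < 0:
            raise ValueError("stroke volume and frequency must be >= 0")
        if self.A <= 0:
            raise ValueError("hydraulic area must be positive")

    @property
    def omega(self) -> float:
        """Angular pulse frequency [rad/s]."""
        return 2.0 * math.pi * self.f / 60.0

    @property
    def period(self) -> float:
        """Oscillation period [s]; inf when f = 0."""
        return math.inf if self.f == 0 else 60.0 / self.f


def volume_waveform(t, state: CSFState):
    """Instantaneous CSF volume V(t) [mL] at time ``t`` [s].

    V(0) = V0 and the waveform oscillates within [V0, V0 + vc].
    """
    t = np.asarray(t, dtype=float)
    out = state.V0 + state.vc / 2.0 - (state.vc / 2.0) * np.cos(state.omega * t)
    return float(out) if out.ndim == 0 else out


def urms(state: CSFState, units: str = "cm/s") -> float:
    """RMS of the cross-section-average oscillatory velocity.

    Closed form for the cosine waveform: vc·ω/(2√2·A); zero whenever either
    the stroke volume or the frequency is zero.
    """
    val = state.vc * state.omega / (2.0 * math.sqrt(2.0) * state.A)
    if units == "cm/s":
        return val
    if units == "cm/min":
        return val * 60.0
    raise ValueError(f"unknown units {units!r}; use 'cm/s' or 'cm/min'")


def womersley(f: float, DH: float = HYDRAULIC_DIAMETER_CM,
              nu: float = KINEMATIC_VISCOSITY_CM2_S) -> float:
    """Womersley number α = (D_H/2)·√(ω/ν), f in beats/min, ν in cm²/s."""
    if f < 0 or DH <= 0 or nu <= 0:
        raise ValueError("f must be >= 0; DH, nu must be positive")
    omega = 2.0 * math.pi * f / 60.0
    return (DH / 2.0) * math.sqrt(omega / nu)


def peclet(urms_cm_min: float, h: float = HYDRAULIC_DIAMETER_CM,
           D0: float = D0_TRYPAN_BLUE) -> float:
    """Peclet number Pe = U_rms·h/D0 with U_rms in cm/min, D0 in cm²/min."""
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    if urms_cm_min < 0 or h <= 0:
        raise ValueError("urms must be >= 0 and h positive")
    return urms_cm_min * h / D0


def delta_d(Dexp: float, D0: float = D0_TRYPAN_BLUE) -> float:
    """Dimensionless dispersion increase ΔD = (D_exp − D0)/D0, >= −1."""
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    return (Dexp - D0) / D0


@dataclass
class DimensionlessPoint:
    """One experiment in dimensionless coordinates (Pe, α, ΔD)."""

    Pe: float
    alpha: float
    deltaD: float
    D0: float = D0_TRYPAN_BLUE
    DH: float = HYDRAULIC_DIAMETER_CM
    nu: float = KINEMATIC_VISCOSITY_CM2_S

    def __post_init__(self):
        if self.Pe < 0 or self.alpha < 0:
            raise ValueError("Pe and alpha must be >= 0")
        if self.deltaD < -1:
            raise ValueError("deltaD cannot fall below -1")

    @classmethod
    def from_state(cls, state: CSFState, Dexp: float,
                   D0: float = D0_TRYPAN_BLUE) -> "DimensionlessPoint":
        u = urms(state, units="cm/min")
        return cls(Pe=peclet(u, D0=D0), alpha=womersley(state.f),
                   deltaD=delta_d(Dexp, D0), D0=D0)


def needle_exit_velocity(ivf: float, d: float,
                         rho: float = 1.0) -> tuple[float, float]:
    """Catheter-tip exit velocity and kinetic-energy discharge rate.

    Parameters
    ----------
    ivf : infusion volumetric flow rate [mL/min].
    d : needle inner diameter [mm].
    rho : infusate density [g/cm³], default water.

    Returns
    -------
    (VExt, KE_rate) : exit velocity [cm/s] and kinetic energy rate
        ½·ρ·Q·VExt² [erg/s = g·cm²/s³].
    """
    if d <= 0:
        raise ValueError("needle diameter must be positive")
    if ivf < 0:
        raise ValueError("flow rate must be >= 0")
    q_cm3_s = ivf / 60.0
    radius_cm = (d / 10.0) / 2.0
    area = math.pi * radius_cm**2
    vext = q_cm3_s / area
    ke_rate = 0.5 * rho * q_cm3_s * vext**2
    return vext, ke_rate
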