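"""Concentration-profile time series: the pipeline's central data container.

A :class:`ProfileSeries` holds a 1D tracer concentration field ``C(x, t)``
sampled on a fixed neuraxial grid at a set of time points.  The ``x``
coordinate increases *caudally* (toward the sacrum), matching the ruler
convention of the bench videography: the lumbar injection site sits near
x = 50 cm and cranial motion corresponds to decreasing x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ProfileSeries"]


@dataclass
class ProfileSeries:
    """Tracer concentration ``C(x, t)`` on a uniform neuraxial grid.

    Parameters
    ----------
    x : ndarray, shape (nx,)
        Strictly increasing positions along the neuraxis [cm]; x increases
        caudally.
    times : ndarray, shape (nt,)
        Strictly increasing sample times [min].
    C : ndarray, shape (nt, nx)
        Non-negative concentration values (arbitrary units unless AUC-scaled).
    injected_amount : float, optional
        Total injected tracer mass (arbitrary mass units); when set, profiles
        are interpreted as AUC-scaled so that ``trapz(C, x) == injected_amount``
        at post-injection times.
    """

    x: np.ndarray
    times: np.ndarray
    C: np.ndarray
    injected_amount: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if self.x.ndim != 1 or np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be 1D and strictly increasing")
        if self.times.ndim != 1 or (len(self.times) > 1 and np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must be 1D and strictly increasing")
        if self.C.shape != (self.times.size, self.x.size):
            raise ValueError(
                f"C has shape {self.C.shape}, expected {(self.times.size, self.x.size)}"
            )
        if np.any(self.C < -1e-12):
            # tolerate tiny negative round-off from solvers, reject real negativity
            if self.C.min() < -1e-6 * max(1.0, np.abs(self.C).max()):
                raise ValueError("concentrations must be non-negative")
        np.clip(self.C, 0.0, None, out=self.C)

    # -- access helpers ----------------------------------------------------

    @property
    def nx(self) -> int:
        return self.x.size

    @property
    def nt(self) -> int:
        return self.times.size

    def profile_at(self, t: float) -> np.ndarray:
        """Profile at time ``t``, linearly interpolated between snapshots."""
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ValueError(f"time {t} outside sampled range "
                             f"[{self.times[0]}, {self.times[-1]}]")
        idx = np.searchsorted(self.times, t)
        if idx < self.nt and abs(self.times[idx] - t) < 1e-9:
            return self.C[idx].copy()
        if idx == 0:
            return self.C[0].copy()
        t0, t1 = self.times[idx - 1], self.times[idx]
        w = (t - t0) / (t1 - t0)
        return (1 - w) * self.C[idx - 1] + w * self.C[idx]

    def auc(self) -> np.ndarray:
        """Area under each profile, by trapezoidal quadrature [mass units]."""
        return np.trapezoid(self.C, self.x, axis=1)

    # -- IO ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns ``time_min, x_cm, C``."""
        tt, xx = np.meshgrid(self.times, self.x, indexing="ij")
        return pd.DataFrame(
            {"time_min": tt.ravel(), "x_cm": xx.ravel(), "C": self.C.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   injected_amount: float | None = None) -> "ProfileSeries":
        times = np.sort(df["time_min"].unique())
        x = np.sort(df["x_cm"].unique())
        wide = df.pivot_table(index="time_min", columns="x_cm", values="C")
        C = wide.reindex(index=times, columns=x).to_numpy()
        return cls(x=x, times=times, C=C, injected_amount=injected_amount)

    @classmethod
    def from_csv(cls, path, injected_amount: float | None = None) -> "ProfileSeries":
        return cls.from_frame(pd.read_csv(path), injected_amount=injected_amount)
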