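"""Optical inversion of tracer videography into 1D concentration profiles.

Each video frame is an 8-bit RGB image of a transparent spine phantom in
which trypan blue encodes the local tracer concentration: white means no
dye, saturated blue means all dye.  Pixels are aggregated to grayscale with
the standard broadcast luma triple, intensities are inferred by white
offset, column-averaged across the tube width, mapped to neuraxial
coordinates through the spatial calibration, and finally AUC-scaled so the
profile integral equals the injected amount.

Uneven lighting along the neuraxis is cancelled per column using the
dye-free background rows above and below the tube as a white reference:
a multiplicative lighting field divides out exactly.

Coordinate convention: x increases caudally; cranial motion is toward
decreasing x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .series import ProfileSeries

__all__ = [
    "LUMA_WEIGHTS",
    "FrameStack",
    "FrontMetrics",
    "ZeroAUCError",
    "rgb_to_intensity",
    "frames_to_profiles",
    "dispersion_width",
    "front_advance",
    "front_metrics",
    "save_stack",
    "load_stack",
]

#: Broadcast (Rec. 601) grayscale weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class ZeroAUCError(ValueError):
    """AUC scaling requested on a frame with no detectable dye."""


@dataclass
class FrameStack:
    """Timestamped RGB frames with spatial calibration.

    frames : uint8 array, shape (nt, H, W, 3), channel values in 0–255.
    timestamps : minutes, strictly increasing.
    cm_per_pixel : spatial calibration along the neuraxis.
    roi : (x0, xm) [cm] imaged extent; column j maps to
        x = x0 + (j + 0.5)·cm_per_pixel.
    tube_rows : (r0, r1) row slice containing the fluid-filled tube; rows
        outside are dye-free background used as the white reference.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    cm_per_pixel: float
    roi: tuple[float, float]
    tube_rows: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (nt, H, W, 3)")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.frames = np.round(self.frames).astype(np.uint8)
        if self.timestamps.size != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        x0, xm = self.roi
        if xm <= x0:
            raise ValueError("roi must satisfy x0 < xm")
        width_cm = self.frames.shape[2] * self.cm_per_pixel
        if abs(width_cm - (xm - x0)) > 0.51 * self.cm_per_pixel:
            raise ValueError(
                f"roi span {xm - x0:.3f} cm inconsistent with "
                f"{self.frames.shape[2]} px at {self.cm_per_pixel} cm/px"
            )

    @property
    def x(self) -> np.ndarray:
        """Neuraxial positions of pixel-column centers [cm]."""
        j = np.arange(self.frames.shape[2])
        return self.roi[0] + (j + 0.5) * self.cm_per_pixel


@dataclass
class FrontMetrics:
    """Per-time dispersion width and front positions, plus the 10-min advance.

    DD(t) is the axial extent of detectable tracer; ``sdd`` (S_DD) is the
    cranial distance from the catheter tip to the cranial front at
    ``sdd_time`` minutes.
    """

    times: np.ndarray
    DD: np.ndarray
    caudal_front: np.ndarray
    cranial_front: np.ndarray
    sdd: float
    sdd_time: float
    tip_position: float
    threshold_frac: float


def rgb_to_intensity(frame: np.ndarray) -> np.ndarray:
    """White-offset dye intensity in [0, 1] from an RGB frame.

    intensity = (255 − luma)/255 with luma = 0.299 R + 0.587 G + 0.114 B:
    0 for a pure-white (dye-free) pixel, 1 for black.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim < 1 or frame.shape[-1] != 3:
        raise ValueError("expected trailing RGB channel axis of size 3")
    luma = frame @ np.asarray(LUMA_WEIGHTS)
    return np.clip((255.0 - luma) / 255.0, 0.0, 1.0)


def _column_intensity(frame: np.ndarray, tube_rows, use_white_reference: bool):
    """Width-averaged dye intensity per pixel column."""
    luma = np.asarray(frame, dtype=float) @ np.asarray(LUMA_WEIGHTS)
    H = luma.shape[0]
    if tube_rows is None:
        r0, r1 = 0, H
    else:
        r0, r1 = tube_rows
    tube = luma[r0:r1].mean(axis=0)
    if use_white_reference and (r0 > 0 or r1 < H):
        margins = np.concatenate([luma[:r0], luma[r1:]], axis=0)
        ref = margins.mean(axis=0)
        ref = np.where(ref <= 1e-9, 255.0, ref)
    else:
        ref = 255.0
    return np.clip(1.0 - tube / ref, 0.0, 1.0)


def frames_to_profiles(stack: FrameStack,
                       injected_amount: float | None = None,
                       use_white_reference: bool = True,
                       normalize: bool = True,
                       noise_floor_frac: float = 0.015,
                       on_blank: str = "error") -> ProfileSeries:
    """Invert a frame stack into an AUC-scaled concentration profile series.

    Each frame's intensities are column-averaged across the tube width,
    lighting-corrected against the background white reference, and scaled so
    the profile integral equals ``injected_amount`` (or 1 when not given).
    Columns below ``noise_floor_frac`` of the frame maximum are zeroed:
    clipping rectifies pixel noise into a positive background floor that
    would otherwise drag the profile moments toward the frame center.
    With ``normalize=False`` the raw width-averaged intensities are
    returned, e.g. for inspecting background residuals.

    ``on_blank`` controls zero-AUC (all-white) frames under scaling:
    ``"error"`` raises :class:`ZeroAUCError`, ``"drop"`` silently discards
    them (useful for pre-injection footage).
    """
    if stack.frames.shape[0] == 0:
        raise ValueError("empty frame stack")
    if on_blank not in ("error", "drop"):
        raise ValueError("on_blank must be 'error' or 'drop'")
    x = stack.x
    profiles, times = [], []
    for i, frame in enumerate(stack.frames):
        prof = _column_intensity(frame, stack.tube_rows, use_white_reference)
        if noise_floor_frac > 0 and normalize:
            prof = np.where(prof >= noise_floor_frac * prof.max(initial=0.0),
                            prof, 0.0)
        if normalize:
            auc = np.trapezoid(prof, x)
            if auc <= 0:
                if on_blank == "drop":
                    continue
                raise ZeroAUCError(
                    f"frame {i} (t={stack.timestamps[i]} min) has zero AUC; "
                    "cannot scale an all-white frame"
                )
            prof = prof * ((injected_amount if injected_amount is not None
                            else 1.0) / auc)
        profiles.append(prof)
        times.append(stack.timestamps[i])
    if not profiles:
        raise ZeroAUCError("every frame in the stack is blank")
    return ProfileSeries(x=x, times=np.asarray(times),
                         C=np.stack(profiles),
                         injected_amount=injected_amount)


def dispersion_width(x: np.ndarray, C: np.ndarray,
                     threshold_frac: float = 0.05) -> float:
    """Axial extent [cm] of the contiguous detectable-tracer region.

    The mask is C > threshold_frac · max(C); the extent is measured over the
    contiguous run containing the profile maximum.  Zero for an empty mask.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    x = np.asarray(x, dtype=float)
    C = np.asarray(C, dtype=float)
    cmax = C.max(initial=0.0)
    if cmax <= 0:
        return 0.0
    mask = C > threshold_frac * cmax
    peak = int(np.argmax(C))
    lo = peak
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = peak
    while hi < C.size - 1 and mask[hi + 1]:
        hi += 1
    return float(x[hi] - x[lo])


def _mask_bounds(x, C, threshold_frac):
    cmax = C.max(initial=0.0)
    if cmax <= 0:
        return None
    idx = np.flatnonzero(C > threshold_frac * cmax)
    return float(x[idx[0]]), float(x[idx[-1]])


def front_advance(series: ProfileSeries, tip_position: float, at_time: float,
                  threshold_frac: float = 0.05) -> float:
    """Cranial front advance S_DD [cm]: tip to the cranial-most detectable x.

    x decreases craniad, so the cranial front is the smallest x exceeding
    the detection threshold; the result is clipped at zero when all mass
    lies caudal of the tip.  Times between snapshots are linearly
    interpolated.
    """
    prof = series.profile_at(at_time)
    bounds = _mask_bounds(series.x, prof, threshold_frac)
    if bounds is None:
        return 0.0
    cranial_front, _ = bounds
    return max(0.0, tip_position - cranial_front)


def front_metrics(series: ProfileSeries, tip_position: float,
                  threshold_frac: float = 0.05,
                  sdd_time: float = 10.0) -> FrontMetrics:
    """DD(t) and front positions for every snapshot, plus S_DD."""
    n = series.nt
    DD = np.zeros(n)
    caudal = np.full(n, np.nan)
    cranial = np.full(n, np.nan)
    for i in range(n):
        DD[i] = dispersion_width(series.x, series.C[i], threshold_frac)
        b = _mask_bounds(series.x, series.C[i], threshold_frac)
        if b is not None:
            cranial[i], caudal[i] = b
    sdd = front_advance(series, tip_position, sdd_time, threshold_frac)
    return FrontMetrics(times=series.times, DD=DD, caudal_front=caudal,
                        cranial_front=cranial, sdd=sdd, sdd_time=sdd_time,
                        tip_position=tip_position,
                        threshold_frac=threshold_frac)


# ---------------------------------------------------------------------------
# PNG stack IO


def save_stack(stack: FrameStack, directory) -> None:
    """Write a stack as numbered 8-bit PNGs plus a JSON calibration sidecar."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        iio.imwrite(directory / f"frame_{i:04d}.png", frame)
    sidecar = {
        "timestamps_min": stack.timestamps.tolist(),
        "cm_per_pixel": stack.cm_per_pixel,
        "roi_cm": list(stack.roi),
        "tube_rows": list(stack.tube_rows) if stack.tube_rows else None,
    }
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=2))


def load_stack(directory) -> FrameStack:
    """Read a PNG stack written by :func:`save_stack`."""
    import imageio.v3 as iio

    directory = Path(directory)
    sidecar = json.loads((directory / "stack.json").read_text())
    paths = sorted(directory.glob("frame_*.png"))
    frames = np.stack([iio.imread(p) for p in paths])
    return FrameStack(
        frames=frames,
        timestamps=np.asarray(sidecar["timestamps_min"]),
        cm_per_pixel=sidecar["cm_per_pixel"],
        roi=tuple(sidecar["roi_cm"]),
        tube_rows=tuple(sidecar["tube_rows"]) if sidecar["tube_rows"] else None,
    )
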