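"""Pixel-to-centimeter calibration and ear-based crossing velocity.

Velocity is the net horizontal displacement of the ear landmark between
the trial bounds divided by elapsed time (frames / fps), reported for
the whole trial and for each temporal half.  The pixel scale comes from
the known 4 cm rung spacing, measured six times per video (left, center,
right, twice each) and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pose_io import KeypointTrack

__all__ = [
    "Calibration",
    "VelocityResult",
    "VelocityUndefinedError",
    "calibrate",
    "compute_velocity",
    "instantaneous_velocity",
]

DEFAULT_RUNG_SPACING_CM = 4.0
EXPECTED_N_MEASUREMENTS = 6


class VelocityUndefinedError(RuntimeError):
    """No confident ear sample near a trial bound."""


@dataclass(frozen=True)
class Calibration:
    """Pixel scale from repeated rung-gap measurements."""

    measurements_px: tuple[float, ...]
    rung_spacing_cm: float

    @property
    def cm_per_px(self) -> float:
        return self.rung_spacing_cm / float(np.mean(self.measurements_px))

    @property
    def spread_px(self) -> float:
        """Sample SD of the gap measurements, kept for QC."""
        if len(self.measurements_px) < 2:
            return 0.0
        return float(np.std(self.measurements_px, ddof=1))


@dataclass(frozen=True)
class VelocityResult:
    v_total: float  # cm/s
    v_first_half: float
    v_second_half: float
    duration_s: float
    distance_cm: float
    bounds_flagged: bool  # True when a bound used a nearest-confident substitute


def calibrate(
    measurements_px: Sequence[float],
    rung_spacing_cm: float = DEFAULT_RUNG_SPACING_CM,
) -> Calibration:
    """cm/px = rung spacing / mean measured gap."""
    meas = tuple(float(m) for m in measurements_px)
    if len(meas) == 0:
        raise ValueError("at least one gap measurement required")
    if any(m <= 0 for m in meas):
        raise ValueError("gap measurements must be positive")
    if rung_spacing_cm <= 0:
        raise ValueError("rung spacing must be positive")
    if len(meas) != EXPECTED_N_MEASUREMENTS:
        warnings.warn(
            f"expected {EXPECTED_N_MEASUREMENTS} gap measurements, got {len(meas)}",
            stacklevel=2,
        )
    return Calibration(measurements_px=meas, rung_spacing_cm=float(rung_spacing_cm))


def _confident_x_at(
    frames: np.ndarray,
    x: np.ndarray,
    ok: np.ndarray,
    frame: int,
    window: int,
) -> tuple[float, bool]:
    """x at ``frame`` from the nearest confident sample within ``window``.

    Returns (x value, substituted?) where substituted means the bound frame
    itself was unconfident.
    """
    conf_frames = frames[ok]
    if conf_frames.size == 0:
        raise VelocityUndefinedError("no confident ear samples at all")
    pos = np.searchsorted(frames, frame)
    if pos < len(frames) and frames[pos] == frame and ok[pos]:
        return float(x[pos]), False
    dist = np.abs(conf_frames - frame)
    best = int(np.argmin(dist))
    if dist[best] > window:
        raise VelocityUndefinedError(
            f"no confident ear sample within {window} frames of frame {frame}"
        )
    return float(x[ok][best]), True


def compute_velocity(
    track: KeypointTrack,
    bounds: tuple[int, int],
    calibration: Calibration,
    fps: float = 30.0,
    *,
    ear_landmark: str = "right_ear",
    likelihood_cutoff: float = 0.75,
    bound_window_frames: int = 5,
) -> VelocityResult:
    """Total and half-trial velocities in cm/s.

    Halves split the frame interval at its temporal midpoint; with an odd
    number of frame intervals the middle frame goes to the first half.  Each
    half's velocity uses its own displacement over its own time, so
    first-half + second-half distance equals the total when the midpoint
    sample is confident.
    """
    start, end = int(bounds[0]), int(bounds[1])
    if end <= start:
        raise ValueError("end bound must exceed start bound")
    if fps <= 0:
        raise ValueError("fps must be positive")
    frames = track.frames
    x = track.x(ear_landmark)
    ok = track.valid(ear_landmark) & (track.likelihood(ear_landmark) > likelihood_cutoff)

    mid = start + (end - start + 1) // 2  # middle frame joins the first half
    x_start, f_start = _confident_x_at(frames, x, ok, start, bound_window_frames)
    x_mid, f_mid = _confident_x_at(frames, x, ok, mid, bound_window_frames)
    x_end, f_end = _confident_x_at(frames, x, ok, end, bound_window_frames)

    cmpx = calibration.cm_per_px
    t_total = (end - start) / fps
    t_first = (mid - start) / fps
    t_second = (end - mid) / fps
    d_total = abs(x_end - x_start) * cmpx
    return VelocityResult(
        v_total=d_total / t_total,
        v_first_half=abs(x_mid - x_start) * cmpx / t_first,
        v_second_half=abs(x_end - x_mid) * cmpx / t_second,
        duration_s=t_total,
        distance_cm=d_total,
        bounds_flagged=f_start or f_mid or f_end,
    )


def instantaneous_velocity(
    track: KeypointTrack,
    calibration: Calibration,
    fps: float = 30.0,
    *,
    ear_landmark: str = "right_ear",
    likelihood_cutoff: float = 0.75,
    window_frames: int = 5,
) -> np.ndarray:
    """Rolling-mean smoothed frame-to-frame ear velocity (cm/s), for plots.

    Computed over confident samples only; intended as an illustrative
    trace, not as the per-trial summary statistic.
    """
    ok = track.valid(ear_landmark) & (track.likelihood(ear_landmark) > likelihood_cutoff)
    frames = track.frames[ok].astype(float)
    x = track.x(ear_landmark)[ok]
    if frames.size < 2:
        return np.empty(0)
    v = np.diff(x) / np.diff(frames) * fps * calibration.cm_per_px
    if window_frames > 1 and v.size >= window_frames:
        kernel = np.ones(window_frames) / window_frames
        v = np.convolve(v, kernel, mode="valid")
    return v
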