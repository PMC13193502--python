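"""Footfall-error detection on ladder-crossing pose tracks.

A footfall error is a paw slipping below the rung plane.  Per paw, a
vertical baseline is estimated as a trimmed mean of confident
y-coordinates; a candidate error opens when a confident sample drops
beyond baseline + offset (the adaptive threshold, default 35 px) and the
epoch runs until the first confident sample back at or above baseline.
Hysteresis (open at threshold, close at baseline) consolidates each slip
into a single epoch so transient fluctuations are not double counted.
Unconfident samples (likelihood <= 0.75 by default) never change the
detector state.

Image coordinates are downward-positive by default, so a slip is a y
increase; set ``y_downward=False`` for upward-positive data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pose_io import PAW_SIDES, KeypointTrack, TrialMeta

__all__ = [
    "ConfidentSeries",
    "PawBaseline",
    "FootfallEpoch",
    "BaselineUndefinedError",
    "filter_confident",
    "compute_baseline",
    "detect_epochs",
    "detect_track_epochs",
    "summarize_errors",
    "epochs_to_frame",
    "merge_manual_annotations",
]

DEFAULT_LIKELIHOOD_CUTOFF = 0.75
DEFAULT_OFFSET_PX = 35.0
DEFAULT_TRIM_FRACTION = 0.10
DEFAULT_MIN_CONFIDENT = 30


class BaselineUndefinedError(RuntimeError):
    """Too few confident samples to estimate a paw baseline."""


@dataclass(frozen=True)
class ConfidentSeries:
    """Confident (likelihood > cutoff, finite) samples of one landmark."""

    landmark: str
    frames: np.ndarray  # frame indices of confident samples, increasing
    y: np.ndarray
    n_frames: int  # total frames in the source track
    cutoff: float

    @property
    def n_confident(self) -> int:
        return int(self.frames.size)


@dataclass(frozen=True)
class PawBaseline:
    """Trimmed-mean resting height and the derived slip threshold."""

    paw: str
    baseline_y: float
    offset_px: float
    trim_fraction: float
    n_samples: int

    @property
    def threshold_y(self) -> float:
        return self.baseline_y + self.offset_px


@dataclass(frozen=True)
class FootfallEpoch:
    """One consolidated slip event on a half-open frame interval."""

    paw: str
    start_frame: int
    end_frame: int
    max_drop_px: float
    closed: bool

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame


def filter_confident(
    track: KeypointTrack,
    landmark: str,
    cutoff: float = DEFAULT_LIKELIHOOD_CUTOFF,
    *,
    flip_y: bool = False,
) -> ConfidentSeries:
    """Keep samples with likelihood strictly above ``cutoff``.

    A likelihood of exactly ``cutoff`` is excluded (the gate is
    ``LH > cutoff``).  Missing samples (non-finite x/y/likelihood) are
    always excluded.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    ok = track.valid(landmark) & (track.likelihood(landmark) > cutoff)
    y = track.y(landmark)[ok]
    if flip_y:
        y = -y
    return ConfidentSeries(
        landmark=landmark,
        frames=track.frames[ok],
        y=y,
        n_frames=track.n_frames,
        cutoff=cutoff,
    )


def compute_baseline(
    series: ConfidentSeries,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    offset_px: float = DEFAULT_OFFSET_PX,
    min_confident: int = DEFAULT_MIN_CONFIDENT,
) -> PawBaseline:
    """Symmetric trimmed mean of confident y; threshold = baseline + offset."""
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    if offset_px < 0:
        raise ValueError("offset_px must be non-negative")
    if series.n_confident < min_confident:
        raise BaselineUndefinedError(
            f"{series.landmark}: {series.n_confident} confident samples "
            f"< required {min_confident}"
        )
    baseline = float(stats.trim_mean(series.y, proportiontocut=trim_fraction))
    return PawBaseline(
        paw=series.landmark,
        baseline_y=baseline,
        offset_px=float(offset_px),
        trim_fraction=float(trim_fraction),
        n_samples=series.n_confident,
    )


def detect_epochs(series: ConfidentSeries, baseline: PawBaseline) -> list[FootfallEpoch]:
    """State machine over the confident subsequence.

    Excursion is measured beyond baseline in the slip direction
    (``y - baseline_y`` in downward-positive convention).  An epoch opens at
    the first confident sample with excursion > offset, closes at the first
    subsequent confident sample with excursion <= 0, and an epoch still open
    at the last frame is emitted with ``closed=False`` and
    ``end_frame = n_frames``.
    """
    epochs: list[FootfallEpoch] = []
    excursion = series.y - baseline.baseline_y
    open_start: int | None = None
    max_drop = 0.0
    for frame, exc in zip(series.frames, excursion):
        if open_start is None:
            if exc > baseline.offset_px:
                open_start = int(frame)
                max_drop = float(exc)
        else:
            if exc <= 0.0:
                epochs.append(
                    FootfallEpoch(
                        paw=series.landmark,
                        start_frame=open_start,
                        end_frame=int(frame),
                        max_drop_px=max_drop,
                        closed=True,
                    )
                )
                open_start = None
                max_drop = 0.0
            else:
                max_drop = max(max_drop, float(exc))
    if open_start is not None:
        epochs.append(
            FootfallEpoch(
                paw=series.landmark,
                start_frame=open_start,
                end_frame=series.n_frames,
                max_drop_px=max_drop,
                closed=False,
            )
        )
    return epochs


def detect_track_epochs(
    track: KeypointTrack,
    *,
    cutoff: float = DEFAULT_LIKELIHOOD_CUTOFF,
    offset_px: float = DEFAULT_OFFSET_PX,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    min_confident: int = DEFAULT_MIN_CONFIDENT,
    paw_sides: dict[str, str] | None = None,
    flip_y: bool = False,
) -> tuple[list[FootfallEpoch], list[str]]:
    """Run the full per-paw pipeline over a track.

    Returns the detected epochs across paws and the list of paws skipped
    because their baseline was undefined (too few confident samples).
    """
    sides = paw_sides if paw_sides is not None else PAW_SIDES
    epochs: list[FootfallEpoch] = []
    skipped: list[str] = []
    for paw in sides:
        if paw not in track.landmarks:
            skipped.append(paw)
            continue
        series = filter_confident(track, paw, cutoff, flip_y=flip_y)
        try:
            baseline = compute_baseline(series, trim_fraction, offset_px, min_confident)
        except BaselineUndefinedError:
            skipped.append(paw)
            continue
        epochs.extend(detect_epochs(series, baseline))
    return epochs, skipped


def summarize_errors(
    epochs: list[FootfallEpoch],
    meta: TrialMeta | None = None,
    paw_sides: dict[str, str] | None = None,
) -> dict:
    """Per-trial error counts and left/right split.

    ``left_fraction`` is None (flagged undefined) when no errors occurred.
    """
    sides = paw_sides if paw_sides is not None else PAW_SIDES
    left = sum(1 for e in epochs if sides.get(e.paw) == "left")
    right = sum(1 for e in epochs if sides.get(e.paw) == "right")
    total = len(epochs)
    out = {
        "total_errors": total,
        "left_errors": left,
        "right_errors": right,
        "left_fraction": left / (left + right) if (left + right) > 0 else None,
        "unclosed_errors": sum(1 for e in epochs if not e.closed),
    }
    if meta is not None:
        out.update(
            subject_id=meta.subject_id,
            sex=meta.sex,
            treatment=meta.treatment,
            cohort=meta.cohort,
            week=meta.week,
        )
    return out


def epochs_to_frame(epochs: list[FootfallEpoch]) -> pd.DataFrame:
    """Epoch list as the exported CSV table layout."""
    return pd.DataFrame(
        [
            {
                "paw": e.paw,
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "duration_frames": e.duration_frames,
                "max_drop_px": e.max_drop_px,
                "closed": e.closed,
            }
            for e in epochs
        ],
        columns=["paw", "start_frame", "end_frame", "duration_frames", "max_drop_px", "closed"],
    )


def merge_manual_annotations(
    epochs: list[FootfallEpoch],
    manual: pd.DataFrame,
) -> list[FootfallEpoch]:
    """Merge manually scored events (paw, start_frame, end_frame) into a
    detected epoch list.

    A manual event overlapping a detected epoch of the same paw is taken as
    confirming it; non-overlapping manual events are appended as extra
    epochs with ``max_drop_px = nan``.  This supports a human-override
    workflow without guessing the original scoring protocol.
    """
    merged = list(epochs)
    for _, row in manual.iterrows():
        paw, s, e = row["paw"], int(row["start_frame"]), int(row["end_frame"])
        overlaps = any(
            ep.paw == paw and ep.start_frame < e and s < ep.end_frame for ep in merged
        )
        if not overlaps:
            merged.append(
                FootfallEpoch(paw=paw, start_frame=s, end_frame=e,
                              max_drop_px=float("nan"), closed=True)
            )
    return sorted(merged, key=lambda ep: (ep.paw, ep.start_frame))
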