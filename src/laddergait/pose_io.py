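"""Reading, writing and validating DeepLabCut-style keypoint tables.

DeepLabCut exports one CSV per video with a three-row header
(``scorer`` / ``bodyparts`` / ``coords``) and, per landmark, three
columns: ``x``, ``y`` (pixels, image convention: y grows downward) and
``likelihood`` (tracker confidence in [0, 1]).  This module wraps that
dialect in a validated :class:`KeypointTrack` container and resolves
per-trial frame bounds (crossing onset / end of apparatus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KeypointTrack",
    "TrialMeta",
    "PoseIOError",
    "UnboundedTrialError",
    "read_dlc_csv",
    "write_dlc_csv",
    "resolve_trial_bounds",
    "rank_trials_by_stops",
]

COORDS = ("x", "y", "likelihood")

#: default landmark set: both forepaws, hind ankle/knee pairs (ankle is the
#: tracked "hind paw" point), tail base/tip and the right ear used for velocity.
DEFAULT_LANDMARKS = (
    "right_ear",
    "forepaw_left",
    "forepaw_right",
    "ankle_left",
    "knee_left",
    "ankle_right",
    "knee_right",
    "tail_base",
    "tail_tip",
)

#: landmarks treated as paws for footfall analysis, mapped to body side.
PAW_SIDES = {
    "forepaw_left": "left",
    "forepaw_right": "right",
    "ankle_left": "left",
    "ankle_right": "right",
}


class PoseIOError(ValueError):
    """Malformed DLC table or invalid track."""


class UnboundedTrialError(RuntimeError):
    """No frame satisfies the trial start or end rule."""


@dataclass
class KeypointTrack:
    """Per-frame pixel coordinates and likelihoods for a set of landmarks.

    Parameters
    ----------
    data
        DataFrame indexed by frame (strictly increasing integers) with
        MultiIndex columns ``(bodypart, coord)``, coord in
        ``("x", "y", "likelihood")``.
    scorer
        Free-text scorer tag preserved on round trips.
    """

    data: pd.DataFrame
    scorer: str = "synthetic"

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise PoseIOError("track has no frames")
        frames = np.asarray(self.data.index)
        if not np.issubdtype(frames.dtype, np.integer):
            try:
                frames = frames.astype(int)
                self.data.index = pd.Index(frames, name="frame")
            except (TypeError, ValueError) as exc:
                raise PoseIOError("frame index must be integer") from exc
        if np.any(np.diff(frames) <= 0):
            raise PoseIOError("frame index must be strictly increasing")
        if not isinstance(self.data.columns, pd.MultiIndex) or self.data.columns.nlevels != 2:
            raise PoseIOError("columns must be a (bodypart, coord) MultiIndex")
        for lm in self.landmarks:
            present = set(self.data[lm].columns)
            missing = set(COORDS) - present
            if missing:
                raise PoseIOError(f"landmark {lm!r} missing channel(s) {sorted(missing)}")
        lik = self.data.loc[:, (slice(None), "likelihood")].to_numpy(float)
        with np.errstate(invalid="ignore"):
            bad = (lik < 0) | (lik > 1)
        if np.any(bad):
            raise PoseIOError("likelihood values must lie in [0, 1]")

    @property
    def landmarks(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def frames(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def x(self, landmark: str) -> np.ndarray:
        return self.data[(landmark, "x")].to_numpy(float)

    def y(self, landmark: str) -> np.ndarray:
        return self.data[(landmark, "y")].to_numpy(float)

    def likelihood(self, landmark: str) -> np.ndarray:
        return self.data[(landmark, "likelihood")].to_numpy(float)

    def valid(self, landmark: str) -> np.ndarray:
        """Finite x, y and likelihood — missing cells are invalid, never zero."""
        sub = self.data[landmark].to_numpy(float)
        return np.isfinite(sub).all(axis=1)


COHORT_LAST_WEEK = {"t1": 2, "t2": 4, "t3": 6}


@dataclass
class TrialMeta:
    """Per-trial metadata: design cell, timing and calibration."""

    subject_id: str
    sex: str = "female"
    treatment: str = "control"
    cohort: str = "t3"
    week: int = 0
    fps: float = 30.0
    start_frame: int | None = None
    end_frame: int | None = None
    calibration_measurements_px: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.treatment not in ("control", "lesion"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.cohort not in COHORT_LAST_WEEK:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if not 0 <= self.week <= COHORT_LAST_WEEK[self.cohort]:
            raise ValueError(
                f"week {self.week} outside cohort {self.cohort} schedule "
                f"(0..{COHORT_LAST_WEEK[self.cohort]})"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if (
            self.start_frame is not None
            and self.end_frame is not None
            and self.end_frame <= self.start_frame
        ):
            raise ValueError("end_frame must exceed start_frame")


def read_dlc_csv(path: str | Path) -> KeypointTrack:
    """Parse a DLC CSV (scorer/bodyparts/coords header) into a track.

    Missing cells become NaN and are flagged invalid by
    :meth:`KeypointTrack.valid`; they are never silently coerced to zero.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path, header=[0, 1, 2], index_col=0, float_precision="round_trip"
        )
    except (pd.errors.ParserError, IndexError) as exc:
        raise PoseIOError(f"{path}: cannot parse three-row DLC header: {exc}") from exc
    if raw.columns.nlevels != 3:
        raise PoseIOError(f"{path}: expected 3 header rows, got {raw.columns.nlevels}")
    scorers = list(dict.fromkeys(raw.columns.get_level_values(0)))
    if len(scorers) != 1:
        raise PoseIOError(f"{path}: multiple scorers {scorers}; multi-animal files unsupported")
    scorer = scorers[0]
    raw.columns = raw.columns.droplevel(0)
    raw.columns.names = ["bodyparts", "coords"]

    seen: dict[str, set[str]] = {}
    for bp, coord in raw.columns:
        if coord not in COORDS:
            raise PoseIOError(f"{path}: unexpected coords label {coord!r} under {bp!r}")
        if coord in seen.setdefault(bp, set()):
            raise PoseIOError(f"{path}: duplicated landmark/channel {bp!r}/{coord}")
        seen[bp].add(coord)
    for bp, coords in seen.items():
        missing = set(COORDS) - coords
        if missing:
            raise PoseIOError(f"{path}: landmark {bp!r} missing column(s) {sorted(missing)}")

    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        newly_bad = vals.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if newly_bad.any():
            row = raw.index[newly_bad.to_numpy()][0]
            raise PoseIOError(f"{path}: non-numeric cell at frame {row}, column {col}")
        raw[col] = vals
    raw.index.name = "frame"
    return KeypointTrack(raw, scorer=scorer)


def write_dlc_csv(track: KeypointTrack, path: str | Path) -> Path:
    """Write a track in the DLC three-row-header dialect.

    Non-finite coordinates are emitted as empty cells, which read back as
    flagged-invalid samples.
    """
    path = Path(path)
    out = track.data.copy()
    out.columns = pd.MultiIndex.from_tuples(
        [(track.scorer, bp, coord) for bp, coord in out.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    out.index.name = "coords"  # DLC quirk: frame column is labelled under coords
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, na_rep="")
    return path


def _movement_onset_ok(ear_x: np.ndarray, i: int, min_dx: float, window: int) -> bool:
    j = min(i + window, len(ear_x) - 1)
    if j <= i:
        return False
    dx = ear_x[j] - ear_x[i]
    return bool(np.isfinite(dx) and dx >= min_dx * (j - i))


def resolve_trial_bounds(
    track: KeypointTrack,
    meta: TrialMeta,
    *,
    end_x_px: float | None = None,
    likelihood_cutoff: float = 0.75,
    min_dx_px_per_frame: float = 2.0,
    onset_window_frames: int = 3,
    paw_landmarks: Sequence[str] | None = None,
    ear_landmark: str = "right_ear",
) -> tuple[int, int]:
    """Resolve (start_frame, end_frame) for a ladder crossing.

    Explicit bounds in ``meta`` are returned unchanged.  Otherwise the start
    is the first frame where all four paw landmarks are simultaneously
    confident (likelihood > cutoff) and forward movement has begun (ear x
    advancing by at least ``min_dx_px_per_frame`` over ``onset_window_frames``
    frames); the end is the first frame at or after the start where the
    confident ear x reaches ``end_x_px``.
    """
    if meta.start_frame is not None and meta.end_frame is not None:
        return int(meta.start_frame), int(meta.end_frame)
    if ear_landmark not in track.landmarks:
        raise PoseIOError(f"ear landmark {ear_landmark!r} absent from track")
    if end_x_px is None:
        raise UnboundedTrialError("auto bound detection requires end_x_px")

    paws = list(paw_landmarks) if paw_landmarks is not None else [
        lm for lm in track.landmarks if lm in PAW_SIDES
    ]
    if len(paws) != 4:
        raise PoseIOError(f"expected 4 paw landmarks, found {paws}")

    conf = np.ones(track.n_frames, dtype=bool)
    for lm in paws:
        conf &= track.valid(lm) & (track.likelihood(lm) > likelihood_cutoff)
    ear_x = track.x(ear_landmark)
    ear_ok = track.valid(ear_landmark) & (track.likelihood(ear_landmark) > likelihood_cutoff)

    start_pos = None
    for i in np.flatnonzero(conf):
        if _movement_onset_ok(ear_x, int(i), min_dx_px_per_frame, onset_window_frames):
            start_pos = int(i)
            break
    if start_pos is None:
        raise UnboundedTrialError("no frame has all four paws confident with forward movement")

    reached = ear_ok & (ear_x >= end_x_px)
    reached[:start_pos + 1] = False
    hits = np.flatnonzero(reached)
    if hits.size == 0:
        raise UnboundedTrialError(f"ear never reaches x = {end_x_px} px after start")
    frames = track.frames
    return int(frames[start_pos]), int(frames[int(hits[0])])


def rank_trials_by_stops(
    tracks: Sequence[KeypointTrack],
    *,
    ear_landmark: str = "right_ear",
    likelihood_cutoff: float = 0.75,
    stop_dx_px: float = 1.0,
    min_stop_frames: int = 3,
) -> list[int]:
    """Order trial indices by number of zero-velocity runs (fewest first).

    A "stop" is a run of at least ``min_stop_frames`` consecutive confident
    frames whose ear x advances less than ``stop_dx_px`` per frame.  This
    operationalizes picking the least-interrupted crossing of a session; the
    criterion is an interpretation, so the ranking is exposed rather than a
    trial silently chosen.
    """
    counts = []
    for idx, track in enumerate(tracks):
        ok = track.valid(ear_landmark) & (track.likelihood(ear_landmark) > likelihood_cutoff)
        x = track.x(ear_landmark)[ok]
        if x.size < 2:
            counts.append((np.inf, idx))
            continue
        slow = np.abs(np.diff(x)) < stop_dx_px
        n_stops, run = 0, 0
        for s in slow:
            run = run + 1 if s else 0
            if run == min_stop_frames:
                n_stops += 1
        counts.append((n_stops, idx))
    return [idx for _, idx in sorted(counts)]
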