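"""Synthetic inputs for every pipeline stage.

Three generators stand in for the study's raw materials:

* :func:`generate_pose_trial` — lateral-view pose tracks of 9 landmarks
  during a ladder crossing, with injected slip events (downward paw
  excursions), low-likelihood occlusion windows, Gaussian pixel jitter
  and a monotonically advancing ear; every injected event is returned in
  a ground-truth table.
* :func:`simulate_longitudinal_outcomes` — per subject-week error
  counts, crossing velocities or left-paw error splits drawn from the
  multi-level linear predictor used for inference (random intercept per
  subject plus sex, sex-by-treatment, week, and week-by-treatment fixed
  effects), under the staggered three-cohort attrition design (t1
  observed through week 2, t2 through week 4, t3 through week 6, all
  with a week-0 baseline).
* :func:`simulate_th_counts` — two-rater, multi-section hemispheric
  TH-positive cell count tables with a programmable asymmetry index per
  treatment group.

Fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .pose_io import COHORT_LAST_WEEK, DEFAULT_LANDMARKS, PAW_SIDES, KeypointTrack

__all__ = [
    "SimTrialSpec",
    "SimStudySpec",
    "STUDY_CELL_SIZES",
    "DEFAULT_TRUE_PARAMS_COUNT",
    "DEFAULT_TRUE_PARAMS_VELOCITY",
    "DEFAULT_TRUE_PARAMS_LATERALITY",
    "FAMILY_DEFAULT_PARAMS",
    "study_spec_for",
    "generate_pose_trial",
    "ear_x_path",
    "simulate_longitudinal_outcomes",
    "simulate_th_counts",
]

WEEKS_POST = (1, 2, 3, 4, 5, 6)

#: study cell sizes (sex, treatment, cohort) -> n, copying the published design
#: (9/11/6/7 male-control/male-lesion/female-control/female-lesion at t1, etc.;
#: 101 subjects in total).
STUDY_CELL_SIZES: dict[tuple[str, str, str], int] = {
    ("male", "control", "t1"): 9,
    ("male", "lesion", "t1"): 11,
    ("female", "control", "t1"): 6,
    ("female", "lesion", "t1"): 7,
    ("male", "control", "t2"): 7,
    ("male", "lesion", "t2"): 9,
    ("female", "control", "t2"): 6,
    ("female", "lesion", "t2"): 7,
    ("male", "control", "t3"): 7,
    ("male", "lesion", "t3"): 14,
    ("female", "control", "t3"): 9,
    ("female", "lesion", "t3"): 9,
}

#: default error-count truth at the magnitudes reported for the fitted count
#: model (log error-rate scale).
DEFAULT_TRUE_PARAMS_COUNT: dict = {
    "eta": -0.875,
    "psi": 0.611,
    "beta_x": -0.160,
    "beta_tx": 0.092,
    "beta_w": (-0.210, 0.707, 0.597, -0.240, -1.849, -0.527),
    "beta_t": (1.313, 0.322, 0.263, 0.820, 2.340, 1.254),
}

#: default velocity truth at the reported magnitudes (log cm/s scale).
DEFAULT_TRUE_PARAMS_VELOCITY: dict = {
    "eta": 2.724,
    "psi": 0.264,
    "beta_x": -0.263,
    "beta_tx": -0.017,
    "beta_w": (0.117, 0.137, 0.198, 0.205, 0.423, 0.362),
    "beta_t": (-0.041, -0.074, -0.040, -0.020, -0.095, -0.171),
}

#: default laterality truth: a 74% population left-paw error share with no
#: sex, treatment or week structure (log-odds scale).
DEFAULT_TRUE_PARAMS_LATERALITY: dict = {
    "eta": float(np.log(0.74 / 0.26)),
    "psi": 0.3,
    "beta_x": 0.0,
    "beta_tx": 0.0,
    "beta_w": (0.0,) * 6,
    "beta_t": (0.0,) * 6,
}

FAMILY_DEFAULT_PARAMS = {
    "count": DEFAULT_TRUE_PARAMS_COUNT,
    "velocity": DEFAULT_TRUE_PARAMS_VELOCITY,
    "laterality": DEFAULT_TRUE_PARAMS_LATERALITY,
}


# ---------------------------------------------------------------------------
# pose trials


@dataclass
class SimTrialSpec:
    """Recipe for one synthetic ladder-crossing pose track.

    Slips are listed as ``(paw, start_frame, duration_frames, drop_px)``;
    occlusions as ``(landmark, start_frame, end_frame, likelihood)`` with
    the likelihood below the 0.75 confidence cutoff.
    """

    n_frames: int = 300
    fps: float = 30.0
    rung_spacing_px: float = 40.0
    baseline_y: Mapping[str, float] = field(
        default_factory=lambda: {
            "forepaw_left": 480.0,
            "forepaw_right": 470.0,
            "ankle_left": 520.0,
            "ankle_right": 510.0,
        }
    )
    slip_events: Sequence[tuple[str, int, int, float]] = ()
    occlusion_windows: Sequence[tuple[str, int, int, float]] = ()
    ear_velocity_px_per_frame: float | tuple[float, float] = 10.0
    ear_x0: float = 50.0
    noise_sd_px: float = 2.0
    lead_in_frames: int = 0  # frames before crossing: paws unconfident, ear parked
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.noise_sd_px < 0:
            raise ValueError("noise_sd_px must be non-negative")
        by_paw: dict[str, list[tuple[int, int]]] = {}
        for paw, start, dur, drop in self.slip_events:
            if paw not in self.baseline_y:
                raise ValueError(f"slip on unknown paw {paw!r}")
            if drop <= 0:
                raise ValueError("slip drop_px must be positive")
            if dur < 1:
                raise ValueError("slip duration must be at least 1 frame")
            if not (0 <= start and start + dur <= self.n_frames):
                raise ValueError(f"slip [{start}, {start + dur}) outside [0, {self.n_frames})")
            by_paw.setdefault(paw, []).append((start, start + dur))
        for paw, spans in by_paw.items():
            spans.sort()
            for (s0, e0), (s1, _) in zip(spans, spans[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping slip events on paw {paw!r}")
        for lm, start, end, lik in self.occlusion_windows:
            if not 0 <= lik < 0.75:
                raise ValueError("occlusion likelihood must lie in [0, 0.75)")
            if not (0 <= start < end <= self.n_frames):
                raise ValueError(f"occlusion window [{start}, {end}) out of range")
            if lm not in DEFAULT_LANDMARKS:
                raise ValueError(f"occlusion on unknown landmark {lm!r}")


def _slip_profile(duration: int, drop: float) -> np.ndarray:
    """Trapezoidal excursion: 2-frame ramps around a plateau at ``drop``."""
    if duration <= 2:
        return np.full(duration, drop)
    ramp = min(2, (duration - 1) // 2)
    k = np.arange(duration, dtype=float)
    prof = np.minimum.reduce([np.ones(duration), (k + 1) / (ramp + 1), (duration - k) / (ramp + 1)])
    prof /= prof.max()
    return prof * drop


def ear_x_path(spec: SimTrialSpec) -> np.ndarray:
    """Noiseless ear x trajectory implied by a trial spec.

    The ear holds ``ear_x0`` during the lead-in, then advances at the
    programmed px/frame speed (optionally a different speed per crossing
    half; the speed change falls on the same midpoint frame the velocity
    computation uses, with the middle frame joining the first half).
    """
    n = spec.n_frames
    v = spec.ear_velocity_px_per_frame
    v1, v2 = (v, v) if np.isscalar(v) else v
    li = spec.lead_in_frames
    span = n - 1 - li  # frame intervals of the crossing [li, n-1]
    mid = li + (span + 1) // 2
    step = np.zeros(n)
    k = np.arange(n)
    step[li + 1 :] = np.where(k[li + 1 :] <= mid, v1, v2)
    return spec.ear_x0 + np.cumsum(step)


def generate_pose_trial(spec: SimTrialSpec) -> tuple[KeypointTrack, pd.DataFrame]:
    """Synthesize a 9-landmark track plus its ground-truth slip table.

    Each slip event produces a contiguous downward excursion of the named
    paw's y reaching ``drop_px`` beyond its resting height; likelihoods are
    high (> 0.9) except inside occlusion windows and the lead-in; Gaussian
    jitter of ``noise_sd_px`` is added to every coordinate.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    frames = np.arange(n)

    resting = {
        "right_ear": 200.0,
        "knee_left": 430.0,
        "knee_right": 420.0,
        "tail_base": 300.0,
        "tail_tip": 330.0,
        **dict(spec.baseline_y),
    }
    ear_x = ear_x_path(spec)

    cols: dict[tuple[str, str], np.ndarray] = {}
    for lm in DEFAULT_LANDMARKS:
        if lm == "right_ear":
            x = ear_x.copy()
        else:
            # body landmarks track the ear with a fixed offset
            x = ear_x - 60.0 - 10.0 * DEFAULT_LANDMARKS.index(lm)
        y = np.full(n, resting[lm])
        if lm in spec.baseline_y:
            for paw, start, dur, drop in spec.slip_events:
                if paw == lm:
                    y[start : start + dur] += _slip_profile(dur, drop)
        lik = rng.uniform(0.9, 1.0, size=n)
        if spec.lead_in_frames and lm in PAW_SIDES:
            lik[: spec.lead_in_frames] = rng.uniform(0.1, 0.5, size=spec.lead_in_frames)
        for lm2, start, end, value in spec.occlusion_windows:
            if lm2 == lm:
                lik[start:end] = value
        if spec.noise_sd_px > 0:
            x = x + rng.normal(0.0, spec.noise_sd_px, size=n)
            y = y + rng.normal(0.0, spec.noise_sd_px, size=n)
        cols[(lm, "x")] = x
        cols[(lm, "y")] = y
        cols[(lm, "likelihood")] = lik

    data = pd.DataFrame(
        cols,
        index=pd.Index(frames, name="frame"),
        columns=pd.MultiIndex.from_product(
            [DEFAULT_LANDMARKS, ("x", "y", "likelihood")], names=["bodyparts", "coords"]
        ),
    )
    track = KeypointTrack(data, scorer="synthetic")
    truth = pd.DataFrame(
        [
            {
                "paw": paw,
                "start_frame": start,
                "end_frame": start + dur,
                "duration_frames": dur,
                "drop_px": drop,
            }
            for paw, start, dur, drop in sorted(spec.slip_events, key=lambda e: (e[0], e[1]))
        ],
        columns=["paw", "start_frame", "end_frame", "duration_frames", "drop_px"],
    )
    return track, truth


# ---------------------------------------------------------------------------
# longitudinal behavioral outcomes


@dataclass
class SimStudySpec:
    """Recipe for a longitudinal cohort dataset drawn from the study model.

    ``cell_sizes`` maps (sex, treatment, cohort) to the number of subjects;
    the default copies the published design (101 subjects).  The true
    parameter set is on the linear-predictor scale: log error rate for the
    count family, log cm/s for velocity, log-odds of a left-paw error for
    laterality.
    """

    family: str = "count"
    cell_sizes: Mapping[tuple[str, str, str], int] = field(
        default_factory=lambda: dict(STUDY_CELL_SIZES)
    )
    eta: float = DEFAULT_TRUE_PARAMS_COUNT["eta"]
    psi: float = DEFAULT_TRUE_PARAMS_COUNT["psi"]
    beta_x: float = DEFAULT_TRUE_PARAMS_COUNT["beta_x"]
    beta_tx: float = DEFAULT_TRUE_PARAMS_COUNT["beta_tx"]
    beta_w: Sequence[float] = DEFAULT_TRUE_PARAMS_COUNT["beta_w"]
    beta_t: Sequence[float] = DEFAULT_TRUE_PARAMS_COUNT["beta_t"]
    sigma_obs: float = 0.2  # log-scale observation SD, velocity family
    laterality_total_rate: float = 2.0  # mean total errors feeding the binomial
    seed: int = 0

    def validate(self) -> None:
        if self.family not in ("count", "velocity", "laterality"):
            raise ValueError(f"unknown outcome family {self.family!r}")
        if self.psi <= 0:
            raise ValueError("psi must be positive")
        if len(self.beta_w) != 6 or len(self.beta_t) != 6:
            raise ValueError("beta_w and beta_t must each have six entries")
        for name, value in [
            ("eta", self.eta),
            ("psi", self.psi),
            ("beta_x", self.beta_x),
            ("beta_tx", self.beta_tx),
            *[(f"beta_w[{i + 1}]", v) for i, v in enumerate(self.beta_w)],
            *[(f"beta_t[{i + 1}]", v) for i, v in enumerate(self.beta_t)],
        ]:
            if not np.isfinite(value):
                raise ValueError(f"non-finite true parameter {name}")
        for cell, n in self.cell_sizes.items():
            if cell[2] not in COHORT_LAST_WEEK:
                raise ValueError(f"unknown cohort in cell {cell}")
            if n < 0:
                raise ValueError(f"negative cell size for {cell}")


def study_spec_for(family: str, seed: int = 0, **overrides) -> SimStudySpec:
    """Study spec with the family's default true parameter set."""
    params = dict(FAMILY_DEFAULT_PARAMS[family])
    params.update(overrides)
    return SimStudySpec(family=family, seed=seed, **params)


def _linear_predictor(
    spec: SimStudySpec, sex_code: float, treat_code: float, week: int
) -> float:
    mu = sex_code * spec.beta_x + treat_code * sex_code * spec.beta_tx
    if week > 0:
        mu += spec.beta_w[week - 1] + treat_code * spec.beta_t[week - 1]
    return mu


def simulate_longitudinal_outcomes(spec: SimStudySpec) -> pd.DataFrame:
    """Draw a per subject-week outcome table from the study model.

    Subject intercepts are drawn from Normal(eta, psi); per observed week
    (baseline plus the weeks the subject's cohort is still on study) the
    linear predictor mu follows the random-intercept + 14-fixed-effect
    structure with sex coded female = -0.5 / male = +0.5 and treatment coded
    control = 0 / lesion = 1.  Outcomes: ``count`` -> errors ~ Poisson(exp mu);
    ``velocity`` -> cm/s ~ lognormal(mu, sigma_obs); ``laterality`` ->
    total ~ Poisson(laterality_total_rate), left ~ Binomial(total,
    logistic(mu)).  True gamma and mu are carried in ``true_*`` columns for
    recovery checks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    sid = 0
    for (sex, treatment, cohort), n_cell in sorted(spec.cell_sizes.items()):
        last_week = COHORT_LAST_WEEK[cohort]
        for _ in range(n_cell):
            sid += 1
            subject = f"s{sid:03d}"
            gamma = spec.eta + spec.psi * rng.standard_normal()
            sex_code = -0.5 if sex == "female" else 0.5
            treat_code = 0.0 if treatment == "control" else 1.0
            for week in range(0, last_week + 1):
                mu = gamma + _linear_predictor(spec, sex_code, treat_code, week)
                if not np.isfinite(mu):
                    raise ValueError(
                        f"non-finite linear predictor for subject {subject}, week {week}"
                    )
                row = {
                    "subject": subject,
                    "sex": sex,
                    "treatment": treatment,
                    "cohort": cohort,
                    "week": week,
                    "true_gamma": gamma,
                    "true_mu": mu,
                }
                if spec.family == "count":
                    row["errors"] = int(rng.poisson(np.exp(mu)))
                elif spec.family == "velocity":
                    row["velocity_cm_s"] = float(
                        np.exp(mu + spec.sigma_obs * rng.standard_normal())
                    )
                else:
                    total = int(rng.poisson(spec.laterality_total_rate))
                    left = int(rng.binomial(total, expit(mu))) if total > 0 else 0
                    row["total_errors"] = total
                    row["left_errors"] = left
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-rater TH count tables

#: default per-(treatment, cohort) animal counts: 27 animals, echoing the
#: residual degrees of freedom of the published asymmetry model.
DEFAULT_TH_CELL_SIZES: dict[tuple[str, str], int] = {
    ("control", "t1"): 4,
    ("control", "t2"): 5,
    ("control", "t3"): 4,
    ("lesion", "t1"): 5,
    ("lesion", "t2"): 4,
    ("lesion", "t3"): 5,
}

#: default true asymmetry index per (treatment, cohort): controls near
#: hemispheric symmetry, lesioned animals at the reported preservation levels.
DEFAULT_TRUE_AI: dict[tuple[str, str], float] = {
    ("control", "t1"): 0.971,
    ("control", "t2"): 1.015,
    ("control", "t3"): 0.995,
    ("lesion", "t1"): 0.531,
    ("lesion", "t2"): 0.554,
    ("lesion", "t3"): 0.402,
}


def simulate_th_counts(
    cell_sizes: Mapping[tuple[str, str], int] | None = None,
    true_ai: Mapping[tuple[str, str], float] | float | None = None,
    *,
    rater_sd: float = 4.0,
    contra_mean: float = 80.0,
    contra_sd: float = 10.0,
    ai_noise_sd: float = 0.0,
    section_sd: float = 5.0,
    n_sections: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-rater hemispheric TH-positive soma count table (long format).

    Per animal, a contralateral mean count is drawn around ``contra_mean``;
    the injected hemisphere's mean is contralateral x AI x lognormal noise
    (``ai_noise_sd`` on the log scale).  Per hemisphere, ``n_sections``
    section-level true counts vary by ``section_sd`` and each rater reads
    every section with independent Normal(0, rater_sd) error.  Counts are
    rounded to whole somata and floored at zero.
    """
    cells = dict(cell_sizes) if cell_sizes is not None else dict(DEFAULT_TH_CELL_SIZES)
    if true_ai is None:
        ai_map: Mapping = dict(DEFAULT_TRUE_AI)
    elif np.isscalar(true_ai):
        ai_map = {cell: float(true_ai) for cell in cells}
    else:
        ai_map = dict(true_ai)
    for cell in cells:
        if ai_map.get(cell, 0.0) <= 0:
            raise ValueError(f"true AI must be positive for cell {cell}")
    if not 1 <= n_sections <= 3:
        raise ValueError("n_sections must be between 1 and 3")

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    aid = 0
    for (treatment, cohort), n_cell in sorted(cells.items()):
        ai_true = float(ai_map[cell := (treatment, cohort)])
        for _ in range(n_cell):
            aid += 1
            animal = f"a{aid:02d}"
            contra = contra_mean + contra_sd * rng.standard_normal()
            contra = max(contra, 5.0)
            injected = contra * ai_true
            if ai_noise_sd > 0:
                injected *= np.exp(ai_noise_sd * rng.standard_normal())
            for hemisphere, mean_count in (("injected", injected), ("contralateral", contra)):
                for section in range(1, n_sections + 1):
                    true_section = mean_count + (
                        section_sd * rng.standard_normal() if section_sd > 0 else 0.0
                    )
                    true_section = max(np.round(true_section), 0.0)
                    for rater in (1, 2):
                        reading = true_section + (
                            rater_sd * rng.standard_normal() if rater_sd > 0 else 0.0
                        )
                        rows.append(
                            {
                                "animal": animal,
                                "treatment": treatment,
                                "cohort": cohort,
                                "hemisphere": hemisphere,
                                "rater": rater,
                                "section": section,
                                "count": max(float(np.round(reading)), 0.0),
                                "true_ai": ai_true,
                            }
                        )
    return pd.DataFrame(rows)
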