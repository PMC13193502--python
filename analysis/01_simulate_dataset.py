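"""Generate the synthetic study: pose trials, behavioral outcomes, TH counts.

Writes a handful of example ladder-crossing pose tracks (DLC CSV dialect)
with their ground-truth slip tables to scratch/pose_trials/, and the
longitudinal behavioral outcome tables plus the two-rater TH count table
to results/.
"""

from pathlib import Path

import numpy as np

from laddergait.pose_io import write_dlc_csv
from laddergait.synthetic_data import (
    SimTrialSpec,
    generate_pose_trial,
    simulate_longitudinal_outcomes,
    simulate_th_counts,
    study_spec_for,
)

SEED = 2024
RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "pose_trials"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # a dozen example crossings with known slips, varying noise and occlusion
    n_events_total = 0
    truths = []
    for i in range(12):
        paws = ["forepaw_left", "forepaw_right", "ankle_left", "ankle_right"]
        events = [
            (paws[int(rng.integers(4))], s, int(rng.integers(6, 15)),
             float(rng.uniform(50, 90)))
            for s in (60, 160, 260)
            if rng.uniform() < 0.6
        ]
        spec = SimTrialSpec(
            n_frames=400,
            slip_events=events,
            occlusion_windows=[("ankle_left", 330, 345, 0.3)] if i % 3 == 0 else [],
            noise_sd_px=float(rng.uniform(1.0, 4.0)),
            seed=int(rng.integers(2**31 - 1)),
        )
        track, truth = generate_pose_trial(spec)
        write_dlc_csv(track, SCRATCH / f"trial_{i:02d}.csv")
        truth.insert(0, "trial", i)
        truths.append(truth)
        n_events_total += len(truth)
    import pandas as pd

    pd.concat(truths, ignore_index=True).to_csv(
        RESULTS / "pose_ground_truth_events.csv", index=False
    )
    print(f"wrote 12 pose trials ({n_events_total} injected slips) to {SCRATCH}")

    # longitudinal behavioral outcomes at the published design (101 subjects)
    for family, fname in [
        ("count", "outcomes_errors.csv"),
        ("velocity", "outcomes_velocity.csv"),
        ("laterality", "outcomes_laterality.csv"),
    ]:
        df = simulate_longitudinal_outcomes(study_spec_for(family, seed=SEED))
        df.to_csv(RESULTS / fname, index=False)
        print(f"{fname}: {len(df)} subject-week rows, "
              f"{df['subject'].nunique()} subjects")

    th = simulate_th_counts(seed=SEED)
    th.to_csv(RESULTS / "th_counts.csv", index=False)
    print(f"th_counts.csv: {th['animal'].nunique()} animals, "
          f"{len(th)} section-level readings")


if __name__ == "__main__":
    main()
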