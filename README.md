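# laddergait

Quantifying rodent skilled locomotion on the horizontal ladder from
markerless pose tracking, and the statistics that turn those measures
into inference about partial dopaminergic lesions.

Rats with low-dose unilateral 6-OHDA lesions of the substantia nigra
pars compacta show subtle, time-varying deficits: more footfall errors
(a paw slipping below the rung plane) with largely preserved crossing
velocity. This package implements the full analysis path from
DeepLabCut-style keypoint CSVs to those conclusions, for researchers
running ladder-crossing assays with accessible video hardware:

* **pose_io** — read/write DLC three-row-header CSVs, validate tracks,
  resolve trial bounds (crossing onset / end of apparatus).
* **footfall** — per-paw trimmed-mean baselines, likelihood gating
  (confidence > 0.75), adaptive threshold (baseline + 35 px), epoch
  consolidation with hysteresis, per-event max drop and duration.
* **kinematics** — pixel→cm calibration from the 4 cm rung spacing and
  ear-based velocity for whole trials and halves.
* **behavior_models** — multi-level Bayesian regressions sharing one
  linear predictor

  `mu[s,w] = gamma[s] + X[s]·beta_x + T[s]·X[s]·beta_tx + W[w]·beta_w + T[s]·(W[w]·beta_t)`

  with subject intercepts gamma[s] ~ Normal(eta, psi), for Poisson
  error counts, lognormal velocities and binomial left-paw laterality;
  condition summaries, post-hoc linear trends, R-hat/ESS diagnostics.
  Sampling is NUTS with analytic gradients (`laddergait.mcmc`).
* **histology** — TH asymmetry index AI = I/C, log(AI) linear model
  with Holm-corrected contrasts, sensitivity models, two-way
  absolute-agreement ICCs and Bland–Altman agreement.
* **synthetic_data** — generators for pose trials with ground-truth
  slips, longitudinal cohorts at the published design (101 subjects,
  staggered t1/t2/t3 attrition), and two-rater TH count tables, so the
  whole pipeline runs and is tested without raw video or histology.

## Worked example

```python
import numpy as np
from laddergait import footfall as ff, kinematics as kin
from laddergait.synthetic_data import SimTrialSpec, generate_pose_trial

spec = SimTrialSpec(
    slip_events=[("forepaw_left", 50, 10, 60.0), ("ankle_right", 120, 8, 70.0)],
    noise_sd_px=3.0, seed=1,
)
track, truth = generate_pose_trial(spec)
epochs, skipped = ff.detect_track_epochs(track)
print(ff.summarize_errors(epochs))
cal = kin.calibrate([40.0] * 6)
print(kin.compute_velocity(track, (0, 299), cal).v_total)
```

prints

```
{'total_errors': 2, 'left_errors': 1, 'right_errors': 1,
 'left_fraction': 0.5, 'unclosed_errors': 0}
29.947462738343994
```

— the two injected slips are each consolidated into one epoch (one per
side, so the left fraction is 0.5), and the programmed 10 px/frame ear
speed comes back as ≈ 30 cm/s given 0.1 cm/px and 30 fps.

The full analysis lives in `analysis/`, each script a thin driver over
the library:

1. `01_simulate_dataset.py` — pose trials (to `scratch/`), behavioral
   outcome tables and TH counts (to `results/`),
2. `02_extract_gait_measures.py` — detection + velocity per trial,
   compared against ground truth,
3. `03_fit_behavior_models.py` — the three Bayesian fits with
   parameter tables, condition estimates and trends,
4. `04_histology_asymmetry.py` — AI model, contrasts, ICC,
   Bland–Altman.

A small CLI mirrors the per-file operations:
`laddergait footfalls --track FILE`, `laddergait velocity ...`,
`laddergait histology --counts FILE`.

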