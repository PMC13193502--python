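# Methods

`laddergait` quantifies skilled locomotion of rats crossing a horizontal
ladder from markerless pose-tracking output, and provides the downstream
statistics used to characterize partial unilateral dopaminergic (6-OHDA)
lesions of the substantia nigra pars compacta: footfall-error counts,
calibrated crossing velocity, multi-level Bayesian models of both over a
six-week design, left/right paw laterality, and tyrosine-hydroxylase
(TH) hemispheric asymmetry. This note records the models, the defaults
and why, the numerical choices, and what the synthetic data do and do
not establish.

## Footfall-error detection

Input is a DeepLabCut-style table: per frame and landmark, pixel
coordinates (x, y) and a tracker likelihood in [0, 1]. Image
coordinates are downward-positive, so a slip below the rung plane is a
y *increase*; a `flip_y` flag accommodates upward-positive data.

1. **Likelihood gating.** Samples with likelihood ≤ 0.75 (strict
   inequality retained: exactly 0.75 is unconfirmed) or with missing
   coordinates are excluded from all baseline estimation and from the
   detector's state transitions. They can never open or close an epoch.
2. **Per-paw baseline.** The resting height of each paw is a symmetric
   trimmed mean of its confident y samples, computed per trial. The
   trim fraction is 10% per tail (a common robust-mean choice; the
   sensible range is covered by tests), with a minimum of 30 confident
   samples — below that the paw is flagged and skipped rather than
   analyzed from noise.
3. **Adaptive threshold and hysteresis.** An error epoch opens at the
   first confident sample whose excursion beyond baseline exceeds a
   fixed offset (35 px default) and closes at the first subsequent
   confident sample at or above baseline. Opening at the threshold but
   closing at the baseline consolidates one physical slip — including
   transient re-crossings of the threshold — into a single epoch, so
   events are never double counted. An epoch still open at the last
   frame is emitted with `closed=False` and counts as one error,
   preserving auditability.
4. **Per-epoch metrics.** Maximum drop (px beyond baseline) and
   duration (frames, half-open interval, 0-based).

Left paws are partially occluded in a right-side lateral view; no
correction beyond likelihood gating is applied, matching the
acquisition geometry's acknowledged limitation.

A brute-force rescan of the confident subsequence (kept in the test
suite and the acceptance script, independent of the state machine) must
reproduce every epoch exactly — count, boundaries, max drop — on random
tracks with noise, occlusions and multiple slips.

## Velocity and calibration

Crossing velocity uses the right-ear landmark (least occluded): net
horizontal displacement between trial bounds divided by elapsed time
(frames / fps, 30 fps default), not path length. Halves split the frame
interval at its temporal midpoint; an odd interval assigns the middle
frame to the first half (deterministic tie-break), and each half uses
its own displacement over its own time so distances add up exactly.
Whether "halves" should be temporal or spatial is not decidable from
the task description; time was chosen and the alternative noted. If a
bound frame is unconfident, the nearest confident sample within a
5-frame window substitutes (flagged); none within the window is an
error.

Pixel scale: the 4 cm rung gap is measured six times (left, center,
right, twice each); cm/px = 4 / mean(gaps). The measurement spread is
retained for QC. A rolling-mean instantaneous-velocity trace (5-frame
window) is available for plots only.

Trial bounds, when not given explicitly, are auto-detected: start at
the first frame where all four paw landmarks are simultaneously
confident *and* the ear advances ≥ 2 px/frame over 3 frames
(operationalizing "stably positioned and initiated forward movement"
from coordinates alone); end when the confident ear x passes the
end-of-apparatus coordinate. Selecting among repeated trials of one
session is exposed as a ranking helper (fewest zero-velocity runs)
rather than an automatic choice, since the original stop-counting
criterion is an interpretation.

## Behavioral models

All three outcomes share one linear predictor for subject *s* in week
*w*:

```
mu[s,w] = gamma[s] + X[s]·beta_x + T[s]·X[s]·beta_tx
          + W[w]·beta_w + T[s]·(W[w]·beta_t)
```

with gamma[s] ~ Normal(eta, psi) a subject random intercept, sex coded
female = −0.5 / male = +0.5, treatment coded control = 0 / lesion = 1,
and six nominal week dummies (all zero at the week-0 baseline): one
random parameter per subject plus 14 fixed effects. Weeks are nominal,
not ordered, so non-monotone trajectories (early disruption, later
recovery) are representable. Families:

* error counts ~ Poisson(exp(mu)),
* velocities ~ lognormal(mu, sigma_v) — chosen so the parameters live
  on the log(cm/s) scale; a gamma observation model is exposed behind a
  flag as an alternative,
* left-paw errors ~ Binomial(total, logistic(mu)); rows with zero total
  errors carry no information about the split and are excluded with a
  warning.

**Priors** are weakly informative and configurable: Normal(0, 5) on
eta, Normal(0, 2) on each beta, half-Normal(1) on psi and sigma_v. The
original analysis's exact priors are not reproducible from the
available material, so parameter-recovery simulations are the guardrail
that these defaults are uninformative enough at the study's sample
sizes.

**Sampling** uses a No-U-Turn sampler written in this package
(`laddergait.mcmc`) with closed-form gradients of each family's log
posterior, a non-centered parameterization gamma = eta + psi·z to avoid
funnel geometry, dual-averaging step-size adaptation (target acceptance
0.9) and a diagonal mass matrix re-estimated once from the middle of
warmup. Defaults: 4 chains, 1000 warmup + 1000 kept draws; recovery
simulations use 2 chains of 500 + 500, which keeps effective sample
sizes in the several hundreds. R-hat and ESS per parameter come from
arviz; a fit with max R-hat > 1.01 or divergent transitions is flagged
(`converged=False`, warning), never silently accepted. All seeds are
explicit; the same seed reproduces draws bit-identically.

**Condition summaries** set gamma = eta (an "average subject"), map mu
through the inverse link per draw, average across weeks on the response
scale (matching how error rates and cm/s are reported), and summarize
with nested 80%/95% credible intervals. Averaging exp(·) across draws
is deliberately Jensen-inflated for conditions with more posterior
uncertainty; null-simulation checks therefore compare conditions via
per-draw differences, not via point estimates.

**Post-hoc trends** are descriptive: per draw, each subject's expected
response-scale value per observed post-baseline week (full model,
subject's own intercept), then a pooled OLS slope against week within
each treatment-by-sex group, summarized across draws.

## TH asymmetry

Asymmetry index AI = I/C (injected over contralateral TH-positive soma
counts); log(AI) (natural log — the base is a documented choice) is the
primary outcome, 0 = symmetry, negative = ipsilateral depletion.
Counts are averaged across sections within animal, hemisphere and
rater first, then across raters, keeping the animal as the unit of
analysis. The primary model is OLS of log(AI) on treatment, cohort time
(unordered 3-level factor: 2, 4, 6 weeks) and their interaction, with
type-II F tests; sex is excluded because histology cells are small and
sex-unbalanced. Control-vs-lesion estimated-marginal-mean contrasts per
time point use the model's t distribution with Holm step-down
correction (statsmodels). Sensitivity analyses rerun the model on the
raw difference I − C and on preservation percent AI × 100 (which is an
exact 100× rescaling of the AI-scale model).

Inter-rater agreement: two-way random-effects absolute-agreement ICCs,
single-measure and average-measure over k = 2 raters, with F-based 95%
confidence intervals (computed via pingouin and cross-checked against
the ANOVA mean-squares decomposition in tests); a table with no
between-target variance is returned flagged degenerate. Bland–Altman
limits are mean ± 1.96 SD of rater differences, optionally stratified
by hemisphere.

## Synthetic data: what it emulates, and what it does not

The generators stand in for the study's videos, behavioral records and
histology, which are not deposited.

* **Pose trials**: 9 landmarks (both forepaws, hind ankle/knee pairs —
  the ankle is the tracked hind-paw point — tail base/tip, right ear)
  at 30 fps; slips are trapezoidal downward excursions of programmed
  drop and duration; occlusions set likelihood below the 0.75 cutoff in
  programmed windows; Gaussian pixel jitter (2 px default) on all
  coordinates; the ear advances monotonically, optionally at different
  speeds per crossing half. Overlapping slips on one paw are rejected.
* **Longitudinal outcomes**: drawn from the model above at the
  published design — 101 subjects in twelve sex × treatment × cohort
  cells (9/11/6/7, 7/9/6/7, 7/14/9/9), with staggered attrition (t1
  observed through week 2, t2 through 4, t3 through 6, all with a
  baseline week). Default true parameters echo the reported posterior
  magnitudes for each family (e.g. count-model eta = −0.875,
  psi = 0.611, week-1 treatment effect 1.313; velocity eta = 2.724; a
  74% left-paw share). Velocity observation noise sigma_obs defaults
  to 0.2 on the log scale; binomial totals draw from
  Poisson(2.0) — both package choices, since the original likelihood
  details are not available. 
* **TH counts**: 27 animals in six treatment × cohort cells (4–5 per
  cell, echoing the published residual degrees of freedom), three
  sections per hemisphere, two raters with independent reading error,
  true AI per cell defaulting to the reported preservation levels
  (controls ≈ 1, lesions 0.40–0.55).

What passing tests on these data show: the detector is exactly
equivalent to its specification, the kinematics are exact, the samplers
are calibrated (interval coverage compatible with nominal at the
study's n), and the histology statistics match hand-computed oracles.
What they do not show: robustness to real tracking pathologies
(identity swaps, systematic likelihood miscalibration, lens
distortion), to non-Poisson overdispersion in real error counts, or to
real raters' non-Gaussian disagreements. The simulators are idealized
by construction.

## Problem sizes and tolerances

Recovery checks use 20 replicate studies per family at the full 101
-subject design with 2 × (500 + 500) draws (the acceptance script uses
10 replicates per family); coverage is tested with a binomial test at
alpha = 0.01 against the nominal 0.95. Exact arithmetic (calibration,
constant-velocity trials, oracle equivalence, Holm example) is asserted
to 1e-9 relative or exactly. Degenerate inputs — empty epoch lists,
zero-error sessions (left fraction undefined), zero between-target
variance, unclosed epochs, unconfident bounds — return flagged values
or typed errors, never silent defaults.

## Known limitations

* Single-animal DLC files only; no HDF5 input.
* No gait-phase segmentation, stride parameters or joint kinematics —
  the two outcomes are deliberate.
* The binomial-logit laterality model and the priors are this package's
  interpretations where the original supplementary details were
  unavailable; both are configurable.
* The hand-written NUTS engine targets these specific posteriors
  (≈ 120 dimensions, smooth, log-concave likelihoods); it is not a
  general-purpose PPL.
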