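"""Fit the three multi-level Bayesian models to the simulated cohort.

Fits the Poisson error-count model, the lognormal velocity model and the
binomial left-paw laterality model to the outcome tables from
01_simulate_dataset.py, then writes population-parameter summaries
(mirroring the published table layout), response-scale condition
estimates and post-hoc linear trends to results/.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from laddergait import behavior_models as bm

RESULTS = Path(__file__).resolve().parents[1] / "results"
CONFIG = bm.SamplerConfig(chains=2, warmup=600, draws=600, seed=7)


def main() -> None:
    # --- error counts -------------------------------------------------------
    errors = pd.read_csv(RESULTS / "outcomes_errors.csv")
    design = bm.build_design(errors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = bm.fit_error_model(design, errors["errors"], config=CONFIG)
    tab = bm.summary_table(fit)
    tab.to_csv(RESULTS / "model_errors_parameters.csv", index=False)
    cond = bm.condition_summaries(fit)
    cond.to_csv(RESULTS / "model_errors_conditions.csv", index=False)
    trends = bm.posthoc_trends(fit)
    trends.to_csv(RESULTS / "model_errors_trends.csv", index=False)
    print("== footfall errors (Poisson, log link) ==")
    print(f"max R-hat {fit.max_rhat:.4f}, min ESS {min(fit.ess.values()):.0f}, "
          f"divergences {fit.n_divergent}")
    print(tab[["effect", "parameter", "mean", "ci95_low", "ci95_high"]]
          .to_string(index=False))
    base = cond.query("condition == 'baseline'")["mean"].mean()
    exp_ = cond.query("condition == 'experimental'")["mean"].mean()
    ctrl = cond.query("condition == 'control'")["mean"].mean()
    print(f"expected errors/session: baseline {base:.3f}, control {ctrl:.3f}, "
          f"lesioned {exp_:.3f}")

    # --- velocity ----------------------------------------------------------
    vel = pd.read_csv(RESULTS / "outcomes_velocity.csv")
    design_v = bm.build_design(vel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_v = bm.fit_velocity_model(design_v, vel["velocity_cm_s"], config=CONFIG)
    bm.summary_table(fit_v).to_csv(RESULTS / "model_velocity_parameters.csv", index=False)
    cond_v = bm.condition_summaries(fit_v)
    cond_v.to_csv(RESULTS / "model_velocity_conditions.csv", index=False)
    bm.posthoc_trends(fit_v).to_csv(RESULTS / "model_velocity_trends.csv", index=False)
    base_v = cond_v[cond_v["condition"] == "baseline"]["mean"].mean()
    print("\n== velocity (lognormal, log cm/s) ==")
    print(f"max R-hat {fit_v.max_rhat:.4f}; baseline velocity {base_v:.2f} cm/s")

    # --- laterality ---------------------------------------------------------
    lat = pd.read_csv(RESULTS / "outcomes_laterality.csv")
    design_l = bm.build_design(lat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_l, _ = bm.fit_laterality_model(
            design_l, lat["left_errors"], lat["total_errors"], config=CONFIG
        )
    bm.summary_table(fit_l).to_csv(RESULTS / "model_laterality_parameters.csv", index=False)
    p = expit(fit_l.flat(fit_l.eta))
    lo, hi = np.quantile(p, [0.025, 0.975])
    print("\n== left-paw laterality (binomial, logit link) ==")
    print(f"population left-paw error proportion {100 * p.mean():.1f}% "
          f"[95% CI {100 * lo:.1f}, {100 * hi:.1f}]")


if __name__ == "__main__":
    main()
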