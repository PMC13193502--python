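"""Design coding, link behavior and sampler contracts for the behavioral models.

Heavy parameter-recovery simulations live in the acceptance suite; here the
fits use small simulated cohorts and short chains to exercise contracts.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from laddergait import behavior_models as bm
from laddergait.mcmc import nuts_sample
from laddergait.synthetic_data import SimStudySpec, simulate_longitudinal_outcomes

SMALL_CELLS = {
    ("female", "control", "t2"): 4,
    ("female", "lesion", "t2"): 4,
    ("male", "control", "t2"): 4,
    ("male", "lesion", "t2"): 4,
}
FAST = bm.SamplerConfig(chains=2, warmup=250, draws=250, seed=7)


def small_sim(family="count", **kw):
    defaults = dict(
        family=family, cell_sizes=SMALL_CELLS, eta=0.3, psi=0.3, beta_x=0.2,
        beta_tx=0.0, beta_w=(0.1, 0.2, 0.1, 0.0, 0.0, 0.0),
        beta_t=(0.4, 0.4, 0.4, 0.0, 0.0, 0.0), seed=21,
    )
    defaults.update(kw)
    return simulate_longitudinal_outcomes(SimStudySpec(**defaults))


class TestDesign:
    def test_baseline_row_has_zero_week_dummies(self):
        df = small_sim()
        d = bm.build_design(df)
        base_rows = d.fixed[d.weeks == 0]
        assert np.all(base_rows[:, 2:] == 0)

    def test_control_male_week3_contribution(self):
        row = bm._fixed_row(0.5, 0.0, 3)
        beta = np.arange(1.0, 15.0)  # beta_x=1, beta_tx=2, beta_w=3..8, beta_t=9..14
        # mu - gamma = 0.5*beta_x + beta_w[3]
        assert row @ beta == pytest.approx(0.5 * 1 + 5)

    def test_lesion_female_week5_contribution(self):
        row = bm._fixed_row(-0.5, 1.0, 5)
        beta = np.arange(1.0, 15.0)
        # -0.5*beta_x - 0.5*beta_tx + beta_w[5] + beta_t[5]
        assert row @ beta == pytest.approx(-0.5 * 1 - 0.5 * 2 + 7 + 13)

    def test_fixed_effect_count_is_fourteen(self):
        d = bm.build_design(small_sim())
        assert d.fixed.shape[1] == 14
        assert len(bm.FIXED_NAMES) == 14

    def test_unknown_levels_rejected(self):
        df = small_sim()
        bad = df.copy()
        bad.loc[0, "sex"] = "unknown"
        with pytest.raises(ValueError, match="sex"):
            bm.build_design(bad)
        bad = df.copy()
        bad.loc[0, "week"] = 9
        with pytest.raises(ValueError, match="week"):
            bm.build_design(bad)

    def test_attrition_violation_rejected(self):
        df = small_sim()
        bad = df.copy()
        bad["cohort"] = "t1"  # claims everyone stopped at week 2, but weeks go to 4
        with pytest.raises(ValueError, match="endpoint"):
            bm.build_design(bad)


class TestNutsEngine:
    def test_recovers_gaussian_moments(self):
        # correlated 3-D Gaussian with known mean and covariance
        cov = np.array([[1.0, 0.6, 0.0], [0.6, 2.0, 0.3], [0.0, 0.3, 0.5]])
        prec = np.linalg.inv(cov)
        mean = np.array([1.0, -2.0, 0.5])

        def lp(q):
            d = q - mean
            return -0.5 * d @ prec @ d, -prec @ d

        res = nuts_sample(lp, np.zeros(3), n_warmup=500, n_draws=2000, seed=3)
        est_mean = res.draws.mean(axis=0)
        est_cov = np.cov(res.draws.T)
        np.testing.assert_allclose(est_mean, mean, atol=0.15)
        np.testing.assert_allclose(est_cov, cov, atol=0.35)

    def test_same_seed_identical_draws(self):
        def lp(q):
            return -0.5 * q @ q, -q

        a = nuts_sample(lp, np.zeros(2), n_warmup=100, n_draws=100, seed=5)
        b = nuts_sample(lp, np.zeros(2), n_warmup=100, n_draws=100, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)


class TestFits:
    def test_count_fit_reproducible_and_sane(self):
        df = small_sim()
        d = bm.build_design(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = bm.fit_error_model(d, df["errors"], config=FAST)
            f2 = bm.fit_error_model(d, df["errors"], config=FAST)
        np.testing.assert_array_equal(f1.eta, f2.eta)
        np.testing.assert_array_equal(f1.beta, f2.beta)
        assert np.all(f1.flat(f1.psi) > 0)

    def test_all_zero_counts_push_eta_negative(self):
        df = small_sim()
        df["errors"] = 0
        d = bm.build_design(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = bm.fit_error_model(d, df["errors"], config=FAST)
        assert fit.flat(fit.eta).mean() < -1.5

    def test_count_validation(self):
        df = small_sim()
        d = bm.build_design(df)
        with pytest.raises(ValueError):
            bm.fit_error_model(d, df["errors"] - 0.5)

    def test_velocity_location_shift_on_log_scale(self):
        df = small_sim("velocity", eta=2.7, sigma_obs=0.15)
        d = bm.build_design(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = bm.fit_velocity_model(d, df["velocity_cm_s"], config=FAST)
            f2 = bm.fit_velocity_model(d, 2.0 * df["velocity_cm_s"], config=FAST)
        shift = f2.flat(f2.eta).mean() - f1.flat(f1.eta).mean()
        assert shift == pytest.approx(np.log(2), abs=0.1)
        bdiff = np.abs(f2.flat(f2.beta).mean(axis=0) - f1.flat(f1.beta).mean(axis=0))
        assert np.all(bdiff < 0.25)

    def test_velocity_rejects_nonpositive(self):
        df = small_sim("velocity")
        d = bm.build_design(df)
        v = df["velocity_cm_s"].copy()
        v.iloc[0] = 0.0
        with pytest.raises(ValueError):
            bm.fit_velocity_model(d, v)

    def test_laterality_all_left_pushes_proportion_to_one(self):
        df = small_sim("laterality")
        df["total_errors"] = 5
        df["left_errors"] = 5
        d = bm.build_design(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, _ = bm.fit_laterality_model(
                d, df["left_errors"], df["total_errors"], config=FAST
            )
        assert expit(fit.flat(fit.eta)).mean() > 0.9

    def test_laterality_excludes_zero_total_rows(self):
        df = small_sim("laterality", laterality_total_rate=0.7)
        d = bm.build_design(df)
        n_zero = int((df["total_errors"] == 0).sum())
        assert n_zero > 0
        with pytest.warns(UserWarning, match="zero total"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                fit, d_used = bm.fit_laterality_model(
                    d, df["left_errors"], df["total_errors"], config=FAST
                )
        assert d_used.n_rows == d.n_rows - n_zero


class TestSummaries:
    # summaries average over all six weeks, so the cohort must reach week 6
    NULL_CELLS = {
        ("female", "control", "t3"): 4,
        ("female", "lesion", "t3"): 4,
        ("male", "control", "t3"): 4,
        ("male", "lesion", "t3"): 4,
    }

    @pytest.fixture(scope="class")
    def null_fit(self):
        df = simulate_longitudinal_outcomes(
            SimStudySpec(
                cell_sizes=self.NULL_CELLS, eta=0.5, psi=0.3, beta_x=0, beta_tx=0,
                beta_w=(0,) * 6, beta_t=(0,) * 6, seed=31,
            )
        )
        d = bm.build_design(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return bm.fit_error_model(
                d, df["errors"], config=bm.SamplerConfig(chains=2, warmup=300, draws=300, seed=2)
            )

    def test_condition_draws_and_interval_nesting(self, null_fit):
        # (the inferential null-coincidence property is checked at the full
        # study design in the end-to-end suite; a 16-subject cohort is too
        # small for it to hold reliably)
        draws = bm.condition_draws(null_fit)
        assert set(draws) == {
            (c, s)
            for c in ("baseline", "control", "experimental")
            for s in ("female", "male")
        }
        n_draws = null_fit.flat(null_fit.eta).size
        assert all(v.shape == (n_draws,) and np.all(v > 0) for v in draws.values())
        summ = bm.condition_summaries(null_fit)
        # CI80 nested inside CI95
        assert (summ["ci80_low"] >= summ["ci95_low"]).all()
        assert (summ["ci80_high"] <= summ["ci95_high"]).all()

    def test_baseline_summary_uses_zero_dummies(self, null_fit):
        # with gamma = eta and no week dummies, baseline must equal
        # mean over draws of exp(eta + X * beta_x)
        summ = bm.condition_summaries(null_fit).set_index(["condition", "sex"])
        eta = null_fit.flat(null_fit.eta)
        bx = null_fit.flat(null_fit.beta_named("beta_x"))
        expected = np.exp(eta + 0.5 * bx).mean()
        assert summ.loc[("baseline", "male"), "mean"] == pytest.approx(expected, rel=1e-9)

    def test_flat_trend_ci_covers_zero(self, null_fit):
        trends = bm.posthoc_trends(null_fit)
        assert ((trends["ci_low"] <= 0) & (trends["ci_high"] >= 0)).all()

    def test_trend_excludes_baseline_week(self, null_fit):
        trends = bm.posthoc_trends(null_fit)
        # six weekly sessions (t3 cohort, baseline excluded) per subject
        per_group_subjects = 4
        assert (trends["n_points"] == per_group_subjects * 6).all()

    def test_summary_table_layout(self, null_fit):
        tab = bm.summary_table(null_fit)
        assert list(tab["parameter"][:2]) == ["eta", "psi"]
        assert len(tab) == 16  # eta, psi, 14 fixed effects
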