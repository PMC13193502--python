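"""Asymmetry index, log-ratio model, Holm contrasts, ICC and Bland-Altman."""

import numpy as np
import pandas as pd
import pytest

from laddergait import histology as hist
from laddergait.synthetic_data import simulate_th_counts


def count_rows(animal, treatment, cohort, injected, contralateral, raters=(1, 2)):
    rows = []
    for hemi, vals in (("injected", injected), ("contralateral", contralateral)):
        for rater in raters:
            for section, c in enumerate(np.atleast_1d(vals[rater - 1]), start=1):
                rows.append(
                    dict(animal=animal, treatment=treatment, cohort=cohort,
                         hemisphere=hemi, rater=rater, section=section, count=float(c))
                )
    return rows


class TestAsymmetryIndex:
    def test_symmetry_gives_unit_ai(self):
        df = pd.DataFrame(count_rows("a1", "control", "t1", ([80], [80]), ([80], [80])))
        rec = hist.asymmetry_index(df)
        assert rec.ai == 1.0
        assert rec.log_ai == 0.0
        assert rec.preservation_pct == 100.0

    def test_half_depletion_arithmetic(self):
        df = pd.DataFrame(count_rows("a1", "lesion", "t1", ([50], [50]), ([100], [100])))
        rec = hist.asymmetry_index(df)
        assert rec.ai == pytest.approx(0.5)
        assert rec.log_ai == pytest.approx(np.log(0.5))
        assert rec.preservation_pct == pytest.approx(50.0)

    def test_rater_averaging_order(self):
        # raters read injected as 40 and 60: the rater means average to 50
        df = pd.DataFrame(count_rows("a1", "lesion", "t1", ([40], [60]), ([100], [100])))
        rec = hist.asymmetry_index(df)
        assert rec.ai == pytest.approx(0.5)

    def test_sections_averaged_within_rater_first(self):
        # rater 1 read 3 sections, rater 2 read 1: each rater still weighs 1/2
        df = pd.DataFrame(
            count_rows("a1", "lesion", "t1", ([30, 40, 50], [80]), ([100], [100]))
        )
        rec = hist.asymmetry_index(df)
        assert rec.injected == pytest.approx((40 + 80) / 2)

    def test_zero_contralateral_raises(self):
        df = pd.DataFrame(count_rows("a1", "lesion", "t1", ([50], [50]), ([0], [0])))
        with pytest.raises(ZeroDivisionError):
            hist.asymmetry_index(df)


class TestLogAIModel:
    def test_all_symmetric_gives_zero_effects(self):
        counts = simulate_th_counts(
            true_ai=1.0, rater_sd=0.0, section_sd=0.0, ai_noise_sd=0.0, seed=1
        )
        ai = hist.asymmetry_table(counts)
        model, anova = hist.fit_logai_model(ai)
        assert np.allclose(model.params, 0.0, atol=1e-10)

    def test_injected_treatment_shift_recovered(self):
        shift = -0.65
        cells = {(t, c): 6 for t in ("control", "lesion") for c in ("t1", "t2", "t3")}
        counts = simulate_th_counts(
            cells,
            {(t, c): (1.0 if t == "control" else float(np.exp(shift)))
             for t in ("control", "lesion") for c in ("t1", "t2", "t3")},
            rater_sd=2.0, section_sd=2.0, ai_noise_sd=0.05, seed=2,
        )
        ai = hist.asymmetry_table(counts)
        model, anova = hist.fit_logai_model(ai)
        assert anova.loc["C(treatment)", "PR(>F)"] < 0.001
        emm = hist.emm_contrasts(model, ai)
        # control minus lesion log(AI) difference recovers the programmed shift
        assert emm["estimate"].mean() == pytest.approx(-shift, abs=0.12)

    def test_empty_cell_rejected(self):
        counts = simulate_th_counts(seed=3)
        ai = hist.asymmetry_table(counts)
        ai = ai[~((ai["treatment"] == "lesion") & (ai["cohort"] == "t2"))]
        with pytest.raises(ValueError, match="rank"):
            hist.fit_logai_model(ai)

    def test_interaction_type_i_error_rate(self):
        # no time structure injected: interaction F significant in ~5% of nulls
        hits = 0
        n_sim = 60
        for i in range(n_sim):
            counts = simulate_th_counts(
                true_ai={(t, c): (1.0 if t == "control" else 0.5)
                         for t in ("control", "lesion") for c in ("t1", "t2", "t3")},
                rater_sd=3.0, section_sd=3.0, ai_noise_sd=0.10, seed=1000 + i,
            )
            ai = hist.asymmetry_table(counts)
            _, anova = hist.fit_logai_model(ai)
            hits += anova.loc["C(treatment):C(cohort)", "PR(>F)"] < 0.05
        # binomial(60, 0.05): reject only far outside the plausible range
        assert hits <= 9


class TestSensitivity:
    def test_preservation_model_is_rescaled_ai_model(self):
        counts = simulate_th_counts(rater_sd=2.0, seed=4)
        ai = hist.asymmetry_table(counts).assign(ai_raw=lambda d: d["ai"])
        fits = hist.sensitivity_models(ai)
        pres_params = fits["preservation_pct"][0].params
        import statsmodels.formula.api as smf

        ai_model = smf.ols("ai_raw ~ C(treatment) * C(cohort)", data=ai).fit()
        np.testing.assert_allclose(pres_params, 100.0 * ai_model.params, rtol=1e-8)

    def test_symmetric_data_zero_effects_on_each_scale(self):
        counts = simulate_th_counts(
            true_ai=1.0, rater_sd=0.0, section_sd=0.0, ai_noise_sd=0.0, seed=5
        )
        ai = hist.asymmetry_table(counts)
        for _, (model, _) in hist.sensitivity_models(ai).items():
            assert np.allclose(model.params[1:], 0.0, atol=1e-8)

    def test_raw_difference_recovers_injected_effect(self):
        cells = {(t, c): 6 for t in ("control", "lesion") for c in ("t1", "t2", "t3")}
        counts = simulate_th_counts(
            cells, {(t, c): (1.0 if t == "control" else 0.5)
                    for t in ("control", "lesion") for c in ("t1", "t2", "t3")},
            rater_sd=1.0, section_sd=1.0, contra_mean=80.0, contra_sd=2.0, seed=6,
        )
        ai = hist.asymmetry_table(counts)
        model, anova = hist.sensitivity_models(ai)["raw_difference"]
        assert anova.loc["C(treatment)", "PR(>F)"] < 0.001


class TestHolm:
    def test_hand_computed_example(self):
        adj = hist.holm_adjust([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])

    def test_never_decreases_p(self, rng):
        p = rng.uniform(0, 1, 8)
        assert np.all(hist.holm_adjust(p) >= p)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(hist.holm_adjust([0.02]), [0.02])


class TestAgreement:
    def test_identical_raters_icc_one(self):
        counts = simulate_th_counts(rater_sd=0.0, seed=7)
        icc = hist.icc_agreement(hist.rater_table(counts)).set_index("type")
        assert icc.loc["ICC2", "icc"] == pytest.approx(1.0, abs=1e-9)

    def test_average_measure_at_least_single(self):
        counts = simulate_th_counts(rater_sd=6.0, seed=8)
        icc = hist.icc_agreement(hist.rater_table(counts)).set_index("type")
        assert icc.loc["ICC2k", "icc"] >= icc.loc["ICC2", "icc"]

    def test_icc_matches_anova_mean_squares(self):
        # oracle: two-way absolute-agreement single-measure ICC from the
        # classic mean-squares decomposition
        counts = simulate_th_counts(rater_sd=5.0, seed=9)
        table = hist.rater_table(counts)
        x = table[["rater1", "rater2"]].to_numpy(float)
        n, k = x.shape
        grand = x.mean()
        ms_rows = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
        ms_cols = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
        ss_err = np.sum((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2)
        ms_err = ss_err / ((n - 1) * (k - 1))
        icc2 = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )
        got = hist.icc_agreement(table).set_index("type").loc["ICC2", "icc"]
        assert got == pytest.approx(icc2, rel=1e-6)

    def test_heavy_noise_drives_icc_down(self):
        counts = simulate_th_counts(
            rater_sd=200.0, contra_sd=1.0, section_sd=0.0, seed=10
        )
        icc = hist.icc_agreement(hist.rater_table(counts)).set_index("type")
        assert icc.loc["ICC2", "icc"] < 0.3

    def test_degenerate_table_flagged(self):
        table = pd.DataFrame(
            {"animal": list("abc"), "hemisphere": ["injected"] * 3,
             "rater1": [50.0, 50.0, 50.0], "rater2": [50.0, 50.0, 50.0]}
        )
        icc = hist.icc_agreement(table)
        assert icc["degenerate"].all()


class TestBlandAltman:
    def test_identical_raters(self):
        table = pd.DataFrame({"rater1": [10.0, 20, 30], "rater2": [10.0, 20, 30]})
        ba = hist.bland_altman(table, by_hemisphere=False)
        assert ba.loc[0, "mean_diff"] == 0.0
        assert ba.loc[0, "loa_low"] == ba.loc[0, "loa_high"] == 0.0

    def test_constant_offset(self):
        table = pd.DataFrame({"rater1": [15.0, 25, 35], "rater2": [10.0, 20, 30]})
        ba = hist.bland_altman(table, by_hemisphere=False)
        assert ba.loc[0, "mean_diff"] == pytest.approx(5.0)
        assert ba.loc[0, "sd_diff"] == pytest.approx(0.0)

    def test_limits_match_simulated_noise(self, rng):
        sigma = 4.0
        base = rng.uniform(50, 120, 3000)
        table = pd.DataFrame(
            {"rater1": base + rng.normal(0, sigma / np.sqrt(2), 3000),
             "rater2": base + rng.normal(0, sigma / np.sqrt(2), 3000)}
        )
        ba = hist.bland_altman(table, by_hemisphere=False)
        assert ba.loc[0, "loa_high"] == pytest.approx(1.96 * sigma, rel=0.08)
        assert ba.loc[0, "loa_low"] == pytest.approx(-1.96 * sigma, rel=0.08)

    def test_hemisphere_stratification(self):
        counts = simulate_th_counts(rater_sd=3.0, seed=11)
        ba = hist.bland_altman(hist.rater_table(counts))
        assert set(ba["stratum"]) == {"all", "injected", "contralateral"}
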