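"""Hemispheric TH asymmetry statistics.

The lesion readout is a within-animal asymmetry index AI = I / C, the
ratio of TH-positive soma counts in the injected (I) and contralateral
(C) hemispheres: 1 means symmetry, values below 1 mean ipsilateral
depletion.  Section-level counts are first averaged within animal and
hemisphere (keeping the animal as the unit of analysis), then across
the two raters.  Inference uses a linear model of log(AI) on treatment,
cohort time (unordered 3-level factor) and their interaction, with
estimated-marginal-mean control-vs-lesion contrasts per time point and
Holm correction.  Sensitivity analyses rerun the model on the raw
interhemispheric difference I - C and on preservation percent AI x 100.
Inter-rater agreement is summarized with two-way random-effects
absolute-agreement ICCs (single and average measure) and Bland-Altman
limits.  Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AsymmetryRecord",
    "asymmetry_index",
    "asymmetry_table",
    "fit_logai_model",
    "emm_contrasts",
    "sensitivity_models",
    "rater_table",
    "icc_agreement",
    "bland_altman",
    "holm_adjust",
]

COUNT_COLUMNS = ["animal", "treatment", "cohort", "hemisphere", "rater", "section", "count"]


@dataclass(frozen=True)
class AsymmetryRecord:
    """Per-animal hemispheric counts and derived asymmetry measures."""

    animal: str
    treatment: str
    cohort: str
    injected: float  # section- then rater-averaged count, injected hemisphere
    contralateral: float

    @property
    def ai(self) -> float:
        return self.injected / self.contralateral

    @property
    def log_ai(self) -> float:
        return float(np.log(self.ai))

    @property
    def preservation_pct(self) -> float:
        return 100.0 * self.ai


def _check_counts(counts: pd.DataFrame) -> None:
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")


def asymmetry_index(counts: pd.DataFrame) -> AsymmetryRecord:
    """Asymmetry record for a single animal's long-format count rows.

    Averaging order: sections within rater and hemisphere first, then
    raters — so an animal with unequal section counts per rater is still
    weighted per rater, not per section.
    """
    _check_counts(counts)
    if counts["animal"].nunique() != 1:
        raise ValueError("asymmetry_index expects rows for exactly one animal")
    hemis = set(counts["hemisphere"])
    if hemis != {"injected", "contralateral"}:
        raise ValueError(f"need both hemispheres, got {sorted(hemis)}")
    per_rater = counts.groupby(["hemisphere", "rater"])["count"].mean()
    per_hemi = per_rater.groupby("hemisphere").mean()
    if per_hemi["contralateral"] <= 0:
        raise ZeroDivisionError("contralateral count is zero; AI undefined")
    if per_hemi["injected"] <= 0:
        raise ZeroDivisionError("injected count is zero; log(AI) undefined")
    return AsymmetryRecord(
        animal=str(counts["animal"].iloc[0]),
        treatment=str(counts["treatment"].iloc[0]),
        cohort=str(counts["cohort"].iloc[0]),
        injected=float(per_hemi["injected"]),
        contralateral=float(per_hemi["contralateral"]),
    )


def asymmetry_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-animal AI table from a long-format count table."""
    _check_counts(counts)
    records = [asymmetry_index(grp) for _, grp in counts.groupby("animal", sort=True)]
    return pd.DataFrame(
        [
            {
                "animal": r.animal,
                "treatment": r.treatment,
                "cohort": r.cohort,
                "injected": r.injected,
                "contralateral": r.contralateral,
                "ai": r.ai,
                "log_ai": r.log_ai,
                "preservation_pct": r.preservation_pct,
            }
            for r in records
        ]
    )


def _fit_lm(table: pd.DataFrame, outcome: str):
    cells = table.groupby(["treatment", "cohort"]).size()
    expected = table["treatment"].nunique() * table["cohort"].nunique()
    if len(cells) < expected or (cells < 1).any():
        raise ValueError("empty treatment-by-time cells: model is rank deficient")
    model = smf.ols(f"{outcome} ~ C(treatment) * C(cohort)", data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    return model, anova


def fit_logai_model(table: pd.DataFrame):
    """OLS of log(AI) on treatment x cohort time; returns (fit, F-table).

    Sex is deliberately not a term: the histology cells are small and
    unbalanced across sex, so the primary model uses treatment and time
    only.
    """
    if table["treatment"].nunique() < 2:
        raise ValueError("need both treatment levels")
    return _fit_lm(table, "log_ai")


def holm_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def emm_contrasts(model, table: pd.DataFrame) -> pd.DataFrame:
    """Control-vs-lesion estimated-marginal-mean contrast per time point.

    With treatment and cohort as the only factors, the EMM of a cell is its
    model-predicted mean, so each contrast is a linear combination of the
    OLS coefficients; p-values come from the model's t distribution and are
    Holm-adjusted across the time points.
    """
    cohorts = sorted(table["cohort"].unique())
    treatments = sorted(table["treatment"].unique())
    if len(treatments) != 2:
        raise ValueError("contrasts require exactly two treatment levels")
    ref, other = treatments[0], treatments[1]
    rows = []
    import patsy

    for cohort in cohorts:
        grid = pd.DataFrame({"treatment": [ref, other], "cohort": [cohort, cohort]})
        X = patsy.dmatrix(model.model.data.design_info, grid, return_type="dataframe")
        L = X.iloc[0].to_numpy() - X.iloc[1].to_numpy()  # ref minus other
        tt = model.t_test(L)
        rows.append(
            {
                "cohort": cohort,
                "contrast": f"{ref} - {other}",
                "estimate": float(np.squeeze(tt.effect)),
                "se": float(np.squeeze(tt.sd)),
                "t": float(np.squeeze(tt.tvalue)),
                "p_raw": float(np.squeeze(tt.pvalue)),
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def sensitivity_models(table: pd.DataFrame) -> dict[str, tuple]:
    """Refit the primary model on I - C and on preservation percent."""
    tab = table.copy()
    tab["raw_difference"] = tab["injected"] - tab["contralateral"]
    tab["preservation_pct"] = 100.0 * tab["ai"]
    return {
        "raw_difference": _fit_lm(tab, "raw_difference"),
        "preservation_pct": _fit_lm(tab, "preservation_pct"),
    }


def rater_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Animal-by-hemisphere rater means (sections averaged first)."""
    _check_counts(counts)
    wide = (
        counts.groupby(["animal", "hemisphere", "rater"])["count"]
        .mean()
        .unstack("rater")
        .reset_index()
    )
    raters = [c for c in wide.columns if c not in ("animal", "hemisphere")]
    if len(raters) != 2:
        raise ValueError(f"expected exactly 2 raters, found {raters}")
    wide = wide.rename(columns={raters[0]: "rater1", raters[1]: "rater2"})
    return wide


def icc_agreement(table: pd.DataFrame) -> pd.DataFrame:
    """Two-way random-effects absolute-agreement ICCs with 95% CIs.

    ``table`` holds one row per target (animal-by-hemisphere) with columns
    ``rater1`` and ``rater2``.  Returns the single-measure (ICC2) and
    average-measure (ICC2k) rows.  Degenerate tables (no between-target
    variance) are flagged with NaN estimates rather than raising.
    """
    import pingouin as pg

    if len(table) < 3:
        raise ValueError("ICC needs at least 3 targets")
    target = (
        table["animal"].astype(str) + ":" + table["hemisphere"].astype(str)
        if {"animal", "hemisphere"} <= set(table.columns)
        else pd.Series(np.arange(len(table)).astype(str), index=table.index)
    )
    long = pd.DataFrame(
        {
            "target": np.tile(target.to_numpy(), 2),
            "rater": np.repeat(["rater1", "rater2"], len(table)),
            "rating": np.concatenate(
                [table["rater1"].to_numpy(float), table["rater2"].to_numpy(float)]
            ),
        }
    )
    if np.isclose(long.groupby("target")["rating"].mean().var(ddof=1), 0.0):
        return pd.DataFrame(
            {
                "type": ["ICC2", "ICC2k"],
                "icc": [np.nan, np.nan],
                "ci_low": [np.nan, np.nan],
                "ci_high": [np.nan, np.nan],
                "degenerate": [True, True],
            }
        )
    import warnings

    with warnings.catch_warnings():
        # perfect agreement makes some of pingouin's F ratios 0/0; the ICC
        # estimates themselves are still well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="rating"
        ).set_index("Type")
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    rows = []
    for typ, label in (("ICC(A,1)", "ICC2"), ("ICC(A,k)", "ICC2k")):
        r = res.loc[typ]
        rows.append(
            {
                "type": label,
                "icc": float(r["ICC"]),
                "ci_low": float(r[ci_col][0]),
                "ci_high": float(r[ci_col][1]),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)


def bland_altman(table: pd.DataFrame, by_hemisphere: bool = True) -> pd.DataFrame:
    """Bland-Altman summary of inter-rater differences.

    Reports the mean difference (rater1 - rater2), its SD and the 95%
    limits of agreement (mean +/- 1.96 SD), overall and optionally per
    hemisphere (the contralateral side typically shows more dispersion,
    having more somata to count).
    """
    diffs = table["rater1"].to_numpy(float) - table["rater2"].to_numpy(float)

    def _summary(d: np.ndarray, label: str) -> dict:
        mean = float(np.mean(d))
        sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
        return {
            "stratum": label,
            "n": int(d.size),
            "mean_diff": mean,
            "sd_diff": sd,
            "loa_low": mean - 1.96 * sd,
            "loa_high": mean + 1.96 * sd,
        }

    rows = [_summary(diffs, "all")]
    if by_hemisphere and "hemisphere" in table.columns:
        for hemi, grp in table.groupby("hemisphere"):
            d = grp["rater1"].to_numpy(float) - grp["rater2"].to_numpy(float)
            rows.append(_summary(d, str(hemi)))
    return pd.DataFrame(rows)
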