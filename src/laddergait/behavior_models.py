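"""Multi-level Bayesian regressions for ladder-crossing performance.

All three behavioral outcomes share one linear predictor: for subject
``s`` in week ``w``

    mu[s, w] = gamma[s] + X[s] * beta_x + T[s] * X[s] * beta_tx
               + W[w] . beta_w + T[s] * (W[w] . beta_t)

with a subject random intercept gamma[s] ~ Normal(eta, psi), sex coded
female = -0.5 / male = +0.5, treatment coded control = 0 / lesion = 1,
and six week dummies (all zero at the week-0 baseline) — one random
parameter per subject plus 14 fixed effects.  Families:

* error counts  ~ Poisson(exp(mu))                   (log link)
* velocities    ~ lognormal(mu, sigma_v)             (log scale, cm/s)
* left errors   ~ Binomial(total, logistic(mu))      (logit link)

Priors are weakly informative and configurable: Normal(0, 5) on eta,
Normal(0, 2) on each beta, half-Normal(1) on psi and sigma_v.  Sampling
uses NUTS (``laddergait.mcmc``) on a non-centered parameterization
(gamma = eta + psi * z); R-hat and effective sample size per parameter
come from arviz, and a fit with max R-hat > 1.01 or divergent
transitions is flagged rather than silently accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .mcmc import nuts_sample
from .pose_io import COHORT_LAST_WEEK

__all__ = [
    "Design",
    "Priors",
    "SamplerConfig",
    "PosteriorFit",
    "ConvergenceWarning",
    "build_design",
    "fit_error_model",
    "fit_velocity_model",
    "fit_laterality_model",
    "condition_summaries",
    "posthoc_trends",
    "summary_table",
]

N_WEEKS = 6
N_FIXED = 14  # beta_x, beta_tx, 6 week effects, 6 week-by-treatment effects
FIXED_NAMES = (
    ["beta_x", "beta_tx"]
    + [f"beta_w[{i}]" for i in range(1, 7)]
    + [f"beta_t[{i}]" for i in range(1, 7)]
)

SEX_CODE = {"female": -0.5, "male": 0.5}
TREAT_CODE = {"control": 0.0, "lesion": 1.0}


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class Design:
    """Encoded design: one row per subject-week observation."""

    table: pd.DataFrame
    subjects: list[str]
    subj_idx: np.ndarray  # (n_rows,) int
    fixed: np.ndarray  # (n_rows, 14)
    weeks: np.ndarray  # (n_rows,) int 0..6
    sex_code: np.ndarray  # per subject
    treat_code: np.ndarray  # per subject
    sex_label: list[str]
    treat_label: list[str]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_rows(self) -> int:
        return self.fixed.shape[0]


def _fixed_row(sex_code: float, treat_code: float, week: int) -> np.ndarray:
    row = np.zeros(N_FIXED)
    row[0] = sex_code
    row[1] = treat_code * sex_code
    if week > 0:
        row[1 + week] = 1.0
        row[7 + week] = treat_code
    return row


def build_design(table: pd.DataFrame, validate_attrition: bool = True) -> Design:
    """Encode an outcome table (subject, sex, treatment, week[, cohort]).

    Weeks must lie in 0..6; week 0 is the pre-treatment baseline with all
    week dummies zero.  When a cohort column is present the attrition
    pattern is validated: no subject may contribute weeks beyond its
    cohort's terminal endpoint (t1 -> 2, t2 -> 4, t3 -> 6).
    """
    required = {"subject", "sex", "treatment", "week"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"outcome table missing columns {sorted(missing)}")
    for col, allowed in (("sex", SEX_CODE), ("treatment", TREAT_CODE)):
        bad = set(table[col].unique()) - set(allowed)
        if bad:
            raise ValueError(f"unknown {col} level(s) {sorted(bad)}")
    weeks = table["week"].to_numpy()
    if not np.all((weeks >= 0) & (weeks <= N_WEEKS)):
        raise ValueError("week out of range 0..6")
    if validate_attrition and "cohort" in table.columns:
        for cohort, grp in table.groupby("cohort"):
            last = COHORT_LAST_WEEK.get(str(cohort))
            if last is None:
                raise ValueError(f"unknown cohort {cohort!r}")
            if grp["week"].max() > last:
                raise ValueError(
                    f"cohort {cohort} has observations after its week-{last} endpoint"
                )

    subjects = list(dict.fromkeys(table["subject"]))
    s_pos = {s: i for i, s in enumerate(subjects)}
    subj_idx = table["subject"].map(s_pos).to_numpy(dtype=int)

    sex_code = np.empty(len(subjects))
    treat_code = np.empty(len(subjects))
    sex_label = [""] * len(subjects)
    treat_label = [""] * len(subjects)
    for s, grp in table.groupby("subject", sort=False):
        if grp["sex"].nunique() > 1 or grp["treatment"].nunique() > 1:
            raise ValueError(f"subject {s} changes sex/treatment across rows")
        i = s_pos[s]
        sex_label[i] = str(grp["sex"].iloc[0])
        treat_label[i] = str(grp["treatment"].iloc[0])
        sex_code[i] = SEX_CODE[sex_label[i]]
        treat_code[i] = TREAT_CODE[treat_label[i]]

    fixed = np.stack(
        [
            _fixed_row(sex_code[i], treat_code[i], int(w))
            for i, w in zip(subj_idx, weeks)
        ]
    )
    return Design(
        table=table.reset_index(drop=True),
        subjects=subjects,
        subj_idx=subj_idx,
        fixed=fixed,
        weeks=weeks.astype(int),
        sex_code=sex_code,
        treat_code=treat_code,
        sex_label=sex_label,
        treat_label=treat_label,
    )


@dataclass
class Priors:
    eta_sd: float = 5.0
    beta_sd: float = 2.0
    psi_scale: float = 1.0  # half-Normal scale on the intercept SD
    sigma_scale: float = 1.0  # half-Normal scale on the lognormal obs SD


@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.9
    max_treedepth: int = 10


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one behavioral model."""

    family: str
    design: Design
    eta: np.ndarray  # (chains, draws)
    psi: np.ndarray
    beta: np.ndarray  # (chains, draws, 14)
    gamma: np.ndarray  # (chains, draws, n_subjects)
    sigma: np.ndarray | None  # velocity family only
    rhat: dict[str, float]
    ess: dict[str, float]
    n_divergent: int
    config: SamplerConfig
    priors: Priors
    converged: bool = True

    def beta_named(self, name: str) -> np.ndarray:
        return self.beta[..., FIXED_NAMES.index(name)]

    def flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


def _make_logp_grad(family, design, priors, y, totals, log_y):
    subj = design.subj_idx
    F = design.fixed
    n_subj = design.n_subjects
    has_sigma = family == "velocity"
    # layout: [eta, log_psi, (log_sigma), beta(14), z(n_subj)]
    b0 = 3 if has_sigma else 2

    def logp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = theta[0]
        log_psi = theta[1]
        psi = np.exp(log_psi)
        beta = theta[b0 : b0 + N_FIXED]
        z = theta[b0 + N_FIXED :]
        gamma = eta + psi * z
        mu = gamma[subj] + F @ beta

        grad = np.empty_like(theta)
        if family == "count":
            lam = np.exp(mu)
            logp = float(np.dot(y, mu) - lam.sum())
            g_mu = y - lam
        elif family == "velocity":
            sigma = np.exp(theta[2])
            resid = log_y - mu
            logp = float(-log_y.size * theta[2] - 0.5 * np.dot(resid, resid) / sigma**2)
            g_mu = resid / sigma**2
            grad[2] = (
                -log_y.size
                + np.dot(resid, resid) / sigma**2
                - sigma**2 / priors.sigma_scale**2
                + 1.0
            )
            logp += -0.5 * sigma**2 / priors.sigma_scale**2 + theta[2]
        else:  # laterality
            logp = float(np.dot(y, mu) - np.dot(totals, np.logaddexp(0.0, mu)))
            g_mu = y - totals * expit(mu)

        # priors: eta ~ N(0, eta_sd); beta ~ N(0, beta_sd); psi ~ halfN(psi_scale)
        # (+ log Jacobian); z ~ N(0, 1)
        logp += (
            -0.5 * eta**2 / priors.eta_sd**2
            - 0.5 * np.dot(beta, beta) / priors.beta_sd**2
            - 0.5 * psi**2 / priors.psi_scale**2
            + log_psi
            - 0.5 * np.dot(z, z)
        )
        g_subj = np.bincount(subj, weights=g_mu, minlength=n_subj)
        grad[0] = g_subj.sum() - eta / priors.eta_sd**2
        grad[1] = psi * np.dot(g_subj, z) - psi**2 / priors.psi_scale**2 + 1.0
        grad[b0 : b0 + N_FIXED] = F.T @ g_mu - beta / priors.beta_sd**2
        grad[b0 + N_FIXED :] = psi * g_subj - z
        return logp, grad

    return logp_grad, b0, has_sigma


def _initial_point(family, design, priors, y, totals, log_y, b0, has_sigma, rng):
    n = 2 + (1 if has_sigma else 0) + N_FIXED + design.n_subjects
    theta = np.zeros(n)
    if family == "count":
        theta[0] = np.log(np.mean(y) + 0.1)
    elif family == "velocity":
        theta[0] = float(np.mean(log_y))
        theta[2] = np.log(max(float(np.std(log_y)), 0.05))
    else:
        p = (y.sum() + 1.0) / (totals.sum() + 2.0)
        theta[0] = np.log(p / (1 - p))
    theta[1] = np.log(0.3)
    theta += 0.1 * rng.standard_normal(n)
    return theta


def _fit(family, design, y, priors, config, totals=None) -> PosteriorFit:
    log_y = np.log(y) if family == "velocity" else None
    logp_grad, b0, has_sigma = _make_logp_grad(family, design, priors, y, totals, log_y)

    chains_draws = []
    n_div = 0
    root = np.random.SeedSequence(config.seed)
    for chain, child in enumerate(root.spawn(config.chains)):
        chain_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(chain_seed)
        theta0 = _initial_point(
            family, design, priors, y, totals, log_y, b0, has_sigma, rng
        )
        res = nuts_sample(
            logp_grad,
            theta0,
            n_warmup=config.warmup,
            n_draws=config.draws,
            seed=chain_seed,
            max_treedepth=config.max_treedepth,
            target_accept=config.target_accept,
        )
        chains_draws.append(res.draws)
        n_div += res.n_divergent

    draws = np.stack(chains_draws)  # (chains, draws, dim)
    eta = draws[..., 0]
    psi = np.exp(draws[..., 1])
    sigma = np.exp(draws[..., 2]) if has_sigma else None
    beta = draws[..., b0 : b0 + N_FIXED]
    z = draws[..., b0 + N_FIXED :]
    gamma = eta[..., None] + psi[..., None] * z

    rhat, ess = _diagnostics(eta, psi, sigma, beta, gamma)
    fit = PosteriorFit(
        family=family,
        design=design,
        eta=eta,
        psi=psi,
        beta=beta,
        gamma=gamma,
        sigma=sigma,
        rhat=rhat,
        ess=ess,
        n_divergent=n_div,
        config=config,
        priors=priors,
    )
    if fit.max_rhat > 1.01 or n_div > 0.01 * config.chains * config.draws:
        fit.converged = False
        warnings.warn(
            f"{family} fit flagged: max R-hat {fit.max_rhat:.3f}, "
            f"{n_div} divergent transitions",
            ConvergenceWarning,
            stacklevel=2,
        )
    return fit


def _diagnostics(eta, psi, sigma, beta, gamma) -> tuple[dict, dict]:
    import arviz as az

    data = {"eta": eta, "psi": psi, "beta": beta, "gamma": gamma}
    if sigma is not None:
        data["sigma"] = sigma
    idata = az.from_dict(posterior=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for name in data:
        r = np.asarray(rhat_ds[name]).ravel()
        e = np.asarray(ess_ds[name]).ravel()
        if name == "beta":
            for i, pname in enumerate(FIXED_NAMES):
                rhat[pname], ess[pname] = float(r[i]), float(e[i])
        elif name == "gamma":
            for i in range(r.size):
                rhat[f"gamma[{i}]"], ess[f"gamma[{i}]"] = float(r[i]), float(e[i])
        else:
            rhat[name], ess[name] = float(r[0]), float(e[0])
    return rhat, ess


def fit_error_model(
    design: Design,
    counts: np.ndarray | pd.Series,
    priors: Priors | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorFit:
    """Poisson log-link fit of total footfall errors."""
    y = np.asarray(counts, dtype=float)
    if y.size != design.n_rows:
        raise ValueError("counts length does not match design")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    return _fit("count", design, y, priors or Priors(), config or SamplerConfig())


def fit_velocity_model(
    design: Design,
    velocities: np.ndarray | pd.Series,
    priors: Priors | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorFit:
    """Lognormal fit of crossing velocities (parameters on the log cm/s scale)."""
    v = np.asarray(velocities, dtype=float)
    if v.size != design.n_rows:
        raise ValueError("velocities length does not match design")
    if np.any(v <= 0):
        raise ValueError("velocities must be positive")
    return _fit("velocity", design, v, priors or Priors(), config or SamplerConfig())


def fit_laterality_model(
    design: Design,
    left_counts: np.ndarray | pd.Series,
    total_counts: np.ndarray | pd.Series,
    priors: Priors | None = None,
    config: SamplerConfig | None = None,
) -> tuple[PosteriorFit, Design]:
    """Binomial logit-link fit of the left-paw share of footfall errors.

    Rows with zero total errors carry no information about the split and are
    excluded (the reduced design is returned alongside the fit).
    """
    left = np.asarray(left_counts, dtype=float)
    total = np.asarray(total_counts, dtype=float)
    if left.size != design.n_rows or total.size != design.n_rows:
        raise ValueError("count vectors do not match design")
    if np.any(left > total):
        raise ValueError("left counts exceed totals")
    keep = total > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} rows with zero total errors",
            stacklevel=2,
        )
        design = build_design(design.table.loc[keep], validate_attrition=False)
        left, total = left[keep], total[keep]
    fit = _fit(
        "laterality",
        design,
        left,
        priors or Priors(),
        config or SamplerConfig(),
        totals=total,
    )
    return fit, design


def _link(family: str):
    if family in ("count", "velocity"):
        return np.exp
    return expit


def condition_draws(
    fit: PosteriorFit, weeks: list[int] | None = None
) -> dict[tuple[str, str], np.ndarray]:
    """Per-draw response-scale value for an average subject, per condition
    and sex.

    The subject intercept is set to the population mean (gamma = eta), mu is
    evaluated for each condition (baseline: T = 0, all week dummies zero;
    control: T = 0; experimental: T = 1), mapped through the inverse link
    and averaged across the requested weeks on the response scale.
    """
    weeks = list(weeks) if weeks is not None else list(range(1, 7))
    g = _link(fit.family)
    eta = fit.flat(fit.eta)
    beta = fit.flat(fit.beta)
    out: dict[tuple[str, str], np.ndarray] = {}
    for condition in ("baseline", "control", "experimental"):
        t_code = 1.0 if condition == "experimental" else 0.0
        use_weeks = [0] if condition == "baseline" else weeks
        for sex, x_code in SEX_CODE.items():
            vals = np.zeros(eta.size)
            for w in use_weeks:
                fx = _fixed_row(x_code, t_code, w)
                vals += g(eta + beta @ fx)
            vals /= len(use_weeks)
            out[(condition, sex)] = vals
    return out


def condition_summaries(
    fit: PosteriorFit,
    weeks: list[int] | None = None,
    ci_levels: tuple[float, float] = (0.80, 0.95),
) -> pd.DataFrame:
    """Posterior summaries of :func:`condition_draws` with nested intervals."""
    rows = []
    for (condition, sex), vals in condition_draws(fit, weeks).items():
        row = {
            "condition": condition,
            "sex": sex,
            "mean": float(vals.mean()),
        }
        for level in ci_levels:
            lo, hi = np.quantile(vals, [(1 - level) / 2, (1 + level) / 2])
            row[f"ci{int(level * 100)}_low"] = float(lo)
            row[f"ci{int(level * 100)}_high"] = float(hi)
        rows.append(row)
    return pd.DataFrame(rows)


def posthoc_trends(fit: PosteriorFit, ci_level: float = 0.95) -> pd.DataFrame:
    """Descriptive per-group linear trends over the post-treatment weeks.

    Per posterior draw, each subject's expected response-scale value is
    computed for every post-baseline week it was observed (full model,
    including the subject's own intercept); an ordinary least-squares slope
    of value against week is then fit pooling subjects within each
    treatment-by-sex group, and the slopes are summarized across draws.
    """
    design = fit.design
    g = _link(fit.family)
    gamma = fit.flat(fit.gamma)  # (ndraw, n_subj)
    beta = fit.flat(fit.beta)
    post = design.weeks > 0
    rows = []
    for treatment in ("control", "lesion"):
        for sex in ("female", "male"):
            sel = post.copy()
            for i, r in enumerate(sel):
                if r:
                    s = design.subj_idx[i]
                    sel[i] = (
                        design.treat_label[s] == treatment
                        and design.sex_label[s] == sex
                    )
            if not sel.any():
                continue
            w = design.weeks[sel].astype(float)
            if np.unique(w).size < 2:
                raise ValueError(
                    f"group {treatment}/{sex} observed in a single week; trend undefined"
                )
            mu = gamma[:, design.subj_idx[sel]] + beta @ design.fixed[sel].T
            vals = g(mu)  # (ndraw, n_points)
            wc = w - w.mean()
            denom = float(np.dot(wc, wc))
            slopes = (vals @ wc) / denom
            lo, hi = np.quantile(slopes, [(1 - ci_level) / 2, (1 + ci_level) / 2])
            rows.append(
                {
                    "treatment": treatment,
                    "sex": sex,
                    "slope_mean": float(slopes.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "n_points": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def summary_table(fit: PosteriorFit, ci_level: float = 0.95) -> pd.DataFrame:
    """Population-parameter summary mirroring the published table layout."""
    lo_q, hi_q = (1 - ci_level) / 2, (1 + ci_level) / 2
    scale = {
        "count": "log(error rate)",
        "velocity": "log(velocity)",
        "laterality": "log-odds(left)",
    }[fit.family]
    entries = [("Pop. Intercept Mean", "eta", fit.flat(fit.eta)),
               ("Pop. Intercept SD", "psi", fit.flat(fit.psi))]
    if fit.sigma is not None:
        entries.append(("Obs. SD", "sigma_v", fit.flat(fit.sigma)))
    labels = {
        "beta_x": "Sex",
        "beta_tx": "Sex x Experiment",
        **{f"beta_w[{i}]": f"Week {i}" for i in range(1, 7)},
        **{f"beta_t[{i}]": f"Week {i} x Experiment" for i in range(1, 7)},
    }
    for name, label in labels.items():
        entries.append((label, name, fit.flat(fit.beta_named(name))))
    rows = []
    for label, param, draws in entries:
        lo, hi = np.quantile(draws, [lo_q, hi_q])
        rows.append(
            {
                "effect": label,
                "scale": scale,
                "parameter": param,
                "mean": float(draws.mean()),
                f"ci{int(ci_level * 100)}_low": float(lo),
                f"ci{int(ci_level * 100)}_high": float(hi),
                "rhat": fit.rhat.get(param, np.nan),
                "ess": fit.ess.get(param, np.nan),
            }
        )
    return pd.DataFrame(rows)
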