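"""Behavioural RT analysis: exclusions, mixed models, EMMs and Bayes factors.

Single-trial response times are screened (incorrect / no-response / <500 ms
fast guesses, then a per-subject 3-SD rule), thinned to each deviant and its
immediately preceding standard ("last standard in each chain"), and
modelled with linear mixed-effects models with a subject random intercept:

    RT ~ Emotion x Expectation + (1 | Subject)
    RT ~ Emotion x Expectation x TraitAnxiety + Experiment + (1 | Subject)

For the pooled anxiety model RTs are z-scored within experiment and trait
anxiety is mean-centred.  Estimated marginal means (EMMs) per condition,
chi-square model comparisons (ML refits), variance inflation factors and
JZS Bayes factors (Cauchy prior, default width 0.707) accompany the fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

__all__ = [
    "ModelFit",
    "apply_rt_filters",
    "select_last_standards",
    "zscore_rt_within_experiment",
    "fit_rt_lmm",
    "chisq_model_compare",
    "compute_vif",
    "jzs_paired_bf",
    "jzs_correlation_bf",
    "subject_expectation_effects",
    "anxiety_effect_correlation",
]


# ---------------------------------------------------------------------------
# Trial selection


def apply_rt_filters(
    trials: pd.DataFrame,
    fast_cutoff: float = 0.5,
    sd_cutoff: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove incorrect/no-response/fast-guess trials, then a per-subject
    SD rule on the remainder; every exclusion is logged with its reason.

    The SD rule uses each subject's overall mean/SD of the surviving RTs
    (not per condition).  Subjects with fewer than 2 surviving trials skip
    the SD rule (logged as a warning row with reason ``sd_rule_skipped``).
    """
    df = trials.copy()
    log_rows = []

    def _exclude(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask]:
            log_rows.append({"index": idx, "subject_id": df.at[idx, "subject_id"],
                             "reason": reason, "rt": df.at[idx, "rt"]})
        df.drop(index=df.index[mask], inplace=True)

    _exclude(df["accuracy"] == "no_response", "no_response")
    _exclude(df["accuracy"] == "incorrect", "incorrect")
    _exclude(df["rt"] < fast_cutoff, "fast_guess")

    for sid, grp in df.groupby("subject_id", sort=False):
        if len(grp) < 2:
            log_rows.append({"index": -1, "subject_id": sid,
                             "reason": "sd_rule_skipped", "rt": np.nan})
            continue
        mu, sd = grp["rt"].mean(), grp["rt"].std(ddof=1)
        if sd == 0:
            continue
        out = grp.index[np.abs(grp["rt"] - mu) > sd_cutoff * sd]
        for idx in out:
            log_rows.append({"index": idx, "subject_id": sid,
                             "reason": "sd_outlier", "rt": df.at[idx, "rt"]})
        df.drop(index=out, inplace=True)

    log = pd.DataFrame(log_rows, columns=["index", "subject_id", "reason", "rt"])
    return df.reset_index(drop=True), log


def select_last_standards(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep every unexpected trial plus, per deviant, the expected trial
    that immediately preceded it in the block (if it survived filtering).

    ``trials`` must be ordered within block; order is preserved.
    """
    keep = np.zeros(len(trials), dtype=bool)
    df = trials.reset_index(drop=True)
    for (_, _), grp in df.groupby(["subject_id", "block_index"], sort=False):
        pos = dict(zip(grp["trial_index_in_block"], grp.index))
        for idx, row in grp.iterrows():
            if row["expectation"] == "unexpected":
                keep[idx] = True
                prev = pos.get(row["trial_index_in_block"] - 1)
                if prev is not None and df.at[prev, "expectation"] == "expected":
                    keep[prev] = True
    return df[keep].reset_index(drop=True)


def zscore_rt_within_experiment(trials: pd.DataFrame,
                                column: str = "rt") -> pd.DataFrame:
    """Add ``rt_z``: the RT z-scored within each experiment."""
    df = trials.copy()
    z = df.groupby("experiment_id")[column].transform(
        lambda x: (x - x.mean()) / x.std(ddof=1)
    )
    df["rt_z"] = z
    return df


# ---------------------------------------------------------------------------
# Mixed models


@dataclass
class ModelFit:
    """A fitted mixed model: fixed-effect table, EMMs and bookkeeping.

    ``params`` columns: beta, se, t, df, p.  p-values use a normal
    approximation (df reported as inf), recorded in ``df_method``.
    """

    formula: str
    params: pd.DataFrame
    loglike: float
    emms: pd.DataFrame
    converged: bool
    method: str  # "reml" | "ml"
    coding: dict = field(default_factory=dict)
    df_method: str = "normal_approximation"
    n_obs: int = 0
    result: object = None  # underlying statsmodels result


def _condition_emms(result, design_info, data: pd.DataFrame,
                    extra_numeric: dict | None = None) -> pd.DataFrame:
    """EMMs for the 2x2 emotion x expectation cells.

    Categorical covariates other than emotion/expectation are averaged over
    their observed levels; numeric covariates are held at 0 (they are
    mean-centred upstream).
    """
    conds = [(e, x) for e in ("neutral", "fearful")
             for x in ("expected", "unexpected")]
    other_cats = [c for c in ("experiment_id", "cluster")
                  if c in data.columns and f"{c}" in design_info.describe()]
    rows = []
    cov = result.cov_params().iloc[: len(result.fe_params), : len(result.fe_params)]
    for emotion, expectation in conds:
        frame = {"emotion": [emotion], "expectation": [expectation]}
        grids = [frame]
        for c in other_cats:
            levels = sorted(data[c].unique())
            grids = [dict(g, **{c: [lv]}) for g in grids for lv in levels]
        xs = []
        for g in grids:
            new = pd.DataFrame(g)
            for col, val in (extra_numeric or {}).items():
                new[col] = val
            (X,) = build_design_matrices([design_info], new)
            xs.append(np.asarray(X)[0])
        x = np.mean(xs, axis=0)
        est = float(x @ result.fe_params)
        se = float(np.sqrt(x @ cov.values @ x))
        rows.append({
            "emotion": emotion, "expectation": expectation, "emm": est,
            "se": se, "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
        })
    return pd.DataFrame(rows)


def fit_lmm(
    data: pd.DataFrame,
    fixed_formula: str,
    response: str,
    groups: str = "subject_id",
    reml: bool = True,
    emm_numeric: dict | None = None,
) -> ModelFit:
    """Fit ``response ~ fixed_formula + (1 | groups)`` by (RE)ML."""
    formula = f"{response} ~ {fixed_formula}"
    model = smf.mixedlm(formula, data=data, groups=data[groups])
    res = model.fit(reml=reml)
    fe = res.fe_params
    se = res.bse_fe
    tvals = fe / se
    pvals = 2 * stats.norm.sf(np.abs(tvals))
    params = pd.DataFrame({
        "beta": fe, "se": se, "t": tvals,
        "df": np.inf, "p": pvals,
    })
    emms = _condition_emms(res, model.data.design_info, data,
                           extra_numeric=emm_numeric)
    return ModelFit(
        formula=formula,
        params=params,
        loglike=float(res.llf),
        emms=emms,
        converged=bool(res.converged),
        method="reml" if reml else "ml",
        n_obs=len(data),
        result=res,
    )


def fit_rt_lmm(
    data: pd.DataFrame,
    formula: str = "basic",
    reml: bool = True,
    emotion_ref: str = "fearful",
    expectation_ref: str = "expected",
) -> ModelFit:
    """Fit the RT mixed model (``basic`` 2x2 or pooled ``anxiety``).

    Treatment coding with configurable reference levels; the default
    (fearful, expected) reproduces the printed sign pattern in which the
    emotion coefficient is positive when neutral responses are slower.
    The anxiety model expects ``rt_z`` and a ``trait_anxiety`` column;
    anxiety is mean-centred across subjects before fitting.
    """
    emo = f"C(emotion, Treatment('{emotion_ref}'))"
    exp_ = f"C(expectation, Treatment('{expectation_ref}'))"
    coding = {"emotion_ref": emotion_ref, "expectation_ref": expectation_ref}
    if formula == "basic":
        fit = fit_lmm(data, f"{emo} * {exp_}", response="rt", reml=reml)
    elif formula == "anxiety":
        df = data.copy()
        subj_anx = df.groupby("subject_id")["trait_anxiety"].first()
        df["anxiety_c"] = df["trait_anxiety"] - subj_anx.mean()
        if "rt_z" not in df:
            df = zscore_rt_within_experiment(df)
        fixed = f"{emo} * {exp_} * anxiety_c + C(experiment_id)"
        fit = fit_lmm(df, fixed, response="rt_z", reml=reml,
                      emm_numeric={"anxiety_c": 0.0})
    else:
        raise ValueError("formula must be 'basic' or 'anxiety'")
    fit.coding = coding
    if not fit.converged:
        fit.params["p"] = np.nan
    return fit


def chisq_model_compare(fit_full: ModelFit, fit_null: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square between nested ML fits."""
    if fit_full.method != "ml" or fit_null.method != "ml":
        raise ValueError("model comparison requires ML (not REML) fits")
    if fit_full.n_obs != fit_null.n_obs:
        raise ValueError("models must be fit to the same data")
    chi2 = max(0.0, 2.0 * (fit_full.loglike - fit_null.loglike))
    df = len(fit_full.params) - len(fit_null.params)
    if df < 0:
        raise ValueError("fit_full must nest fit_null")
    p = 1.0 if df == 0 and chi2 <= 1e-12 else float(stats.chi2.sf(chi2, max(df, 1)))
    if df == 0 and chi2 > 1e-12:
        raise ValueError("models have equal dimension but different likelihoods")
    return float(chi2), int(df), p


def compute_vif(design: pd.DataFrame | np.ndarray,
                threshold: float = 4.0) -> pd.DataFrame:
    """Variance inflation factors for a fixed-effect design matrix.

    VIF_j = 1/(1 - R^2_j) from regressing predictor j on the others (with
    an intercept).  Perfect collinearity raises an error naming the column.
    """
    X = pd.DataFrame(design)
    cols = list(X.columns)
    rows = []
    for j, col in enumerate(cols):
        others = X.drop(columns=[col])
        exog = sm.add_constant(others.to_numpy(dtype=float)) if len(cols) > 1 \
            else np.ones((len(X), 1))
        r2 = sm.OLS(X[col].to_numpy(dtype=float), exog).fit().rsquared
        if r2 > 1 - 1e-10:
            raise ValueError(f"perfect collinearity involving predictor {col!r}")
        vif = 1.0 / (1.0 - r2)
        rows.append({"predictor": col, "vif": vif, "flagged": vif >= threshold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayes factors (JZS; Cauchy prior width 0.707 by default)


def jzs_paired_bf(x, y, cauchy_scale: float = 0.707) -> float:
    """JZS Bayes factor (BF10) for a paired difference.

    Marginalises the Cauchy(0, scale) prior on standardised effect size via
    its normal/inverse-gamma mixture representation, giving a 1-D integral
    over the prior variance g evaluated to relative tolerance 1e-6.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    t = d.mean() / (sd / np.sqrt(n))
    return jzs_bf_from_t(t, n, cauchy_scale)


def jzs_bf_from_t(t: float, n: int, cauchy_scale: float = 0.707) -> float:
    """One-sample JZS BF10 from a t statistic with n observations."""
    nu = n - 1
    r2 = cauchy_scale**2

    def integrand(g: float) -> float:
        c = 1.0 + n * g * r2
        dens = (1.0 / np.sqrt(2 * np.pi)) * g**-1.5 * np.exp(-1.0 / (2 * g))
        return c**-0.5 * (1.0 + t**2 / (c * nu)) ** (-(nu + 1) / 2.0) * dens

    num, _ = integrate.quad(integrand, 0, np.inf, epsrel=1e-6, limit=200)
    den = (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return float(num / den)


def jzs_correlation_bf(r: float, n: int) -> float:
    """Default two-sided Bayes factor (BF10) for a Pearson correlation.

    Jeffreys' correlation test with the uniform stretched-beta prior on
    the population correlation (the convention behind reported correlation
    Bayes factors), evaluated by quadrature of the exact marginal
    likelihood.
    """
    if not (-1.0 <= r <= 1.0) or n < 3:
        raise ValueError("need -1 <= r <= 1 and n >= 3")
    if abs(r) >= 1.0 - 1e-12:
        return np.inf

    def f(rho: float) -> float:
        return (
            (1.0 - rho**2) ** ((n - 1) / 2.0)
            * (1.0 - rho * r) ** ((3.0 - 2.0 * n) / 2.0)
            * special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
        )

    num, _ = integrate.quad(f, -1, 1, epsrel=1e-8)
    den = 2.0 * special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return float(num / den)


# ---------------------------------------------------------------------------
# Anxiety correlations


def subject_expectation_effects(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject and emotion: mean z-RT difference unexpected - expected."""
    df = trials if "rt_z" in trials else zscore_rt_within_experiment(trials)
    cell = df.groupby(["subject_id", "emotion", "expectation"])["rt_z"].mean()
    wide = cell.unstack("expectation")
    eff = (wide["unexpected"] - wide["expected"]).rename("effect").reset_index()
    anx = df.groupby("subject_id")["trait_anxiety"].first().rename("trait_anxiety")
    return eff.merge(anx, on="subject_id")


def anxiety_effect_correlation(effects: pd.DataFrame,
                               emotion: str) -> tuple[float, float, float]:
    """Pearson r (two-sided p) between trait anxiety and the expectation
    effect for one emotion, plus a JZS correlation Bayes factor."""
    sub = effects[effects["emotion"] == emotion].dropna(subset=["effect"])
    r, p = stats.pearsonr(sub["trait_anxiety"], sub["effect"])
    bf = jzs_correlation_bf(float(r), len(sub))
    return float(r), float(p), bf
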