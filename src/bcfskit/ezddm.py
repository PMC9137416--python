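"""Closed-form EZ-diffusion estimation and condition-wise ANOVAs.

The EZ model maps three summary statistics per subject x condition — mean
RT (``mrt``), RT variance (``vrt``) and proportion correct (``pc``) — to
the three diffusion parameters: drift rate ``v``, boundary separation ``a``
and non-decision time ``ter``, with the scaling constant ``s`` fixed at
0.1.  With L = logit(pc):

    x   = L (L pc^2 - L pc + pc - 1/2) / vrt
    v   = sign(pc - 1/2) s x^(1/4)
    a   = s^2 L / v
    y   = -v a / s^2
    MDT = (a / 2v) (1 - e^y) / (1 + e^y)
    ter = mrt - MDT

The mapping is exactly invertible: pc = 1/(1+e^y) and mrt = ter + MDT hold
to machine precision for any valid output.  pc = 0.5 leaves the drift
undefined; pc in {0, 1} excludes the subject (at least one correct and one
incorrect trial are required).  Below-chance pc yields negative drift and
is flagged rather than rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EZInput",
    "EZParams",
    "UndefinedDriftError",
    "PerfectAccuracyError",
    "ez_fit",
    "forward_moments",
    "moments_from_trials",
    "exclude_perfect_accuracy",
    "params_anova",
]


class UndefinedDriftError(ValueError):
    """pc = 0.5: the logit is zero and the drift direction undefined."""


class PerfectAccuracyError(ValueError):
    """pc in {0, 1}: EZ needs at least one correct and one incorrect trial."""


@dataclass(frozen=True)
class EZInput:
    subject_id: str
    condition: str
    mrt: float
    vrt: float
    pc: float
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.vrt <= 0:
            raise ValueError("vrt must be positive")
        if self.mrt <= 0:
            raise ValueError("mrt must be positive")
        if not (0.0 <= self.pc <= 1.0):
            raise ValueError("pc must lie in [0, 1]")


@dataclass(frozen=True)
class EZParams:
    v: float
    a: float
    ter: float
    s: float = 0.1
    below_chance: bool = False


def ez_fit(inp: EZInput, s: float = 0.1) -> EZParams:
    """Closed-form EZ parameter estimates from (mrt, vrt, pc)."""
    pc = inp.pc
    if pc in (0.0, 1.0):
        raise PerfectAccuracyError(
            f"{inp.subject_id}/{inp.condition}: pc={pc} leaves EZ undefined"
        )
    if pc == 0.5:
        raise UndefinedDriftError(
            f"{inp.subject_id}/{inp.condition}: pc=0.5 gives an undefined drift"
        )
    L = np.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / inp.vrt
    v = float(np.sign(pc - 0.5) * s * x**0.25)
    a = float(s**2 * L / v)
    y = -v * a / s**2
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    ter = float(inp.mrt - mdt)
    return EZParams(v=v, a=a, ter=ter, s=s, below_chance=pc < 0.5)


def forward_moments(params: EZParams) -> tuple[float, float, float]:
    """Exact (mrt, vrt, pc) implied by diffusion parameters (EZ forward map)."""
    v, a, s = params.v, params.a, params.s
    y = -v * a / s**2
    pc = 1.0 / (1.0 + np.exp(y))
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    vrt = (a * s**2 / (2.0 * v**3)) * (
        (2.0 * y * np.exp(y) - np.exp(2.0 * y) + 1.0) / (np.exp(y) + 1.0) ** 2
    )
    return params.ter + mdt, float(vrt), float(pc)


def moments_from_trials(trials: pd.DataFrame) -> list[EZInput]:
    """Per subject x condition RT moments, computed across all responded
    trials (correct and incorrect alike, per the all-trials convention)."""
    out = []
    resp = trials[trials["accuracy"].isin(["correct", "incorrect"])]
    for (sid, emo, exp_), grp in resp.groupby(
        ["subject_id", "emotion", "expectation"], sort=True
    ):
        if len(grp) < 2:
            continue
        out.append(EZInput(
            subject_id=sid,
            condition=f"{emo}_{exp_}",
            mrt=float(grp["rt"].mean()),
            vrt=float(grp["rt"].var(ddof=1)),
            pc=float((grp["accuracy"] == "correct").mean()),
            n_trials=len(grp),
        ))
    return out


def exclude_perfect_accuracy(
    inputs: list[EZInput],
) -> tuple[list[EZInput], list[tuple[str, str]]]:
    """Drop subjects with pc = 1 or pc = 0 in any condition.

    Returns (kept inputs, [(subject_id, offending condition), ...]).
    """
    excluded = {}
    for inp in inputs:
        if inp.pc in (0.0, 1.0) and inp.subject_id not in excluded:
            excluded[inp.subject_id] = inp.condition
    kept = [inp for inp in inputs if inp.subject_id not in excluded]
    return kept, sorted(excluded.items())


def _zscore_within_subject(df: pd.DataFrame, value: str) -> pd.Series:
    return df.groupby("subject_id")[value].transform(
        lambda x: (x - x.mean()) / x.std(ddof=1) if x.std(ddof=1) > 0 else x * 0.0
    )


def _zscore_within_cell(df: pd.DataFrame, value: str) -> pd.Series:
    return df.groupby("condition")[value].transform(
        lambda x: (x - x.mean()) / x.std(ddof=1) if x.std(ddof=1) > 0 else x * 0.0
    )


def params_anova(
    params_table: pd.DataFrame,
    zscore: str = "within_subject",
) -> dict[str, pd.DataFrame]:
    """2x2 repeated-measures ANOVAs (emotion x expectation within,
    experiment between) for each EZ parameter.

    ``params_table`` columns: subject_id, experiment_id, condition
    ("emotion_expectation"), v, a, ter.  Estimates are z-scored per subject
    across its four cells by default (``within_subject``) or per cell
    across subjects (``within_cell``).

    Both within factors have two levels, so the mixed ANOVA reduces
    exactly to per-subject contrast scores: each within effect's F equals
    the (intercept) F from an OLS of the contrast score on the
    between-subjects factor (effects-coded), and the effect's interaction
    with experiment is that model's experiment term.
    """
    df = params_table.copy()
    parts = df["condition"].str.split("_", expand=True)
    df["emotion"], df["expectation"] = parts[0], parts[1]
    counts = df.groupby("subject_id")["condition"].nunique()
    if (counts != 4).any():
        bad = counts[counts != 4].index.tolist()
        raise ValueError(f"incomplete 2x2 cells for subjects {bad}")
    out: dict[str, pd.DataFrame] = {}
    for param in ("v", "a", "ter"):
        col = f"{param}_z"
        if zscore == "within_subject":
            df[col] = _zscore_within_subject(df, param)
        elif zscore == "within_cell":
            df[col] = _zscore_within_cell(df, param)
        else:
            raise ValueError("zscore must be within_subject or within_cell")
        wide = df.pivot_table(index=["subject_id", "experiment_id"],
                              columns=["emotion", "expectation"], values=col)
        ne, nu = wide[("neutral", "expected")], wide[("neutral", "unexpected")]
        fe, fu = wide[("fearful", "expected")], wide[("fearful", "unexpected")]
        contrasts = {
            "emotion": ((fe + fu) - (ne + nu)) / 2.0,
            "expectation": ((nu + fu) - (ne + fe)) / 2.0,
            "interaction": (fu - fe) - (nu - ne),
        }
        experiment = wide.index.get_level_values("experiment_id").to_numpy()
        levels = np.unique(experiment)
        rows = []
        for name, c in contrasts.items():
            c = c.to_numpy(dtype=float)
            if len(levels) > 1:
                coded = np.where(experiment == levels[0], 1.0, -1.0)
                X = np.column_stack([np.ones_like(c), coded])
            else:
                X = np.ones((c.size, 1))
            fit = sm.OLS(c, X).fit()
            df_resid = int(fit.df_resid)
            if fit.scale <= 0 or not np.isfinite(fit.scale) or fit.scale < 1e-24:
                rows.append({"effect": name, "F": np.nan, "df1": 1,
                             "df2": df_resid, "p": np.nan, "degenerate": True})
                continue
            tval = fit.tvalues[0]
            F = float(tval**2)
            rows.append({"effect": name, "F": F, "df1": 1, "df2": df_resid,
                         "p": float(stats.f.sf(F, 1, df_resid)),
                         "degenerate": False})
            if len(levels) > 1:
                tb = fit.tvalues[1]
                Fb = float(tb**2)
                rows.append({"effect": f"{name} x experiment", "F": Fb,
                             "df1": 1, "df2": df_resid,
                             "p": float(stats.f.sf(Fb, 1, df_resid)),
                             "degenerate": False})
        out[param] = pd.DataFrame(rows)
    return out
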