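"""Self-validation benchmarks: each function recomputes, from scratch, one
of the package's headline accuracy or calibration figures on synthetic data
with known ground truth.  They back both the acceptance checks and the
reproducibility script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import replication
from .behaviour import jzs_bf_from_t
from .changepoint import detect_slope_change, extract_cluster_cps
from .clusterstats import second_level_test
from .design import experiment_spec, generate_block_sequence
from .eeg import EpochSet, gesd_outliers, smooth_moving_average
from .ezddm import EZInput, ez_fit
from .montage import chain_montage
from .synthdata import DDMParams, EffectConfig, generate_cohort, simulate_ddm_trials, simulate_epochs

__all__ = [
    "design_counts",
    "ez_grid_recovery",
    "slope_change_oracle_agreement",
    "cp_recovery_errors",
    "cluster_fwe_rate",
    "gesd_oracle_agreement",
    "boxcar_10hz_residual",
    "jzs_oracle_deviation",
]


def design_counts(seed: int = 0) -> dict:
    """Trial totals and per-expression condition counts, both experiments."""
    out = {}
    for exp in (1, 2):
        trials = generate_block_sequence(experiment_spec(exp), seed=seed + exp)
        counts = trials.groupby(["emotion", "expectation"]).size()
        out[f"exp{exp}_total_trials"] = int(len(trials))
        for emo in ("neutral", "fearful"):
            out[f"exp{exp}_expected_{emo}"] = int(counts[(emo, "expected")])
            out[f"exp{exp}_unexpected_{emo}"] = int(counts[(emo, "unexpected")])
    return out


def ez_grid_recovery(n_trials: int = 100_000, seed: int = 0) -> dict:
    """EZ round trip on a 3x3 (v, a) grid at ter = 0.3, s = 0.1.

    Simulates ``n_trials`` diffusion trials per cell, feeds the empirical
    (mrt, vrt, pc) moments to the closed-form estimator and reports the
    worst relative parameter error plus the worst forward-identity
    (implied-pc) deviation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    identity_dev = 0.0
    for v in (0.1, 0.2, 0.3):
        for a in (0.08, 0.11, 0.14):
            rt, correct = simulate_ddm_trials(
                DDMParams(v=v, a=a, ter=0.3), n_trials,
                seed=int(rng.integers(2**31)))
            ok = ~np.isnan(rt)
            est = ez_fit(EZInput("grid", f"v{v}a{a}", float(rt[ok].mean()),
                                 float(rt[ok].var(ddof=1)),
                                 float(correct[ok].mean())))
            rows.append({
                "v": v, "a": a,
                "v_err": abs(est.v - v) / v,
                "a_err": abs(est.a - a) / a,
                "ter_err": abs(est.ter - 0.3) / 0.3,
            })
            implied_pc = 1.0 / (1.0 + np.exp(-est.v * est.a / est.s**2))
            identity_dev = max(identity_dev,
                               abs(implied_pc - float(correct[ok].mean())))
    table = pd.DataFrame(rows)
    return {
        "max_relative_error": float(
            table[["v_err", "a_err", "ter_err"]].to_numpy().max()),
        "forward_identity_max_dev": float(identity_dev),
        "table": table,
        "n": n_trials,
    }


def _brute_split(y: np.ndarray, min_segment: int = 3) -> int:
    n = len(y)
    best, bk = None, None
    for k in range(min_segment, n - min_segment + 1):
        rss = 0.0
        for a, b in ((0, k), (k, n)):
            xx = np.arange(a, b)
            co = np.polyfit(xx, y[a:b], 1)
            rss += float(((y[a:b] - np.polyval(co, xx)) ** 2).sum())
        if best is None or rss < best - 1e-9:
            best, bk = rss, k
    return bk


def slope_change_oracle_agreement(n_vectors: int = 1000, seed: int = 0) -> dict:
    """Detector vs exhaustive split search on random vectors of length <= 60,
    plus sample-exact recovery of a noiseless two-segment signal."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        n = int(rng.integers(6, 61))
        y = rng.standard_normal(n)
        k, _ = detect_slope_change(y)
        agree += k == _brute_split(y)
    x = np.arange(60.0)
    k_clean, _ = detect_slope_change(np.where(x < 30, 0.0, x - 30))
    return {"agreement": agree / n_vectors, "n": n_vectors,
            "noiseless_break_error_samples": abs(k_clean - 30)}


def cp_recovery_errors(n_trials: int = 500, seed: int = 0,
                       effects: EffectConfig | None = None) -> dict:
    """Mean absolute early/late change-point error (ms) against the
    generator's stored break latencies, at the default SNR, after the
    pipeline's 200-ms smoothing."""
    effects = effects or EffectConfig(max_rt=3.0)
    design = replication.replication_design()
    rng = np.random.default_rng(seed)
    _, trials = generate_cohort(design, effects, max(6, n_trials // 80),
                                seed=int(rng.integers(2**31)))
    resp = trials[trials["accuracy"] == "correct"].head(n_trials)
    resp = resp.reset_index(drop=True)
    epochs, truth = simulate_epochs(resp, effects,
                                    seed=int(rng.integers(2**31)))
    smoothed = smooth_moving_average(epochs)
    records = extract_cluster_cps(smoothed, resp["rt"].to_numpy())
    truth = truth.set_index("trial")
    early_err = (records["early_cp"].to_numpy()
                 - truth.loc[records["trial"], "early_true"].to_numpy())
    late_err = (records["late_cp"].to_numpy()
                - truth.loc[records["trial"], "late_true"].to_numpy())
    return {
        "early_mae_ms": float(np.abs(early_err).mean() * 1000),
        "late_mae_ms": float(np.abs(late_err).mean() * 1000),
        "n": int(len(resp)),
    }


def cluster_fwe_rate(n_sims: int = 200, n_subjects: int = 12,
                     n_electrodes: int = 8, n_samples: int = 100,
                     n_perm: int = 500, seed: int = 0) -> dict:
    """Familywise false-positive rate of the second-level sign-flip test on
    i.i.d. Gaussian subject maps."""
    mont = chain_montage(n_electrodes)
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_sims):
        maps = rng.standard_normal((n_subjects, n_electrodes, n_samples))
        res = second_level_test(maps, mont, n_perm=n_perm,
                                seed=int(rng.integers(2**31)))
        hits += bool(res.significant())
    return {"fwe_rate": hits / n_sims, "n": n_sims}


def _brute_gesd(x: np.ndarray, alpha: float, max_outliers: int) -> list[int]:
    vals = x.copy()
    idx = np.arange(x.size)
    n = x.size
    removed, n_sig = [], 0
    for i in range(1, max_outliers + 1):
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            break
        j = int(np.argmax(np.abs(vals - mu)))
        r = abs(vals[j] - mu) / sd
        p = 1 - alpha / (2 * (n - i + 1))
        tcrit = stats.t.ppf(p, n - i - 1)
        lam = (n - i) * tcrit / np.sqrt((n - i - 1 + tcrit**2) * (n - i + 1))
        removed.append(int(idx[j]))
        if r > lam:
            n_sig = i
        vals = np.delete(vals, j)
        idx = np.delete(idx, j)
    return sorted(removed[:n_sig])


def gesd_oracle_agreement(n_inputs: int = 300, seed: int = 0) -> dict:
    """Equality with an independent brute-force Rosner recursion on random
    inputs of n <= 25 (with and without injected outliers)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_inputs):
        n = int(rng.integers(10, 26))
        x = rng.standard_normal(n)
        n_out = int(rng.integers(0, 3))
        x[:n_out] += rng.choice([-9.0, 9.0], size=n_out)
        mo = max(1, min(4, (n - 1) // 2 - 1))
        got = gesd_outliers(x, max_outliers=mo).tolist()
        agree += got == _brute_gesd(x, 0.05, mo)
    return {"agreement": agree / n_inputs, "n": n_inputs}


def boxcar_10hz_residual(sfreq: float = 100.0, window: float = 0.2) -> dict:
    """Residual amplitude (percent) of a 10 Hz sinusoid after the 200-ms
    moving average — the analytic null of the boxcar at 1/window Hz."""
    times = np.arange(int(6 * sfreq)) / sfreq
    sig = np.sin(2 * np.pi * 10.0 * times)
    ep = EpochSet(data=sig[None, None, :], sfreq=sfreq, times=times,
                  lock="stimulus", labels=["Pz"], adjacency=[])
    out = smooth_moving_average(ep, window=window)
    interior = out.data[0, 0, int(sfreq):-int(sfreq)]
    return {"residual_amplitude_pct": float(np.abs(interior).max() * 100),
            "n": int(interior.size)}


def jzs_oracle_deviation(seed: int = 0) -> dict:
    """Worst relative deviation of the JZS Bayes factor from an independent
    noncentral-t grid quadrature over a (t, n) grid."""
    delta = np.linspace(-15, 15, 30001)
    prior = stats.cauchy.pdf(delta, 0, 0.707)
    worst = 0.0
    grid = [(t, n) for t in (0.0, 0.5, 1.5, 2.5, 3.5, 5.0) for n in (5, 15, 40, 80)]
    for t, n in grid:
        nu = n - 1
        like = stats.nct.pdf(t, nu, delta * np.sqrt(n))
        oracle = np.trapezoid(like * prior, delta) / stats.t.pdf(t, nu)
        worst = max(worst, abs(jzs_bf_from_t(t, n) / oracle - 1.0))
    return {"max_relative_deviation_pct": float(worst * 100), "n": len(grid)}
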