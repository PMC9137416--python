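"""Expanding-window change-point detection for single-trial ERPs.

A single trial's pre-response waveform is idealised as piecewise linear:
flat during initial sensory encoding, ramping once evidence accumulation
begins (the "early" break) and steepening close to commitment (the "late"
break).  The detector finds, in a window, the split that minimises the
total residual sum of squares of two independently fitted regression
lines.  Because a single window would be dominated by the steep
pre-response segment, the procedure applies the detector to many windows
expanding in 50-ms steps from 0.1 s post-onset towards 0.3 s before the
response — so early samples appear in every window — and takes the modal
detected change point as the early latency; expanding the windows from
the response end backwards instead yields the late latency.

Change points are extracted per trial and electrode, then averaged over
the bilateral parietal-occipital cluster (P7, P9, PO7, P8, P10, PO8) and
the central-parietal cluster (Cz, CPz, Pz), and expressed both in seconds
post-onset and as a proportion of that trial's response time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behaviour import ModelFit, fit_lmm
from .eeg import EpochSet
from .montage import ELECTRODE_CLUSTERS

__all__ = [
    "detect_slope_change",
    "expanding_window_cp",
    "extract_cluster_cps",
    "window_durations",
    "correlate_windows_ddm",
    "fit_cp_models",
]

_TIE_TOL = 1e-9
# Pointwise level of the per-window F screen on the two-line improvement.
_SIGNIFICANCE_ALPHA = 0.01


def _segment_cumsums(y: np.ndarray):
    """Prefix sums for O(1) two-line RSS of any [i, j) segment of y.

    x is the sample index.  Returns closures over cumulative sums of
    1, x, x^2, y, x*y, y^2 along the last axis.
    """
    n = y.shape[-1]
    x = np.arange(n, dtype=float)
    zeros = np.zeros(y.shape[:-1] + (1,))

    def c(v):
        cs = np.cumsum(v, axis=-1)
        return np.concatenate([np.zeros_like(cs[..., :1]), cs], axis=-1)

    cx = np.concatenate([np.zeros(1), np.cumsum(x)])
    cxx = np.concatenate([np.zeros(1), np.cumsum(x * x)])
    cy = c(y)
    cyy = c(y * y)
    cxy = c(x * y)

    def rss(i, j):
        """RSS of one least-squares line on y[..., i:j); i, j broadcastable."""
        i, j = np.broadcast_arrays(np.asarray(i), np.asarray(j))
        m = (j - i).astype(float)
        s1 = cy[..., j] - cy[..., i]
        sx = cx[j] - cx[i]
        sxx = cxx[j] - cxx[i]
        sxy = cxy[..., j] - cxy[..., i]
        syy = cyy[..., j] - cyy[..., i]
        vxx = sxx - sx * sx / m
        vxy = sxy - sx * s1 / m
        vyy = syy - s1 * s1 / m
        out = vyy - np.where(vxx > 0, vxy * vxy / np.where(vxx > 0, vxx, 1.0), 0.0)
        return np.maximum(out, 0.0)

    return rss


def detect_slope_change(y: np.ndarray, min_segment: int = 3) -> tuple[int, bool]:
    """Best single change of linear slope in ``y``.

    Returns ``(k, degenerate)``: ``k`` is the 0-based first sample of the
    right segment minimising RSS(line on y[0:k)) + RSS(line on y[k:n)),
    ties broken towards the earliest k.  ``degenerate`` is set when the
    split does not improve on a single line (e.g. constant or purely
    linear input).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2 * min_segment:
        raise ValueError(f"need at least {2 * min_segment} samples")
    rss = _segment_cumsums(y)
    ks = np.arange(min_segment, n - min_segment + 1)
    total = rss(0, ks) + rss(ks, n)
    best = total.min()
    scale = max(rss(0, n), 1.0)
    k = int(ks[np.argmax(total <= best + _TIE_TOL * scale)])
    degenerate = (rss(0, n) - best) <= _TIE_TOL * scale
    return k, bool(degenerate)


def _window_breaks(y: np.ndarray, ends: np.ndarray, min_segment: int) -> np.ndarray:
    """Best split per expanding window over the last axis of ``y``.

    Windows share the segment start (index 0) and end at ``ends``
    (exclusive).  Returns breaks of shape ``y.shape[:-1] + (len(ends),)``;
    windows too short for two segments get -1.

    The (split x window) RSS matrices are evaluated in float32: RSS values
    here only rank candidate splits of noisy signals, and exact noiseless
    ties are still resolved through the shared tie tolerance.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[-1]
    rss = _segment_cumsums(y)
    kmax = n - min_segment
    ks = np.arange(min_segment, kmax + 1)
    left = rss(0, ks)  # (..., K)
    right = _right_rss_outer(y, ks, ends)  # (..., K, E)
    valid = ks[:, None] <= ends[None, :] - min_segment
    total = left[..., :, None].astype(np.float32) + right
    total = np.where(valid, total, np.inf)
    best = total.min(axis=-2, keepdims=True)
    scale = np.maximum(rss(0, n), 1.0)
    if np.ndim(scale):
        scale = scale[..., None, None]
    first = np.argmax(total <= best + _TIE_TOL * scale, axis=-2)
    breaks = ks[first]
    too_short = ends < 2 * min_segment
    breaks = np.where(too_short, -1, breaks)
    # A window only gets a vote if its split marks a *significant* slope
    # change: windows holding flat or single-slope content (plus noise)
    # otherwise pile their arbitrary best splits onto early indices.  The
    # screen is an F test of the two-line fit against one line (2 extra
    # parameters), plus an exact-degeneracy guard for noiseless input.
    from scipy import stats as _stats

    one_line = rss(0, ends)
    best_e = best.squeeze(-2)
    degen = (one_line - best_e) <= _TIE_TOL * np.maximum(one_line, 1.0)
    df2 = ends - 4
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = ((one_line - best_e) / 2.0) / np.where(
            best_e > 0, best_e / np.maximum(df2, 1), np.nan
        )
    fcrit = _stats.f.ppf(1.0 - _SIGNIFICANCE_ALPHA, 2, np.maximum(df2, 1))
    significant = np.isnan(fstat) | (fstat > fcrit)  # exact fits pass
    masked = np.where(degen | ~significant, -1, breaks)
    # Fall back to the unmasked votes where every window is screened out.
    all_out = (masked < 0).all(axis=-1, keepdims=True)
    return np.where(all_out, breaks, masked)


def _right_rss_outer(y: np.ndarray, ks: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Float32 RSS of one line on y[..., k:e) for all (k, e) pairs.

    Uses outer differences of 1-D prefix-sum gathers instead of paired
    fancy indexing; invalid pairs (e - k < 2) yield garbage that callers
    must mask out.
    """
    n = y.shape[-1]
    x = np.arange(n, dtype=np.float64)

    def c(v):
        cs = np.cumsum(v, axis=-1)
        return np.concatenate([np.zeros_like(cs[..., :1]), cs], axis=-1)

    cx = np.concatenate([np.zeros(1), np.cumsum(x)])
    cxx = np.concatenate([np.zeros(1), np.cumsum(x * x)])
    cy, cyy, cxy = c(y), c(y * y), c(x * y)

    def outer(pref):
        hi = pref[..., ends][..., None, :]
        lo = pref[..., ks][..., :, None]
        return (hi - lo).astype(np.float32)

    f32 = np.float32
    m = (ends[None, :] - ks[:, None]).astype(f32)
    m = np.where(m >= 2, m, f32(2))
    sx = (cx[ends][None, :] - cx[ks][:, None]).astype(f32)
    sxx = (cxx[ends][None, :] - cxx[ks][:, None]).astype(f32)
    s1 = outer(cy)
    sxy = outer(cxy)
    syy = outer(cyy)
    vxx = sxx - sx * sx / m
    vxy = sxy - sx * s1 / m
    vyy = syy - s1 * s1 / m
    vxx = np.where(vxx > 0, vxx, f32(1.0))
    out = vyy - vxy * vxy / vxx
    return np.maximum(out, f32(0.0))


# Half-width (samples) of the vote neighbourhood used when taking the mode
# over windows: detections of the same underlying break jitter by about one
# sample, so votes are pooled over +/-1 sample before the winner is picked.
_MODE_HALFWIDTH = 1


def _modal_rows(breaks: np.ndarray, n_values: int, prefer: str) -> np.ndarray:
    """Row-wise neighbourhood mode of break indices, (..., n_windows) -> (...,).

    Inadmissible windows are marked -1 and ignored.  Votes are pooled over
    a +/-``_MODE_HALFWIDTH``-sample neighbourhood; the winning
    neighbourhood's most-voted exact sample is returned.  Ties resolve to
    the smallest value for ``earliest`` and the largest for ``latest``.
    """
    flat = breaks.reshape(-1, breaks.shape[-1])
    vals = flat.copy()
    if prefer == "latest":
        # Work on mirrored indices so "first maximum" = "latest sample".
        vals = np.where(vals >= 0, n_values - 1 - vals, -1)
    rows = np.repeat(np.arange(flat.shape[0]), flat.shape[1])
    v = vals.ravel()
    ok = v >= 0
    counts = np.bincount(rows[ok] * n_values + v[ok],
                         minlength=flat.shape[0] * n_values)
    counts = counts.reshape(flat.shape[0], n_values)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("no admissible windows for some rows")
    h = _MODE_HALFWIDTH
    padded = np.pad(counts, ((0, 0), (h, h)))
    pooled = np.zeros_like(counts)
    for off in range(2 * h + 1):
        pooled += padded[:, off: off + n_values]
    centre = pooled.argmax(axis=1)  # first max = smallest value
    # Most-voted exact sample within the winning neighbourhood.
    offsets = np.arange(-h, h + 1)
    local = np.stack(
        [padded[np.arange(len(counts)), centre + h + o] for o in offsets], axis=1
    )
    modes = centre + offsets[local.argmax(axis=1)]
    modes = np.clip(modes, 0, n_values - 1)
    if prefer == "latest":
        modes = n_values - 1 - modes
    return modes.reshape(breaks.shape[:-1])


def _modal(values: np.ndarray, prefer: str) -> int:
    """Neighbourhood mode of one vote vector (see :func:`_modal_rows`)."""
    values = np.asarray(values, dtype=int)
    if (values >= 0).sum() == 0:
        raise ValueError("no admissible windows")
    n_values = int(values.max()) + 1
    return int(_modal_rows(values[None, :], n_values, prefer)[0])


@dataclass(frozen=True)
class ExpandingWindowConfig:
    step: float = 0.05
    t_start: float = 0.1
    guard: float = 0.3
    min_segment: int = 3


def expanding_window_cp(
    signal: np.ndarray,
    times: np.ndarray,
    rt: float,
    direction: str = "forward",
    step: float = 0.05,
    t_start: float = 0.1,
    guard: float = 0.3,
    min_segment: int = 3,
) -> float:
    """Modal change point (seconds post-onset) over expanding windows.

    ``forward`` windows run [t_start, t_start + j*step] for j = 1..J with
    the last endpoint at rt - guard, and bias towards the early break
    (ties to the earliest mode); ``reverse`` anchors windows at rt - guard
    expanding back towards t_start and biases towards the late break
    (ties to the latest mode).
    """
    breaks = _trial_window_breaks(
        np.asarray(signal, dtype=float)[None, :], times, rt, direction,
        step, t_start, guard, min_segment,
    )[0]
    sfreq = 1.0 / (times[1] - times[0])
    i0 = int(round((t_start - times[0]) * sfreq))
    prefer = "earliest" if direction == "forward" else "latest"
    k = _modal(breaks, prefer)
    return float(times[0] + (i0 + k) / sfreq)


def _trial_window_breaks(
    signals: np.ndarray,
    times: np.ndarray,
    rt: float,
    direction: str,
    step: float,
    t_start: float,
    guard: float,
    min_segment: int,
) -> np.ndarray:
    """Window-wise break indices (segment-relative) for channels x samples."""
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be forward or reverse")
    sfreq = 1.0 / (times[1] - times[0])
    n_windows = int(np.floor((rt - guard - t_start) / step + 1e-9))
    if n_windows < 1:
        raise ValueError("analysis interval shorter than the minimum window")
    i0 = int(round((t_start - times[0]) * sfreq))
    step_samp = int(round(step * sfreq))
    n_seg = n_windows * step_samp + 1
    if i0 < 0 or i0 + n_seg > times.size:
        raise ValueError("analysis interval outside the epoch")
    seg = signals[..., i0: i0 + n_seg]
    ends = (np.arange(1, n_windows + 1) * step_samp) + 1
    if direction == "reverse":
        seg = seg[..., ::-1]
    breaks = _window_breaks(seg, ends, min_segment)
    if direction == "reverse":
        breaks = np.where(breaks >= 0, n_seg - 1 - breaks, -1)
    return breaks


def extract_cluster_cps(
    epochs: EpochSet,
    rts: np.ndarray,
    clusters: dict[str, list[str]] | None = None,
    step: float = 0.05,
    t_start: float = 0.1,
    guard: float = 0.3,
    min_segment: int = 3,
) -> pd.DataFrame:
    """Early/late change points per trial x electrode cluster.

    Change points are detected per electrode and averaged over each
    cluster's electrodes; proportions are computed against the trial's RT.
    Trials whose analysis interval is shorter than one step are skipped
    (reason logged in the ``skipped`` attribute of the result).
    """
    clusters = clusters or ELECTRODE_CLUSTERS
    rts = np.asarray(rts, dtype=float)
    label_idx = {lab: i for i, lab in enumerate(epochs.labels)}
    cluster_idx = {}
    for name, labs in clusters.items():
        missing = [lab for lab in labs if lab not in label_idx]
        if missing:
            raise ValueError(f"cluster {name} missing electrodes {missing}")
        cluster_idx[name] = np.array([label_idx[lab] for lab in labs])
    table = epochs.trial_table
    skipped = []
    sfreq = epochs.sfreq
    i0 = int(round((t_start - epochs.times[0]) * sfreq))
    step_samp = int(round(step * sfreq))
    n_windows = np.floor((rts - guard - t_start) / step + 1e-9)
    n_windows = np.where(np.isnan(rts), 0, n_windows).astype(int)
    for i in np.nonzero(n_windows < 1)[0]:
        skipped.append((int(i), "analysis_interval_too_short"))

    early_cp = np.full(epochs.n_trials, np.nan)
    late_cp = np.full(epochs.n_trials, np.nan)
    all_idx = np.concatenate(list(cluster_idx.values()))
    cluster_slices = {}
    off = 0
    for name, idx in cluster_idx.items():
        cluster_slices[name] = slice(off, off + len(idx))
        off += len(idx)
    early_by_ch = np.full((epochs.n_trials, len(all_idx)), np.nan)
    late_by_ch = np.full((epochs.n_trials, len(all_idx)), np.nan)
    # Trials with equal window counts share segment geometry: batch them.
    for j in np.unique(n_windows[n_windows >= 1]):
        tr = np.nonzero(n_windows == j)[0]
        n_seg = j * step_samp + 1
        if i0 + n_seg > epochs.times.size:
            for i in tr:
                skipped.append((int(i), "analysis_interval_outside_epoch"))
            continue
        seg = epochs.data[np.ix_(tr, all_idx)][..., i0: i0 + n_seg]
        ends = (np.arange(1, j + 1) * step_samp) + 1
        fwd = _window_breaks(seg, ends, min_segment)
        rev = _window_breaks(seg[..., ::-1], ends, min_segment)
        rev = np.where(rev >= 0, n_seg - 1 - rev, -1)
        early_by_ch[tr] = _modal_rows(fwd, n_seg, "earliest")
        late_by_ch[tr] = _modal_rows(rev, n_seg, "latest")

    rows = []
    for name, idx in cluster_idx.items():
        sl = cluster_slices[name]
        early = epochs.times[0] + (i0 + early_by_ch[:, sl].mean(axis=1)) / sfreq
        late = epochs.times[0] + (i0 + late_by_ch[:, sl].mean(axis=1)) / sfreq
        for i in np.nonzero(n_windows >= 1)[0]:
            if np.isnan(early[i]):
                continue
            meta = table.iloc[i] if table is not None else {}
            rows.append({
                "subject_id": meta.get("subject_id", "sub-01"),
                "trial": int(i),
                "cluster": name,
                "early_cp": float(early[i]),
                "late_cp": float(late[i]),
                "rt": float(rts[i]),
                "early_prop": float(early[i] / rts[i]),
                "late_prop": float(late[i] / rts[i]),
                "order_violation": bool(late[i] < early[i]),
                "emotion": meta.get("emotion", ""),
                "expectation": meta.get("expectation", ""),
            })
    records = pd.DataFrame(rows).sort_values(["trial", "cluster"]).reset_index(drop=True)
    records.attrs["skipped"] = skipped
    return records


def window_durations(records: pd.DataFrame) -> pd.DataFrame:
    """Initial / middle / late window durations per change-point record.

    Records with late < early are flagged upstream and excluded here.
    """
    ok = records[~records["order_violation"]].copy()
    ok["initial"] = ok["early_cp"]
    ok["middle"] = ok["late_cp"] - ok["early_cp"]
    ok["late"] = ok["rt"] - ok["late_cp"]
    return ok


def correlate_windows_ddm(
    durations: pd.DataFrame,
    ez_params: pd.DataFrame,
    n_comparisons: int = 9,
) -> pd.DataFrame:
    """Pearson correlations between window durations and EZ parameters.

    ``durations``: subject_id, condition, initial, middle, late (seconds,
    per subject x condition).  ``ez_params``: subject_id, condition, v, a,
    ter.  Each variable is z-scored across conditions within participant,
    the data pooled, and each of the 3 x 3 correlations Bonferroni-
    adjusted (p_adj = min(1, 9p)).
    """
    from scipy import stats

    merged = durations.merge(ez_params, on=["subject_id", "condition"])
    if merged.empty:
        raise ValueError("no subjects present in both inputs")
    cols = ["initial", "middle", "late", "v", "a", "ter"]
    for c in cols:
        merged[c + "_z"] = merged.groupby("subject_id")[c].transform(
            lambda x: (x - x.mean()) / x.std(ddof=1) if x.std(ddof=1) > 0 else x * 0.0
        )
    rows = []
    for w in ("initial", "middle", "late"):
        for p in ("v", "a", "ter"):
            sub = merged[[w + "_z", p + "_z"]].dropna()
            r, praw = stats.pearsonr(sub[w + "_z"], sub[p + "_z"])
            rows.append({
                "window": w, "parameter": p, "r": float(r),
                "df": len(sub) - 2, "p": float(praw),
                "p_adj": float(min(1.0, n_comparisons * praw)),
            })
    return pd.DataFrame(rows)


def fit_cp_models(
    records: pd.DataFrame,
    emotion_ref: str = "fearful",
    expectation_ref: str = "expected",
) -> tuple[ModelFit, ModelFit]:
    """Mixed models for early and late change points.

    Early:  cp ~ Emotion x Expectation + ElectrodeGroup + EarlyRTprop
    Late:   cp ~ Emotion x Expectation + ElectrodeGroup + LateRTprop
                 + EarlyCP + EarlyRTprop
    both with a subject random intercept.  RT-proportion covariates enter
    exactly as printed despite their partial collinearity with the
    response; inspect them with :func:`bcfskit.behaviour.compute_vif`.
    """
    df = records.copy()
    emo = f"C(emotion, Treatment('{emotion_ref}'))"
    exp_ = f"C(expectation, Treatment('{expectation_ref}'))"
    early = fit_lmm(
        df, f"{emo} * {exp_} + C(cluster) + early_prop",
        response="early_cp",
        emm_numeric={"early_prop": float(df["early_prop"].mean())},
    )
    late = fit_lmm(
        df, f"{emo} * {exp_} + C(cluster) + late_prop + early_cp + early_prop",
        response="late_cp",
        emm_numeric={
            "late_prop": float(df["late_prop"].mean()),
            "early_cp": float(df["early_cp"].mean()),
            "early_prop": float(df["early_prop"].mean()),
        },
    )
    for f in (early, late):
        f.coding = {"emotion_ref": emotion_ref, "expectation_ref": expectation_ref}
    return early, late
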