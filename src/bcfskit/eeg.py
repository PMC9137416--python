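"""EEG preprocessing primitives.

The canonical pipeline order is: average reference -> band-pass + notch
filter -> downsample -> (artifact rejection) -> epoch -> interpolate bad
channels -> moving-average smoothing -> amplitude rejection ->
response-locking -> baseline correction.  Each primitive operates on either
continuous data (channels x samples) or an :class:`EpochSet`
(trials x channels x samples) and preserves shapes explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "PreprocConfig",
    "EpochSet",
    "rereference_average",
    "filter_signal",
    "downsample",
    "gesd_outliers",
    "epoch_continuous",
    "response_lock",
    "interpolate_bad_channels",
    "screen_bad_channels",
    "smooth_moving_average",
    "baseline_correct",
    "preprocess_epochs",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing constants.

    Band-pass 0.1-45 Hz with a 50 Hz notch, downsample to 100 Hz, GESD
    outlier screening at alpha=0.05, -0.1..3 s epochs, -50..0 ms baseline,
    200 ms moving-average smoothing.  The behavioural RT screen at this
    stage uses a 4-SD rule (the behavioural module's own rule is 3 SD).
    """

    bandpass: tuple[float, float] = (0.1, 45.0)
    notch: float = 50.0
    target_sfreq: float = 100.0
    gesd_alpha: float = 0.05
    epoch_window: tuple[float, float] = (-0.1, 3.0)
    baseline_window: tuple[float, float] = (-0.05, 0.0)
    smooth_window: float = 0.2
    response_lock_window: tuple[float, float] = (-1.0, 0.0)
    rt_sd_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if not (self.epoch_window[0] <= self.baseline_window[0]
                and self.baseline_window[1] <= self.epoch_window[1]):
            raise ValueError("baseline window must lie inside the epoch window")
        if self.smooth_window <= 0:
            raise ValueError("smooth window must be positive")


@dataclass
class EpochSet:
    """Trials x electrodes x samples with its time axis and montage.

    ``times`` is uniform at 1/sfreq; ``lock`` is ``stimulus`` or
    ``response``; ``adjacency`` is an undirected electrode edge list.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    lock: str
    labels: list[str]
    adjacency: list[tuple[int, int]]
    trial_table: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x electrodes x samples")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("electrode axis does not match labels")
        if self.data.shape[2] != self.times.size:
            raise ValueError("sample axis does not match times")
        dt = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(dt, 1.0 / self.sfreq, atol=1e-9):
            raise ValueError("times must be uniform at 1/sfreq and increasing")
        for i, j in self.adjacency:
            if i == j:
                raise ValueError("adjacency must be irreflexive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self, **changes) -> "EpochSet":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "log" not in changes:
            out.log = list(self.log)
        if "trial_table" not in changes and self.trial_table is not None:
            out.trial_table = self.trial_table.copy()
        return out

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("times", data=self.times)
            f.create_dataset("labels", data=np.array(self.labels, dtype="S"))
            f.create_dataset("adjacency", data=np.asarray(self.adjacency, dtype=np.int64)
                             if self.adjacency else np.empty((0, 2), dtype=np.int64))
            f.attrs["sfreq"] = self.sfreq
            f.attrs["lock"] = self.lock

    @classmethod
    def load_h5(cls, path, trial_table: pd.DataFrame | None = None) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][...].astype(np.float64),
                sfreq=float(f.attrs["sfreq"]),
                times=f["times"][...],
                lock=str(f.attrs["lock"]),
                labels=[s.decode() for s in f["labels"][...]],
                adjacency=[tuple(e) for e in f["adjacency"][...]],
                trial_table=trial_table,
            )


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across electrodes."""
    if epochs.data.shape[1] < 2:
        raise ValueError("average reference undefined for a single electrode")
    out = epochs.copy()
    out.data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    out.log.append("rereference_average")
    return out


def filter_signal(data: np.ndarray, sfreq: float,
                  config: PreprocConfig | None = None) -> np.ndarray:
    """Zero-phase band-pass (4th-order Butterworth) plus 50 Hz IIR notch.

    Operates on the last axis of continuous data (channels x samples).
    """
    config = config or PreprocConfig()
    lo, hi = config.bandpass
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    out = signal.sosfiltfilt(sos, data, axis=-1)
    if config.notch and config.notch < sfreq / 2:
        b, a = signal.iirnotch(config.notch, Q=30.0, fs=sfreq)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def downsample(data: np.ndarray, sfreq: float, target_sfreq: float) -> np.ndarray:
    """Polyphase resampling of the last axis to ``target_sfreq``."""
    from fractions import Fraction

    frac = Fraction(target_sfreq / sfreq).limit_denominator(1000)
    return signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)


def _gesd_lambda(n: int, i: int, alpha: float) -> float:
    # Rosner's critical value for the i-th removal (1-based).
    p = 1.0 - alpha / (2.0 * (n - i + 1))
    t = stats.t.ppf(p, df=n - i - 1)
    return (n - i) * t / np.sqrt((n - i - 1 + t**2) * (n - i + 1))


def gesd_outliers(values, alpha: float = 0.05, max_outliers: int | None = None) -> np.ndarray:
    """Generalised extreme studentized deviate (Rosner) outlier indices.

    Sequentially removes the most extreme studentized value; the flagged set
    is the first ``i*`` removals where ``i*`` is the largest step whose test
    statistic exceeds its critical value.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if max_outliers is None:
        max_outliers = max(1, int(0.2 * n))
    if max_outliers >= n / 2:
        raise ValueError("max_outliers must be below n/2")
    if n < 3 + max_outliers:
        raise ValueError("need at least 3 + max_outliers observations")
    remaining = np.arange(n)
    xr = x.copy()
    removed: list[int] = []
    n_flagged = 0
    for i in range(1, max_outliers + 1):
        mu, sd = xr.mean(), xr.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(xr - mu)
        j = int(np.argmax(dev))
        r = dev[j] / sd
        removed.append(int(remaining[j]))
        if r > _gesd_lambda(n, i, alpha):
            n_flagged = i
        remaining = np.delete(remaining, j)
        xr = np.delete(xr, j)
    return np.array(sorted(removed[:n_flagged]), dtype=int)


def epoch_continuous(
    continuous: np.ndarray,
    sfreq: float,
    event_samples,
    window: tuple[float, float] = (-0.1, 3.0),
    labels: list[str] | None = None,
    adjacency: list[tuple[int, int]] | None = None,
    trial_table: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut stimulus-locked epochs from continuous channels x samples data.

    Sample convention is half-open ``[start, end)`` with 0-based indices;
    the time of sample ``k`` is ``window[0] + k/sfreq``.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_ch, n_total = continuous.shape
    start_off = int(round(window[0] * sfreq))
    n_samp = int(round((window[1] - window[0]) * sfreq))
    epochs = []
    for ev in np.asarray(event_samples, dtype=int):
        a, b = ev + start_off, ev + start_off + n_samp
        if a < 0 or b > n_total:
            raise ValueError(f"epoch window for event at sample {ev} out of record")
        epochs.append(continuous[:, a:b])
    times = window[0] + np.arange(n_samp) / sfreq
    labels = labels or [f"ch{i}" for i in range(n_ch)]
    return EpochSet(
        data=np.stack(epochs) if epochs else np.empty((0, n_ch, n_samp)),
        sfreq=sfreq,
        times=times,
        lock="stimulus",
        labels=labels,
        adjacency=adjacency or [],
        trial_table=trial_table,
    )


def response_lock(
    epochs: EpochSet,
    rts,
    window: tuple[float, float] = (-1.0, 0.0),
) -> tuple[EpochSet, np.ndarray]:
    """Re-index stimulus-locked epochs so time zero is response onset.

    Pure re-indexing: no resampling.  Trials with missing RT, or whose
    response-locked window is not fully contained in the stimulus-locked
    epoch, are dropped; returns (locked epochs, indices of kept trials).
    """
    if epochs.lock != "stimulus":
        raise ValueError("response_lock expects stimulus-locked epochs")
    rts = np.asarray(rts, dtype=float)
    if rts.size != epochs.n_trials:
        raise ValueError("one RT per trial required")
    n_out = int(round((window[1] - window[0]) * epochs.sfreq))
    kept, cut = [], []
    dropped = []
    for i, rt in enumerate(rts):
        if np.isnan(rt):
            dropped.append((i, "no_response"))
            continue
        resp_idx = int(round((rt - epochs.times[0]) * epochs.sfreq))
        a = resp_idx + int(round(window[0] * epochs.sfreq))
        b = a + n_out
        if a < 0 or b > epochs.times.size:
            dropped.append((i, "window_out_of_epoch"))
            continue
        kept.append(i)
        cut.append(epochs.data[i, :, a:b])
    times = window[0] + np.arange(n_out) / epochs.sfreq
    out = EpochSet(
        data=np.stack(cut) if cut else np.empty((0, len(epochs.labels), n_out)),
        sfreq=epochs.sfreq,
        times=times,
        lock="response",
        labels=list(epochs.labels),
        adjacency=list(epochs.adjacency),
        trial_table=(epochs.trial_table.iloc[kept].reset_index(drop=True)
                     if epochs.trial_table is not None else None),
        log=list(epochs.log) + [f"response_lock dropped={dropped}"],
    )
    return out, np.array(kept, dtype=int)


def interpolate_bad_channels(epochs: EpochSet, bad_labels,
                             weights: dict | None = None) -> EpochSet:
    """Replace bad channels by the weighted mean of their good neighbours.

    Weights default to uniform over adjacency neighbours and are normalised
    to sum to one.
    """
    out = epochs.copy()
    bad_idx = {epochs.labels.index(lab) for lab in bad_labels}
    neigh: dict[int, set[int]] = {i: set() for i in range(len(epochs.labels))}
    for i, j in epochs.adjacency:
        neigh[i].add(j)
        neigh[j].add(i)
    for b in bad_idx:
        good = [g for g in neigh[b] if g not in bad_idx]
        if not good:
            raise ValueError(
                f"cannot interpolate {epochs.labels[b]}: no good neighbours"
            )
        w = np.array([1.0 if weights is None
                      else weights.get(epochs.labels[g], 1.0) for g in good])
        w = w / w.sum()
        out.data[:, b, :] = np.einsum("g,tgs->ts", w, epochs.data[:, good, :])
        out.log.append(f"interpolated {epochs.labels[b]} from "
                       f"{[epochs.labels[g] for g in good]}")
    return out


def smooth_moving_average(epochs: EpochSet, window: float = 0.2) -> EpochSet:
    """Centred boxcar smoothing; edges use a shrinking window.

    The window is ``round(window*sfreq)`` points; at 100 Hz the default
    200 ms boxcar (20 points) nulls the 10 Hz mask oscillation exactly.
    """
    w = int(round(window * epochs.sfreq))
    if w < 1:
        raise ValueError("smoothing window shorter than one sample")
    out = epochs.copy()
    out.data = _boxcar_shrink(epochs.data, w)
    out.log.append(f"smooth_moving_average window={w} samples")
    return out


def _boxcar_shrink(data: np.ndarray, w: int) -> np.ndarray:
    """Centred w-point moving average along the last axis, edges shrinking."""
    n = data.shape[-1]
    left = (w - 1) // 2
    right = w - 1 - left
    csum = np.cumsum(data, axis=-1)
    csum = np.concatenate([np.zeros_like(csum[..., :1]), csum], axis=-1)
    idx = np.arange(n)
    a = np.maximum(idx - left, 0)
    b = np.minimum(idx + right + 1, n)
    return (csum[..., b] - csum[..., a]) / (b - a)


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = (-0.05, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-electrode mean over the baseline window."""
    mask = (epochs.times >= window[0] - 1e-9) & (epochs.times <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError("baseline window outside the epoch")
    out = epochs.copy()
    out.data = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    out.log.append(f"baseline_correct window={window}")
    return out


def screen_bad_channels(epochs: EpochSet, alpha: float = 0.05) -> list[str]:
    """GESD screen for outlier electrodes.

    The feature is each electrode's log signal variance pooled over trials
    and time — a simplified variance screen standing in for component-based
    artifact classification.
    """
    feat = np.log(epochs.data.var(axis=(0, 2)) + 1e-30)
    bad = gesd_outliers(feat, alpha=alpha,
                        max_outliers=max(1, len(epochs.labels) // 5))
    return [epochs.labels[i] for i in bad]


def preprocess_epochs(epochs: EpochSet, config: PreprocConfig | None = None,
                      reject_artifacts: bool = True) -> EpochSet:
    """Epoch-level tail of the pipeline: reference, smooth, GESD trial
    screen, baseline.  (Continuous-data steps — filtering, downsampling —
    live in :func:`filter_signal` / :func:`downsample` and run upstream.)
    """
    config = config or PreprocConfig()
    out = rereference_average(epochs)
    out = smooth_moving_average(out, config.smooth_window)
    if reject_artifacts and out.n_trials >= 10:
        feat = np.log(out.data.var(axis=(1, 2)) + 1e-30)
        bad = gesd_outliers(feat, alpha=config.gesd_alpha)
        if bad.size:
            keep = np.setdiff1d(np.arange(out.n_trials), bad)
            out = out.copy(
                data=out.data[keep],
                trial_table=(out.trial_table.iloc[keep].reset_index(drop=True)
                             if out.trial_table is not None else None),
            )
            out.log.append(f"gesd rejected trials {bad.tolist()}")
    out = baseline_correct(out, config.baseline_window)
    return out
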