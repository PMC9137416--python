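"""Synthetic cohorts: diffusion-model response times and CPP-like EEG epochs.

Behavioural ground truth follows a two-boundary drift-diffusion process:
evidence starts equidistant between the boundaries (z = a/2), drifts at rate
``v`` with diffusion scale ``s`` (fixed at 0.1), and the response time is the
non-decision time ``Ter`` plus the first-passage time.  Condition effects
(emotion, expectation, and their moderation by trait anxiety) enter through
``Ter``, mirroring the observation that threat and surprise act on sensory
encoding rather than on the decision process itself.

EEG ground truth is a per-trial piecewise-linear "evidence accumulation"
ramp with two slope breaks — an early one near 25% of the trial window and a
late one near 61% — an emotion amplitude gain over parietal-occipital
electrodes, a 10 Hz mask oscillation plus its 20 Hz harmonic, and broadband
white + 1/f noise.  True break latencies are returned alongside the epochs
so downstream detectors can be scored; no analysis stage reads them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec, generate_subject_trials
from .eeg import EpochSet
from .montage import PARIETAL_OCCIPITAL, default_montage

__all__ = [
    "DDMParams",
    "EffectConfig",
    "SubjectProfile",
    "simulate_ddm_trial",
    "simulate_ddm_trials",
    "ddm_accuracy",
    "ddm_mean_decision_time",
    "generate_cohort",
    "simulate_epochs",
]


@dataclass(frozen=True)
class DDMParams:
    """Two-boundary diffusion parameters (unbiased start z = a/2)."""

    v: float
    a: float
    ter: float
    s: float = 0.1

    def __post_init__(self) -> None:
        if self.a <= 0 or self.ter <= 0 or self.s <= 0:
            raise ValueError("a, ter and s must be positive")


def ddm_accuracy(v: float, a: float, s: float = 0.1) -> float:
    """Closed-form P(upper boundary first) for an unbiased start."""
    if v == 0:
        return 0.5
    return 1.0 / (1.0 + np.exp(-v * a / s**2))


def ddm_mean_decision_time(v: float, a: float, s: float = 0.1) -> float:
    """Closed-form mean first-passage time for an unbiased start."""
    if v == 0:
        return a**2 / (4.0 * s**2)
    y = v * a / s**2
    return (a / (2.0 * v)) * np.tanh(y / 2.0)


def simulate_ddm_trials(
    params: DDMParams,
    n: int,
    seed: int,
    dt: float = 0.001,
    max_t: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Euler-Maruyama walks; returns (rt, correct).

    ``rt`` is NaN and ``correct`` False where no boundary is reached within
    ``max_t`` of decision time (a no-response trial).  Between-step boundary
    crossings are resolved with the Brownian-bridge crossing probability,
    which removes the O(sqrt(dt)) first-passage bias of the bare walk.
    """
    if dt <= 0 or dt >= params.a**2 / params.s**2:
        raise ValueError("dt must satisfy 0 < dt < a^2/s^2 for a stable walk")
    rng = np.random.default_rng(seed)
    a, s = params.a, params.s
    x = np.full(n, a / 2.0)
    rt = np.full(n, np.nan)
    correct = np.zeros(n, dtype=bool)
    active = np.arange(n)
    sq = s * np.sqrt(dt)
    var2 = s * s * dt
    n_steps = int(np.ceil(max_t / dt))
    for step in range(1, n_steps + 1):
        x_prev = x[active]
        x_new = x_prev + params.v * dt + sq * rng.standard_normal(active.size)
        hit_up = x_new >= a
        hit_lo = x_new <= 0.0
        inside = ~(hit_up | hit_lo)
        if inside.any():
            # Brownian bridge between the endpoints may still have crossed.
            xp, xn = x_prev[inside], x_new[inside]
            p_up = np.exp(-2.0 * (a - xp) * (a - xn) / var2)
            p_lo = np.exp(-2.0 * xp * xn / var2)
            u = rng.random(xp.size)
            bridge_up = u < p_up
            bridge_lo = (~bridge_up) & (u < p_up + p_lo)
            hit_up[inside] |= bridge_up
            hit_lo[inside] |= bridge_lo
        done = hit_up | hit_lo
        if done.any():
            idx = active[done]
            rt[idx] = params.ter + step * dt
            correct[idx] = hit_up[done]
            active = active[~done]
        x[active] = x_new[~done] if done.any() else x_new
        if active.size == 0:
            break
    return rt, correct


def simulate_ddm_trial(
    v: float,
    a: float,
    ter: float,
    s: float = 0.1,
    dt: float = 0.001,
    max_t: float = 10.0,
    seed: int = 0,
) -> tuple[float, bool]:
    """Single-trial convenience wrapper around :func:`simulate_ddm_trials`."""
    rt, correct = simulate_ddm_trials(
        DDMParams(v=v, a=a, ter=ter, s=s), n=1, seed=seed, dt=dt, max_t=max_t
    )
    return float(rt[0]), bool(correct[0])


@dataclass(frozen=True)
class EffectConfig:
    """Generative effect sizes, in the directions the task is built around.

    Non-decision time is shorter for fearful than neutral faces; surprise
    slows neutral encoding but speeds fearful encoding, more so in subjects
    with higher trait anxiety (negative moderation of the fearful
    expectation effect).  EEG effects shift the early slope break per
    condition and add a fearful amplitude gain over parietal-occipital
    electrodes.  Magnitudes are free generator parameters.
    """

    # Behaviour (seconds; anxiety slopes per mean-centred STAI point).
    ter_baseline: float = 1.60
    ter_emotion: float = -0.08          # fearful minus neutral
    ter_expectation_neutral: float = 0.05   # unexpected minus expected, neutral
    ter_expectation_fearful: float = -0.08  # unexpected minus expected, fearful
    anxiety_slope_neutral: float = 0.002
    anxiety_slope_fearful: float = -0.004
    ter_subject_sd: float = 0.08
    v_mean: float = 0.24
    v_subject_sd: float = 0.03
    a_mean: float = 0.11
    a_subject_sd: float = 0.008
    s: float = 0.1
    max_rt: float | None = None  # None -> trial never times out (Exp-1 style)

    # Anxiety distribution (STAI trait, bounded 20-80).
    anxiety_mean: float = 40.0
    anxiety_sd: float = 10.0

    # EEG (seconds / microvolts).
    early_frac: float = 0.25
    late_frac: float = 0.61
    early_shift_emotion: float = -0.01        # fearful minus neutral
    early_shift_expectation_neutral: float = 0.02
    early_shift_expectation_fearful: float = -0.02
    late_shift_emotion: float = -0.01
    fearful_gain: float = 1.3                 # multiplicative, PO electrodes
    gain_band: tuple[float, float] = (1.0, 2.2)
    mid_slope: float = 4.5                    # uV/s between breaks
    late_slope: float = 13.0                  # uV/s after the late break
    mask_amp: float = 2.0                     # 10 Hz mask oscillation, uV
    mask_harmonic_amp: float = 0.7            # 20 Hz harmonic, uV
    white_sd: float = 0.15                    # uV per sample
    pink_sd: float = 0.15                     # 1/f noise, uV RMS

    def ter_shift(self, emotion: str, expectation: str, anxiety_c: float) -> float:
        shift = 0.0
        if emotion == "fearful":
            shift += self.ter_emotion
        if expectation == "unexpected":
            if emotion == "fearful":
                shift += self.ter_expectation_fearful
                shift += self.anxiety_slope_fearful * anxiety_c
            else:
                shift += self.ter_expectation_neutral
                shift += self.anxiety_slope_neutral * anxiety_c
        return shift

    def early_shift(self, emotion: str, expectation: str) -> float:
        shift = 0.0
        if emotion == "fearful":
            shift += self.early_shift_emotion
        if expectation == "unexpected":
            if emotion == "fearful":
                shift += self.early_shift_expectation_fearful
            else:
                shift += self.early_shift_expectation_neutral
        return shift

    def late_shift(self, emotion: str) -> float:
        return self.late_shift_emotion if emotion == "fearful" else 0.0


@dataclass
class SubjectProfile:
    """Ground-truth generative description of one synthetic subject."""

    subject_id: str
    experiment_id: int
    trait_anxiety: float
    v: float
    a: float
    ter_baseline: float
    s: float = 0.1
    titrated_contrast: float = 76.75
    start_block_emotion: str = "neutral"

    def condition_ter(self, effects: EffectConfig, emotion: str,
                      expectation: str, anxiety_mean: float) -> float:
        ter = self.ter_baseline + effects.ter_shift(
            emotion, expectation, self.trait_anxiety - anxiety_mean
        )
        if ter <= 0:
            raise ValueError(
                f"{self.subject_id}: non-positive Ter in condition "
                f"({emotion}, {expectation})"
            )
        return ter


CONDITIONS = [
    ("neutral", "expected"),
    ("neutral", "unexpected"),
    ("fearful", "expected"),
    ("fearful", "unexpected"),
]


def generate_cohort(
    design: DesignSpec,
    effects: EffectConfig,
    n_subjects: int,
    seed: int,
) -> tuple[list[SubjectProfile], pd.DataFrame]:
    """Simulate a cohort: trial sequences plus diffusion-model RTs.

    Accuracy is "correct" on upper-boundary hits; trials whose first passage
    exceeds the trial window (``effects.max_rt``) are no-responses with
    missing RT.
    """
    root = np.random.default_rng(seed)
    profiles: list[SubjectProfile] = []
    tables: list[pd.DataFrame] = []
    anx_mean_pop = effects.anxiety_mean
    for i in range(n_subjects):
        sid_seed = int(root.integers(2**31))
        rng = np.random.default_rng(sid_seed)
        anxiety = float(np.clip(rng.normal(effects.anxiety_mean, effects.anxiety_sd), 20, 80))
        prof = SubjectProfile(
            subject_id=f"sub-{i + 1:02d}",
            experiment_id=design.experiment_id,
            trait_anxiety=anxiety,
            v=float(max(rng.normal(effects.v_mean, effects.v_subject_sd), 0.05)),
            a=float(max(rng.normal(effects.a_mean, effects.a_subject_sd), 0.04)),
            ter_baseline=float(
                max(rng.normal(effects.ter_baseline, effects.ter_subject_sd), 0.05)
            ),
            s=effects.s,
            start_block_emotion="neutral" if i % 2 == 0 else "fearful",
        )
        profiles.append(prof)
        trials = generate_subject_trials(design, subject_index=i, seed=int(rng.integers(2**31)))
        trials["rt"] = np.nan
        trials["accuracy"] = "no_response"
        max_t = effects.max_rt if effects.max_rt is not None else 10.0
        for emotion, expectation in CONDITIONS:
            mask = (trials["emotion"] == emotion) & (trials["expectation"] == expectation)
            n = int(mask.sum())
            if n == 0:
                continue
            ter = prof.condition_ter(effects, emotion, expectation, anx_mean_pop)
            params = DDMParams(v=prof.v, a=prof.a, ter=ter, s=prof.s)
            rt, correct = simulate_ddm_trials(
                params, n, seed=int(rng.integers(2**31)), max_t=max_t - ter
            )
            if effects.max_rt is not None:
                rt[rt > effects.max_rt] = np.nan
            acc = np.where(np.isnan(rt), "no_response",
                           np.where(correct, "correct", "incorrect"))
            trials.loc[mask, "rt"] = rt
            trials.loc[mask, "accuracy"] = acc
            trials.loc[mask, "ter_true"] = ter
        trials["trait_anxiety"] = anxiety
        tables.append(trials)
    return profiles, pd.concat(tables, ignore_index=True)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """1/f noise by spectral shaping of white noise (exponent 1)."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    out = np.fft.irfft(spec, n=n, axis=-1)
    rms = out.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return sd * out / rms


def simulate_epochs(
    trials: pd.DataFrame,
    effects: EffectConfig,
    montage: dict | None = None,
    seed: int = 0,
    sfreq: float = 100.0,
    tmin: float = -0.1,
    tmax: float = 3.0,
) -> tuple[EpochSet, pd.DataFrame]:
    """Simulate stimulus-locked epochs for the given trial table.

    Each responded trial carries a three-segment linear ramp with breaks at
    ``early = early_frac*rt + condition shift`` and ``late = late_frac*rt +
    condition shift``; no-response trials get the first ramp only.  Returns
    the EpochSet and a ground-truth table (true early/late latencies).
    """
    montage = montage or default_montage()
    labels = montage["labels"]
    required = set(PARIETAL_OCCIPITAL) | {"Cz", "CPz", "Pz"}
    missing = required - set(labels)
    if missing:
        raise ValueError(f"montage missing required electrodes: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n_trials = len(trials)
    n_ch = len(labels)
    times = tmin + np.arange(int(round((tmax - tmin) * sfreq))) / sfreq
    n_samp = times.size
    po_idx = np.array([labels.index(ch) for ch in PARIETAL_OCCIPITAL])

    t = np.maximum(times, 0.0)
    rt = trials["rt"].to_numpy(dtype=float)
    emotion = trials["emotion"].to_numpy()
    expectation = trials["expectation"].to_numpy()
    responded = ~np.isnan(rt)

    e_shift = np.zeros(n_trials)
    l_shift = np.zeros(n_trials)
    fearful = emotion == "fearful"
    unexpected = expectation == "unexpected"
    e_shift[fearful] += effects.early_shift_emotion
    e_shift[fearful & unexpected] += effects.early_shift_expectation_fearful
    e_shift[~fearful & unexpected] += effects.early_shift_expectation_neutral
    l_shift[fearful] += effects.late_shift_emotion

    early = np.where(
        responded,
        np.clip(effects.early_frac * rt + e_shift, 0.15,
                np.where(responded, rt, np.inf) - 0.45),
        effects.early_frac * (tmax - tmin),
    )
    late = np.where(
        responded,
        np.clip(effects.late_frac * rt + l_shift, early + 0.1,
                np.where(responded, rt, np.inf) - 0.35),
        np.nan,
    )
    mid_len = np.where(responded, late - early, np.inf)
    ramp = np.clip(t[None, :] - early[:, None], 0.0, mid_len[:, None]) * effects.mid_slope
    late_part = np.clip(
        t[None, :] - np.where(responded, late, np.inf)[:, None],
        0.0,
        np.where(responded, rt - late, 0.0)[:, None],
    ) * effects.late_slope
    ramp = ramp + late_part

    data = np.repeat(ramp[:, None, :], n_ch, axis=1)
    if effects.fearful_gain != 1.0 and fearful.any():
        # Graded gain envelope: raised-cosine edges so the emotion effect
        # modulates amplitude without introducing slope discontinuities.
        lo, hi = effects.gain_band
        edge = 0.3
        w = np.clip(np.minimum((times - lo) / edge, (hi - times) / edge), 0.0, 1.0)
        w = 0.5 - 0.5 * np.cos(np.pi * w)
        envelope = 1.0 + (effects.fearful_gain - 1.0) * w
        sel = np.ix_(np.nonzero(fearful)[0], po_idx)
        data[sel] *= envelope[None, None, :]
    truth_rows = [
        {"trial": i, "early_true": early[i], "late_true": late[i], "rt": rt[i]}
        for i in range(n_trials)
    ]

    osc = effects.mask_amp * np.sin(2 * np.pi * 10.0 * times)
    osc = osc + effects.mask_harmonic_amp * np.sin(2 * np.pi * 20.0 * times)
    data += osc[None, None, :]
    if effects.white_sd > 0:
        data += rng.normal(0.0, effects.white_sd, size=data.shape)
    if effects.pink_sd > 0:
        data += _pink_noise(rng, data.shape, effects.pink_sd)

    epochs = EpochSet(
        data=data,
        sfreq=sfreq,
        times=times,
        lock="stimulus",
        labels=list(labels),
        adjacency=[tuple(e) for e in montage["edges"]],
        trial_table=trials.reset_index(drop=True),
    )
    return epochs, pd.DataFrame(truth_rows)
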