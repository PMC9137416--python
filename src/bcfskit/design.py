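"""Oddball block/trial sequence generation for breaking-CFS experiments.

Two experiments share the same oddball logic: trials are presented in blocks
of 90, each block dominated (5:6) by one facial expression (neutral or
fearful).  The dominant expression is *expected*, the rare one *unexpected*.
Blocks alternate dominance; each block opens with at least two dominant
trials and rare trials are spaced 2-7 standards apart following a (truncated,
rounded) Gaussian.  Experiment 1 runs 8 blocks with a 6-s face contrast ramp
against a down-ramping mask; Experiment 2 runs 14 blocks with a 3-s ramp to a
titrated subject-specific maximum against a fixed 100%-contrast mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "DesignInfeasibleError",
    "experiment_spec",
    "generate_block_sequence",
    "generate_subject_trials",
    "assign_rotations",
    "sample_itis",
    "contrast_schedule",
    "StaircaseConfig",
    "run_titration_staircase",
]

EMOTIONS = ("neutral", "fearful")


class DesignInfeasibleError(ValueError):
    """Raised when deviants cannot be placed under the spacing constraints."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one experiment's trial design.

    ``dominant_ratio`` is the fraction of dominant-expression (expected)
    trials per block; ``deviant_spacing_range`` bounds the number of
    standards between consecutive deviants; ``ramp_duration`` is the face
    contrast ramp in seconds; ``mask_schedule`` is ``ramp_down`` (mask =
    100 - face) or ``fixed_100``.
    """

    experiment_id: int
    n_blocks: int = 8
    trials_per_block: int = 90
    dominant_ratio: float = 5.0 / 6.0
    min_leading_dominant: int = 2
    deviant_spacing_range: tuple[int, int] = (2, 7)
    ramp_duration: float = 6.0
    face_max_contrast: float = 100.0
    mask_schedule: str = "ramp_down"
    iti_range: tuple[float, float] = (0.5, 1.0)
    iti_step: float = 0.1
    rotation_magnitude: float = 5.0
    gap_mean: float = 4.5
    gap_sd: float = 1.25

    def __post_init__(self) -> None:
        if not (0.5 < self.dominant_ratio <= 1.0):
            raise ValueError("dominant_ratio must lie in (0.5, 1]")
        n_dom = self.dominant_ratio * self.trials_per_block
        if abs(n_dom - round(n_dom)) > 1e-9:
            raise ValueError(
                "trials_per_block * dominant_ratio must be an integer"
            )
        lo, hi = self.deviant_spacing_range
        if lo > hi or lo < 0:
            raise ValueError("invalid deviant_spacing_range")
        if self.mask_schedule not in ("ramp_down", "fixed_100"):
            raise ValueError("mask_schedule must be ramp_down or fixed_100")
        span = self.iti_range[1] - self.iti_range[0]
        if self.iti_step > 0 and abs(span / self.iti_step - round(span / self.iti_step)) > 1e-9:
            raise ValueError("iti step must divide iti range exactly")

    @property
    def n_dominant_per_block(self) -> int:
        return round(self.dominant_ratio * self.trials_per_block)

    @property
    def n_deviant_per_block(self) -> int:
        return self.trials_per_block - self.n_dominant_per_block


def experiment_spec(experiment_id: int) -> DesignSpec:
    """Printed design of Experiment 1 or 2."""
    if experiment_id == 1:
        return DesignSpec(experiment_id=1)
    if experiment_id == 2:
        return DesignSpec(
            experiment_id=2,
            n_blocks=14,
            ramp_duration=3.0,
            mask_schedule="fixed_100",
            iti_range=(0.25, 0.50),
            iti_step=0.05,
        )
    raise ValueError("experiment_id must be 1 or 2")


def _sample_gap(rng: np.random.Generator, spec: DesignSpec) -> int:
    """One deviant gap: rounded Gaussian resampled until within range."""
    lo, hi = spec.deviant_spacing_range
    if lo == hi:
        return lo
    while True:
        g = int(round(rng.normal(spec.gap_mean, spec.gap_sd)))
        if lo <= g <= hi:
            return g


def _place_deviants(rng: np.random.Generator, spec: DesignSpec) -> np.ndarray:
    """Deviant positions (0-based) for one block.

    gap = number of standards between consecutive deviants (and before the
    first one, which must also be >= min_leading_dominant).  The trailing
    run of standards is unconstrained.  Backtracks by full resampling.
    """
    n = spec.trials_per_block
    n_dev = spec.n_deviant_per_block
    if n_dev == 0:
        return np.empty(0, dtype=int)
    lo, _ = spec.deviant_spacing_range
    min_lead = max(spec.min_leading_dominant, lo)
    for _attempt in range(100):
        gaps = [max(_sample_gap(rng, spec), min_lead)]
        gaps += [_sample_gap(rng, spec) for _ in range(n_dev - 1)]
        pos = np.cumsum(np.asarray(gaps) + 1) - 1
        if pos[-1] < n:
            return pos
    raise DesignInfeasibleError(
        f"could not place {n_dev} deviants in {n} trials with gaps in "
        f"{spec.deviant_spacing_range} after 100 attempts"
    )


def generate_block_sequence(
    spec: DesignSpec,
    seed: int,
    start_emotion: str = "neutral",
    subject_id: str = "sub-01",
) -> pd.DataFrame:
    """Generate the full multi-block trial table for one subject.

    Block dominance alternates starting from ``start_emotion``; expectation
    is *expected* iff the trial's emotion equals the block's dominant one.
    """
    if start_emotion not in EMOTIONS:
        raise ValueError("start_emotion must be neutral or fearful")
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(spec.n_blocks):
        dominant = EMOTIONS[(EMOTIONS.index(start_emotion) + b) % 2]
        rare = EMOTIONS[1 - EMOTIONS.index(dominant)]
        dev_pos = set(_place_deviants(rng, spec).tolist())
        for t in range(spec.trials_per_block):
            emotion = rare if t in dev_pos else dominant
            rows.append(
                {
                    "subject_id": subject_id,
                    "experiment_id": spec.experiment_id,
                    "block_index": b,
                    "trial_index_in_block": t,
                    "block_dominant_emotion": dominant,
                    "emotion": emotion,
                    "expectation": "expected" if emotion == dominant else "unexpected",
                    "rotation": "",
                    "rt": np.nan,
                    "accuracy": "",
                    "excluded": False,
                    "exclusion_reason": "",
                }
            )
    trials = pd.DataFrame(rows)
    trials = assign_rotations(trials, seed=int(rng.integers(2**31)))
    trials["iti"] = sample_itis(len(trials), spec, seed=int(rng.integers(2**31)))
    return trials


def generate_subject_trials(spec: DesignSpec, subject_index: int, seed: int) -> pd.DataFrame:
    """Per-subject table with starting dominance counterbalanced by parity."""
    start = EMOTIONS[subject_index % 2]
    return generate_block_sequence(
        spec, seed=seed, start_emotion=start, subject_id=f"sub-{subject_index + 1:02d}"
    )


def assign_rotations(trials: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign cw/ccw rotations, balanced within block (counts differ <= 1)."""
    trials = trials.copy()
    if len(trials) == 0:
        return trials
    rng = np.random.default_rng(seed)
    rot = np.empty(len(trials), dtype=object)
    for _, idx in trials.groupby(["block_index"], sort=False).indices.items():
        n = len(idx)
        half = n // 2
        labels = np.array(["cw"] * half + ["ccw"] * (n - half), dtype=object)
        rng.shuffle(labels)
        rot[idx] = labels
    trials["rotation"] = rot
    return trials


def sample_itis(n: int, spec: DesignSpec, seed: int) -> np.ndarray:
    """Inter-trial intervals drawn uniformly on the design's jitter grid."""
    rng = np.random.default_rng(seed)
    lo, hi = spec.iti_range
    n_steps = int(round((hi - lo) / spec.iti_step)) + 1
    grid = lo + spec.iti_step * np.arange(n_steps)
    return rng.choice(grid, size=n)


def contrast_schedule(t: float, spec: DesignSpec) -> tuple[float, float]:
    """(face, mask) contrast in percent at time ``t`` into the ramp."""
    if t < 0 or t > spec.ramp_duration:
        raise ValueError(f"t={t} outside [0, {spec.ramp_duration}]")
    face = spec.face_max_contrast * t / spec.ramp_duration
    if spec.mask_schedule == "ramp_down":
        mask = 100.0 - face
    else:
        mask = 100.0
    return face, mask


@dataclass
class StaircaseConfig:
    """Titration staircase: contrast steps 10,8,6,4 across the first four
    reversals, then fixed at 2; goal RT 2 s; face+mask contrasts sum to 100."""

    goal_rt: float = 2.0
    initial_step: float = 10.0
    step_decrement: float = 2.0
    reversals_until_fixed: int = 4
    final_step: float = 2.0
    trials_per_block: int = 90
    n_blocks: int = 4
    start_contrast: float = 100.0


@dataclass
class _Staircase:
    config: StaircaseConfig
    contrast: float
    step: float = field(init=False)
    n_reversals: int = 0
    last_type: str | None = None  # "fast" | "slow"

    def __post_init__(self) -> None:
        self.step = self.config.initial_step

    def update(self, rt: float) -> None:
        # RT equal to the goal counts as "slow" (contrast increases).
        resp = "fast" if rt < self.config.goal_rt else "slow"
        if self.last_type is not None and resp != self.last_type:
            self.n_reversals += 1
            if self.n_reversals >= self.config.reversals_until_fixed:
                self.step = self.config.final_step
            else:
                self.step = max(
                    self.config.final_step,
                    self.config.initial_step
                    - self.config.step_decrement * self.n_reversals,
                )
        self.last_type = resp
        delta = -self.step if resp == "fast" else self.step
        self.contrast = float(np.clip(self.contrast + delta, 0.0, 100.0))


def run_titration_staircase(
    responder: Callable[[float], float],
    config: StaircaseConfig | None = None,
) -> float:
    """Simulate the four-block titration and return the final face contrast.

    Two independent staircases (one per dominant-emotion block type) each run
    over two blocks of 90 trials; the two final contrasts are averaged.
    ``responder`` maps face contrast (percent) to an RT in seconds.
    """
    config = config or StaircaseConfig()
    stairs = [
        _Staircase(config, contrast=config.start_contrast),
        _Staircase(config, contrast=config.start_contrast),
    ]
    # Blocks alternate between the two staircases: A B A B.
    for block in range(config.n_blocks):
        sc = stairs[block % 2]
        for trial in range(config.trials_per_block):
            try:
                rt = responder(sc.contrast)
            except Exception as exc:  # pragma: no cover - plumbing
                raise RuntimeError(
                    f"responder failed at block {block}, trial {trial}"
                ) from exc
            sc.update(rt)
    final = 0.5 * (stairs[0].contrast + stairs[1].contrast)
    return float(np.clip(final, 0.0, 100.0))
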