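"""End-to-end direction-replication runs on synthetic cohorts.

One replicate generates a cohort whose effects point in the directions the
task is built around (shorter non-decision time for fearful faces;
expectation effects of opposite sign for neutral vs fearful; negative
anxiety moderation of the fearful expectation effect), pushes it through
the behavioural pipeline (filters, last-standard selection, RT mixed
model, anxiety correlation) and the EEG pipeline (epoch simulation,
smoothing, change-point extraction, change-point mixed model), and
records whether each headline effect is recovered with the right sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behaviour import (
    apply_rt_filters,
    fit_rt_lmm,
    select_last_standards,
    subject_expectation_effects,
    anxiety_effect_correlation,
    zscore_rt_within_experiment,
)
from .changepoint import extract_cluster_cps, fit_cp_models
from .design import DesignSpec
from .eeg import smooth_moving_average
from .synthdata import EffectConfig, generate_cohort, simulate_epochs

__all__ = ["ReplicateOutcome", "run_replicate", "replication_rates"]


def _interaction_row(fit) -> pd.Series:
    name = [n for n in fit.params.index if n.count(":") == 1
            and "emotion" in n and "expectation" in n]
    return fit.params.loc[name[0]]


@dataclass
class ReplicateOutcome:
    rt_interaction_t: float
    rt_interaction_p: float
    cp_interaction_t: float
    cp_interaction_p: float
    anxiety_r_fearful: float

    @property
    def rt_interaction_sig(self) -> bool:
        return self.rt_interaction_p < 0.05

    @property
    def cp_interaction_sig_matching(self) -> bool:
        # Matching sign: with (fearful, expected) reference the interaction
        # must be positive in both the RT and the change-point model.
        return self.cp_interaction_p < 0.05 and (
            np.sign(self.cp_interaction_t) == np.sign(self.rt_interaction_t)
        )

    @property
    def anxiety_negative(self) -> bool:
        return self.anxiety_r_fearful < 0


def replication_design() -> DesignSpec:
    """Reduced study design used for replication runs: 2 blocks x 90
    trials per subject (one neutral-, one fearful-dominant), 3-s ramp."""
    return DesignSpec(
        experiment_id=2,
        n_blocks=2,
        ramp_duration=3.0,
        mask_schedule="fixed_100",
        iti_range=(0.25, 0.50),
        iti_step=0.05,
    )


def run_replicate(
    seed: int,
    n_subjects: int = 32,
    effects: EffectConfig | None = None,
    design: DesignSpec | None = None,
) -> ReplicateOutcome:
    """One full synthetic-cohort pipeline run."""
    effects = effects or EffectConfig(max_rt=3.0)
    design = design or replication_design()
    rng = np.random.default_rng(seed)
    _, trials = generate_cohort(design, effects, n_subjects,
                                seed=int(rng.integers(2**31)))
    kept, _ = apply_rt_filters(trials)
    selected = select_last_standards(kept)

    fit_rt = fit_rt_lmm(selected, formula="basic")
    rt_row = _interaction_row(fit_rt)

    eff = subject_expectation_effects(zscore_rt_within_experiment(selected))
    r_fear, _, _ = anxiety_effect_correlation(eff, "fearful")

    epochs, _ = simulate_epochs(selected, effects,
                                seed=int(rng.integers(2**31)))
    epochs = smooth_moving_average(epochs)
    records = extract_cluster_cps(epochs, selected["rt"].to_numpy())
    fit_early, _ = fit_cp_models(records)
    cp_row = _interaction_row(fit_early)

    return ReplicateOutcome(
        rt_interaction_t=float(rt_row["t"]),
        rt_interaction_p=float(rt_row["p"]),
        cp_interaction_t=float(cp_row["t"]),
        cp_interaction_p=float(cp_row["p"]),
        anxiety_r_fearful=float(r_fear),
    )


def replication_rates(
    n_replicates: int = 50,
    seed: int = 0,
    n_subjects: int = 32,
    effects: EffectConfig | None = None,
) -> dict:
    """Fraction of replicates recovering each headline effect."""
    root = np.random.SeedSequence(seed)
    outcomes = [
        run_replicate(int(s.generate_state(1)[0] % 2**31), n_subjects, effects)
        for s in root.spawn(n_replicates)
    ]
    return {
        "rt_interaction_rate": float(np.mean([o.rt_interaction_sig for o in outcomes])),
        "cp_interaction_rate": float(np.mean([o.cp_interaction_sig_matching
                                              for o in outcomes])),
        "anxiety_negative_rate": float(np.mean([o.anxiety_negative for o in outcomes])),
        "outcomes": outcomes,
    }
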