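import warnings

import numpy as np
import pandas as pd
import pytest

from bcfskit import behaviour, replication, synthdata

# MixedLM routinely reports boundary/Hessian warnings on variance components
# that are genuinely near zero in the synthetic designs; the fits themselves
# are checked against R in the oracle tests.
warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")
try:
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except Exception:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort on the reduced two-block design, with filters and
    last-standard selection applied."""
    design = replication.replication_design()
    effects = synthdata.EffectConfig(max_rt=3.0)
    profiles, trials = synthdata.generate_cohort(design, effects, 6, seed=401)
    kept, log = behaviour.apply_rt_filters(trials)
    selected = behaviour.select_last_standards(kept)
    return {
        "design": design,
        "effects": effects,
        "profiles": profiles,
        "trials": trials,
        "kept": kept,
        "selected": selected,
        "log": log,
    }


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    """Simulated epochs (with ground truth) for the selected trials."""
    sel = small_cohort["selected"].head(120).reset_index(drop=True)
    epochs, truth = synthdata.simulate_epochs(
        sel, small_cohort["effects"], seed=402
    )
    return {"trials": sel, "epochs": epochs, "truth": truth}
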