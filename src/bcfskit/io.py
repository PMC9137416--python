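"""Tabular I/O: BIDS-events-style trial tables and results TSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_events_tsv", "read_events_tsv", "write_table"]

_EVENT_COLUMNS = [
    "onset", "duration", "subject_id", "experiment", "block", "trial",
    "emotion", "expectation", "rotation", "rt", "accuracy", "excluded",
    "exclusion_reason",
]


def write_events_tsv(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as a BIDS-events-style TSV (missing RT -> n/a)."""
    df = trials.copy()
    rename = {
        "experiment_id": "experiment",
        "block_index": "block",
        "trial_index_in_block": "trial",
    }
    df = df.rename(columns={k: v for k, v in rename.items() if k in df})
    if "onset" not in df:
        dur = df.get("rt", pd.Series(np.nan, index=df.index)).fillna(0.0)
        iti = df.get("iti", pd.Series(0.5, index=df.index))
        df["duration"] = df.get("rt", np.nan)
        df["onset"] = (dur + iti).cumsum().shift(fill_value=0.0)
    cols = [c for c in _EVENT_COLUMNS if c in df]
    extra = [c for c in df.columns if c not in cols and c not in ("iti",)]
    df[cols + extra].to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=True)
    rename = {
        "experiment": "experiment_id",
        "block": "block_index",
        "trial": "trial_index_in_block",
    }
    return df.rename(columns={k: v for k, v in rename.items() if k in df})


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")
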