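"""Electrode montage and neighbour graph used across the package.

The default montage is a posterior subset of the 10-20 layout covering the
two electrode clusters used for change-point extraction: the bilateral
parietal-occipital cluster (P7, P9, PO7 / P8, P10, PO8) and the
central-parietal cluster (Cz, CPz, Pz).  Adjacency is stored as an
undirected edge list and serialised as JSON
``{"labels": [...], "edges": [[i, j], ...]}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "PARIETAL_OCCIPITAL",
    "CENTRAL_PARIETAL",
    "ELECTRODE_CLUSTERS",
    "default_montage",
    "chain_montage",
    "adjacency_matrix",
    "save_adjacency",
    "load_adjacency",
]

PARIETAL_OCCIPITAL = ["P7", "P9", "PO7", "P8", "P10", "PO8"]
CENTRAL_PARIETAL = ["Cz", "CPz", "Pz"]
ELECTRODE_CLUSTERS = {
    "parietal_occipital": PARIETAL_OCCIPITAL,
    "central_parietal": CENTRAL_PARIETAL,
}

_DEFAULT_LABELS = [
    "P7", "P9", "PO7", "POz", "Oz", "PO8", "P10", "P8", "Pz", "CPz", "Cz",
]
_DEFAULT_EDGES_BY_LABEL = [
    ("P7", "P9"), ("P7", "PO7"), ("P9", "PO7"),
    ("P8", "P10"), ("P8", "PO8"), ("P10", "PO8"),
    ("PO7", "POz"), ("POz", "PO8"), ("POz", "Oz"),
    ("PO7", "Oz"), ("PO8", "Oz"),
    ("Pz", "POz"), ("Pz", "PO7"), ("Pz", "PO8"),
    ("Pz", "CPz"), ("CPz", "Cz"),
    ("P7", "Pz"), ("P8", "Pz"),
]


def default_montage() -> dict:
    """Posterior 11-electrode montage with its neighbour edge list."""
    idx = {lab: i for i, lab in enumerate(_DEFAULT_LABELS)}
    edges = [[idx[a], idx[b]] for a, b in _DEFAULT_EDGES_BY_LABEL]
    return {"labels": list(_DEFAULT_LABELS), "edges": edges}


def chain_montage(n: int, prefix: str = "E") -> dict:
    """Synthetic linear-chain montage of ``n`` electrodes (for simulations)."""
    labels = [f"{prefix}{i + 1}" for i in range(n)]
    edges = [[i, i + 1] for i in range(n - 1)]
    return {"labels": labels, "edges": edges}


def adjacency_matrix(montage: dict) -> np.ndarray:
    """Boolean symmetric, irreflexive adjacency matrix from an edge list."""
    n = len(montage["labels"])
    adj = np.zeros((n, n), dtype=bool)
    for i, j in montage["edges"]:
        if i == j:
            raise ValueError("self-edges are not allowed in an adjacency")
        adj[i, j] = adj[j, i] = True
    return adj


def save_adjacency(montage: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(montage, indent=2))


def load_adjacency(path: str | Path) -> dict:
    montage = json.loads(Path(path).read_text())
    if set(montage) < {"labels", "edges"}:
        raise ValueError("adjacency JSON must contain 'labels' and 'edges'")
    return montage
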