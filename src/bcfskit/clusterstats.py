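"""Two-level spatiotemporal cluster-based permutation testing.

Pointwise t statistics over an electrode x time grid are thresholded at a
two-tailed alpha (default 0.05 on the t distribution), grouped into
connected clusters under the montage adjacency (same-sample neighbouring
electrodes) united with temporal contiguity (same electrode, consecutive
samples), and summarised by cluster mass (sum of t).  Permutation null
distributions use the maximum |mass| across clusters; the observed
labelling is always a member of the null set, so p >= 1/(n_perm + 1).

First level: trial-label shuffles (two-condition contrast) or covariate
shuffles (trial-wise regression, e.g. amplitude on RT), 100 permutations by
default.  Second level: subject-map sign flips (one-sample), 500 by
default, optionally replacing the one-sample t by the regression t on a
subject covariate (e.g. mean-centred trait anxiety) with covariate
permutation.  An FDR-corrected correlation map with a >=2-neighbouring-
electrode co-activation rule covers the parameter-correlation analyses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .montage import adjacency_matrix

__all__ = [
    "Cluster",
    "ClusterResult",
    "find_clusters",
    "first_level_contrast",
    "mismatch_difference",
    "second_level_test",
    "fdr_correlation_map",
]


@dataclass
class Cluster:
    members: np.ndarray  # (k, 2) array of (electrode, sample) indices
    mass: float
    sign: int
    p: float = np.nan


@dataclass
class ClusterResult:
    tmap: np.ndarray            # corrected map (non-cluster points zeroed)
    raw_tmap: np.ndarray
    clusters: list[Cluster]
    n_permutations: int
    threshold: float
    seed: int | None = None
    log: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= alpha]


def _grid_edges(adj: np.ndarray, n_samples: int) -> np.ndarray:
    """All connectivity edges on the electrode x time grid, as node pairs.

    Node id = electrode * n_samples + sample.  Spatial edges join
    neighbouring electrodes at the same sample; temporal edges join
    consecutive samples at the same electrode.
    """
    n_el = adj.shape[0]
    ei, ej = np.nonzero(np.triu(adj, 1))
    s = np.arange(n_samples)
    spatial = np.stack([
        (ei[:, None] * n_samples + s[None, :]).ravel(),
        (ej[:, None] * n_samples + s[None, :]).ravel(),
    ], axis=1)
    e = np.arange(n_el)
    temporal = np.stack([
        (e[:, None] * n_samples + s[None, :-1]).ravel(),
        (e[:, None] * n_samples + s[None, 1:]).ravel(),
    ], axis=1)
    return np.concatenate([spatial, temporal], axis=0)


def find_clusters(tmap: np.ndarray, threshold: float,
                  edges: np.ndarray) -> list[Cluster]:
    """Signed suprathreshold clusters of an electrode x time t-map."""
    n_el, n_samp = tmap.shape
    flat = tmap.ravel()
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = flat * sign > threshold
        if not mask.any():
            continue
        keep = mask[edges[:, 0]] & mask[edges[:, 1]]
        sub = edges[keep]
        n_nodes = flat.size
        graph = sparse.coo_matrix(
            (np.ones(len(sub)), (sub[:, 0], sub[:, 1])), shape=(n_nodes, n_nodes)
        )
        n_comp, labels = connected_components(graph, directed=False)
        masked_idx = np.nonzero(mask)[0]
        comp_of = labels[masked_idx]
        for comp in np.unique(comp_of):
            nodes = masked_idx[comp_of == comp]
            members = np.stack([nodes // n_samp, nodes % n_samp], axis=1)
            clusters.append(Cluster(
                members=members,
                mass=float(flat[nodes].sum()),
                sign=sign,
            ))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _max_cluster_mass(tmap: np.ndarray, threshold: float,
                      edges: np.ndarray) -> float:
    cl = find_clusters(tmap, threshold, edges)
    return max((abs(c.mass) for c in cl), default=0.0)


def _two_sample_tmap(data: np.ndarray, labels: np.ndarray) -> np.ndarray:
    a, b = data[labels], data[~labels]
    na, nb = len(a), len(b)
    va = a.var(axis=0, ddof=1) / na
    vb = b.var(axis=0, ddof=1) / nb
    denom = np.sqrt(va + vb)
    denom[denom == 0] = np.inf
    return (a.mean(axis=0) - b.mean(axis=0)) / denom


def _regression_tmap(data: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Pointwise t of the slope of amplitude on a trial covariate."""
    n = len(covariate)
    xc = covariate - covariate.mean()
    sxx = float(xc @ xc)
    yc = data - data.mean(axis=0)
    beta = np.tensordot(xc, yc, axes=(0, 0)) / sxx
    resid = yc - beta[None] * xc[:, None, None]
    mse = (resid**2).sum(axis=0) / (n - 2)
    se = np.sqrt(mse / sxx)
    se[se == 0] = np.inf
    return beta / se


def _attach_pvalues(clusters: list[Cluster], null_max: np.ndarray) -> None:
    m = len(null_max)
    for c in clusters:
        c.p = float((np.sum(null_max >= abs(c.mass) - 1e-12) + 0.0) / m)


def first_level_contrast(
    epochs_data: np.ndarray,
    labels_or_covariate: np.ndarray,
    montage: dict,
    n_perm: int = 100,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    exhaustive: bool = False,
    zero_nonsignificant: bool = True,
) -> ClusterResult:
    """Subject-level corrected t-map (trials x electrodes x samples input).

    Boolean ``labels_or_covariate`` runs a two-sample contrast with label
    shuffles; a float array runs a trial-wise regression with covariate
    shuffles.  Points outside clusters surviving the permutation test at
    ``cluster_alpha`` are zeroed (configurable).
    """
    data = np.asarray(epochs_data, dtype=float)
    cov = np.asarray(labels_or_covariate)
    n_trials = data.shape[0]
    if cov.shape[0] != n_trials:
        raise ValueError("one label/covariate per trial required")
    two_sample = cov.dtype == bool
    if two_sample and (cov.all() or (~cov).all()):
        raise ValueError("degenerate label split: both conditions required")
    if two_sample and (cov.sum() < 2 or (~cov).sum() < 2):
        raise ValueError("need >= 2 trials per condition")
    adj = adjacency_matrix(montage)
    edges = _grid_edges(adj, data.shape[2])
    df = n_trials - 2
    threshold = stats.t.ppf(1 - alpha / 2, df)
    observed = _two_sample_tmap(data, cov) if two_sample else _regression_tmap(data, cov)
    clusters = find_clusters(observed, threshold, edges)

    rng = np.random.default_rng(seed)
    null_max = []
    if exhaustive and two_sample:
        n1 = int(cov.sum())
        for comb in itertools.combinations(range(n_trials), n1):
            perm = np.zeros(n_trials, dtype=bool)
            perm[list(comb)] = True
            null_max.append(_max_cluster_mass(_two_sample_tmap(data, perm),
                                              threshold, edges))
    else:
        null_max.append(_max_cluster_mass(observed, threshold, edges))
        for _ in range(n_perm - 1):
            if two_sample:
                perm = rng.permutation(cov)
                t = _two_sample_tmap(data, perm)
            else:
                t = _regression_tmap(data, rng.permutation(cov))
            null_max.append(_max_cluster_mass(t, threshold, edges))
    null_max = np.asarray(null_max)
    _attach_pvalues(clusters, null_max)

    corrected = observed.copy()
    if zero_nonsignificant:
        keep = np.zeros_like(corrected, dtype=bool)
        for c in clusters:
            if c.p <= cluster_alpha:
                keep[c.members[:, 0], c.members[:, 1]] = True
        corrected[~keep] = 0.0
    return ClusterResult(
        tmap=corrected, raw_tmap=observed, clusters=clusters,
        n_permutations=len(null_max), threshold=float(threshold), seed=seed,
    )


def mismatch_difference(
    epochs_data: np.ndarray,
    emotion: np.ndarray,
    expectation: np.ndarray,
) -> dict[str, np.ndarray]:
    """Single-trial mismatch sets: each unexpected trial minus that
    emotion's mean expected waveform, per emotion."""
    emotion = np.asarray(emotion)
    expectation = np.asarray(expectation)
    out = {}
    for emo in np.unique(emotion):
        exp_mask = (emotion == emo) & (expectation == "expected")
        unexp_mask = (emotion == emo) & (expectation == "unexpected")
        if not exp_mask.any() or not unexp_mask.any():
            raise ValueError(f"both expected and unexpected trials required for {emo}")
        mean_expected = epochs_data[exp_mask].mean(axis=0)
        out[str(emo)] = epochs_data[unexp_mask] - mean_expected[None]
    return out


def second_level_test(
    subject_maps: np.ndarray,
    montage: dict,
    n_perm: int = 500,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    covariate: np.ndarray | None = None,
    seed: int = 0,
    exhaustive: bool = False,
) -> ClusterResult:
    """Group-level sign-flip cluster permutation on subject t-maps.

    With a covariate, the statistic is the regression t of each subject's
    map value on the (mean-centred) covariate and permutations shuffle the
    covariate across subjects.
    """
    maps = np.asarray(subject_maps, dtype=float)
    n_sub = maps.shape[0]
    adj = adjacency_matrix(montage)
    edges = _grid_edges(adj, maps.shape[2])
    if covariate is None:
        df = n_sub - 1

        def one_sample_t(signs: np.ndarray) -> np.ndarray:
            flipped = maps * signs[:, None, None]
            m = flipped.mean(axis=0)
            sd = flipped.std(axis=0, ddof=1)
            sd[sd == 0] = np.inf
            return m / (sd / np.sqrt(n_sub))

        threshold = stats.t.ppf(1 - alpha / 2, df)
        observed = one_sample_t(np.ones(n_sub))
        clusters = find_clusters(observed, threshold, edges)
        rng = np.random.default_rng(seed)
        null_max = []
        if exhaustive:
            for signs in itertools.product([1.0, -1.0], repeat=n_sub):
                null_max.append(_max_cluster_mass(
                    one_sample_t(np.array(signs)), threshold, edges))
        else:
            null_max.append(_max_cluster_mass(observed, threshold, edges))
            for _ in range(n_perm - 1):
                signs = rng.choice([-1.0, 1.0], size=n_sub)
                null_max.append(_max_cluster_mass(
                    one_sample_t(signs), threshold, edges))
    else:
        cov = np.asarray(covariate, dtype=float)
        cov = cov - cov.mean()
        df = n_sub - 2
        threshold = stats.t.ppf(1 - alpha / 2, df)
        observed = _regression_tmap(maps, cov)
        clusters = find_clusters(observed, threshold, edges)
        rng = np.random.default_rng(seed)
        null_max = [_max_cluster_mass(observed, threshold, edges)]
        for _ in range(n_perm - 1):
            null_max.append(_max_cluster_mass(
                _regression_tmap(maps, rng.permutation(cov)), threshold, edges))
    null_max = np.asarray(null_max)
    _attach_pvalues(clusters, null_max)
    corrected = observed.copy()
    keep = np.zeros_like(corrected, dtype=bool)
    for c in clusters:
        if c.p <= cluster_alpha:
            keep[c.members[:, 0], c.members[:, 1]] = True
    corrected[~keep] = 0.0
    if n_perm <= 100 and not exhaustive:
        warnings.warn("p-value resolution at <=100 permutations is 0.01 or coarser")
    return ClusterResult(
        tmap=corrected, raw_tmap=observed, clusters=clusters,
        n_permutations=len(null_max), threshold=float(threshold), seed=seed,
    )


def fdr_correlation_map(
    subject_maps: np.ndarray,
    covariate: np.ndarray,
    montage: dict,
    alpha: float = 0.05,
    min_coactive: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise Pearson correlation across subjects, BH-FDR corrected,
    retaining only samples where >= ``min_coactive`` adjacent electrodes
    co-survive.  Returns (significant boolean map, r map)."""
    maps = np.asarray(subject_maps, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    n = len(cov)
    xc = cov - cov.mean()
    yc = maps - maps.mean(axis=0)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum(axis=0))
    denom[denom == 0] = np.inf
    r = np.tensordot(xc, yc, axes=(0, 0)) / denom
    r = np.clip(r, -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    rej, _, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    sig = rej.reshape(r.shape)
    adj = adjacency_matrix(montage)
    # Neighbour rule: a surviving point needs itself plus at least
    # (min_coactive - 1) adjacent electrodes surviving at the same sample.
    counts = sig.astype(int) + adj.astype(int) @ sig.astype(int)
    sig = sig & (counts >= min_coactive)
    return sig, r
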