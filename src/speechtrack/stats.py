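"""Group-level inference: paired t-tests and cluster-mass permutation tests.

The permutation scheme for paired condition contrasts flips the sign of
each subject's condition difference (equivalent to exchanging the condition
labels within a subject), uses a two-tailed paired t per cell as the test
statistic, forms sign-homogeneous suprathreshold clusters (temporal
adjacency for waveforms, 4-neighbour time-frequency adjacency for maps),
scores them by summed |t| mass, and compares each observed cluster with the
permutation null of the maximum cluster mass. Multiple comparisons are
corrected within a channel: no cross-channel clustering is performed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sp_stats

__all__ = [
    "paired_t",
    "cluster_permutation",
    "cluster_fwer_simulation",
    "ClusterResult",
    "decoding_tmap",
    "tmap_correlation",
    "cluster_table",
]


def paired_t(
    a: np.ndarray, b: np.ndarray, tail: str = "one_greater"
) -> tuple[float, int, float]:
    """Paired t-test on per-subject (a, b) values.

    ``tail="one_greater"`` tests a > b (the attended-exceeds-ignored
    direction); ``tail="two"`` is two-sided. Returns ``(t, df, p)``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    df = n - 1
    if sd == 0:
        if np.all(d == 0):  # identical conditions: no evidence either way
            return 0.0, df, 0.5 if tail == "one_greater" else 1.0
        raise ValueError("degenerate test: zero-variance differences")
    t = float(d.mean() / (sd / np.sqrt(n)))
    if tail == "one_greater":
        p = float(sp_stats.t.sf(t, df))
    elif tail == "two":
        p = float(2 * sp_stats.t.sf(abs(t), df))
    else:
        raise ValueError("tail must be 'one_greater' or 'two'")
    return t, df, p


def _t_map(diffs: np.ndarray) -> np.ndarray:
    """Paired t per cell from per-subject difference maps (n x cells...)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _max_cluster_mass(t: np.ndarray, threshold: float) -> float:
    """Maximum summed-|t| mass over sign-homogeneous suprathreshold clusters."""
    best = 0.0
    for sign in (1.0, -1.0):
        mask = sign * t > threshold
        if not mask.any():
            continue
        labels, n_lab = ndimage.label(mask)
        if n_lab:
            masses = ndimage.sum_labels(np.abs(t), labels, np.arange(1, n_lab + 1))
            best = max(best, float(np.max(masses)))
    return best


@dataclass
class Cluster:
    cells: np.ndarray  # boolean mask over the map
    mass: float
    sign: int
    p_value: float
    significant: bool


@dataclass
class ClusterResult:
    """Observed clusters, their Monte-Carlo p-values and significance mask."""

    t_map: np.ndarray
    pre_threshold: float
    clusters: list[Cluster] = field(default_factory=list)
    null_max_masses: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_permutations: int = 0
    significance_mask: np.ndarray | None = None

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.clusters)


def cluster_permutation(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int = 10000,
    p_pre: float = 0.01,
    p_cluster: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Cluster-mass permutation test between paired condition arrays.

    ``cond_a``/``cond_b`` hold one within-subject average per subject:
    shape (n_subjects, n_times) for waveforms or
    (n_subjects, n_freqs, n_times) for time-frequency maps. Adjacency is
    temporal for 1-D data and 4-connected in (frequency, time) for 2-D.
    The null flips each subject's condition difference (full enumeration
    when 2**n_subjects <= n_perm, random sign draws otherwise).
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must be aligned")
    if a.ndim not in (2, 3):
        raise ValueError("expect (subjects x times) or (subjects x freqs x times)")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives very coarse p-values", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    diffs = a - b
    t_obs = _t_map(diffs)
    t_crit = float(sp_stats.t.ppf(1 - p_pre / 2, n - 1))

    # observed clusters
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = sign * t_obs > t_crit
        if not mask.any():
            continue
        labels, n_lab = ndimage.label(mask)
        for lab in range(1, n_lab + 1):
            cells = labels == lab
            clusters.append(
                Cluster(cells, float(np.abs(t_obs[cells]).sum()), sign, 1.0, False)
            )

    # permutation null of the maximum cluster mass; the identity arrangement
    # (all signs +1) is always part of the ensemble, as required for a valid
    # Monte-Carlo permutation test (full enumeration includes it anyway)
    if 2**n <= n_perm:
        sign_sets = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        sign_sets = rng.choice([1.0, -1.0], size=(n_perm, n))
        sign_sets[0] = 1.0
    flat = diffs.reshape(n, -1)
    sq_mean = np.mean(flat**2, axis=0)  # invariant under sign flips
    null = np.empty(sign_sets.shape[0])
    shape = diffs.shape[1:]
    for i, signs in enumerate(sign_sets):
        mean = (signs @ flat) / n
        var = (sq_mean - mean**2) * n / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = mean / np.sqrt(var / n)
        t_perm = np.where(var == 0, 0.0, t_perm).reshape(shape)
        null[i] = _max_cluster_mass(t_perm, t_crit)

    cutoff = float(np.quantile(null, 1 - p_cluster)) if null.size else np.inf
    sig_mask = np.zeros(t_obs.shape, dtype=bool)
    for c in clusters:
        c.p_value = float((1 + np.sum(null >= c.mass)) / (null.size + 1))
        c.significant = c.mass > cutoff
        if c.significant:
            sig_mask |= c.cells
    clusters.sort(key=lambda c: -c.mass)
    return ClusterResult(
        t_map=t_obs,
        pre_threshold=t_crit,
        clusters=clusters,
        null_max_masses=null,
        n_permutations=sign_sets.shape[0],
        significance_mask=sig_mask,
    )


def cluster_table(result: ClusterResult) -> pd.DataFrame:
    """Tidy table of the observed clusters (one row per cluster)."""
    rows = [
        {
            "mass": c.mass,
            "sign": c.sign,
            "n_cells": int(c.cells.sum()),
            "p_value": c.p_value,
            "significant": c.significant,
        }
        for c in result.clusters
    ]
    return pd.DataFrame(rows, columns=["mass", "sign", "n_cells", "p_value", "significant"])


def cluster_fwer_simulation(
    n_datasets: int = 500,
    n_subjects: int = 12,
    n_cells: int = 40,
    n_perm: int = 1000,
    p_pre: float = 0.01,
    p_cluster: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise error rate of the cluster test under a simulated null.

    Both conditions are i.i.d. standard normal (no true effect); the
    returned value is the fraction of datasets in which any cluster reaches
    significance, which should sit near ``p_cluster``.
    """
    rng = np.random.default_rng(seed)
    false_positives = 0
    for _ in range(n_datasets):
        a = rng.standard_normal((n_subjects, n_cells))
        b = rng.standard_normal((n_subjects, n_cells))
        res = cluster_permutation(
            a, b, n_perm=n_perm, p_pre=p_pre, p_cluster=p_cluster, seed=rng
        )
        false_positives += res.any_significant
    return false_positives / n_datasets


def decoding_tmap(attended: np.ndarray, ignored: np.ndarray) -> np.ndarray:
    """One-tailed paired t per channel for an attention-decoding measure.

    Inputs are (n_subjects x n_channels) per-subject measure values; the
    test direction is attended > ignored.
    """
    att = np.asarray(attended, dtype=float)
    ign = np.asarray(ignored, dtype=float)
    if att.shape != ign.shape or att.ndim != 2:
        raise ValueError("expect matching (subjects x channels) arrays")
    return np.array(
        [paired_t(att[:, c], ign[:, c])[0] for c in range(att.shape[1])]
    )


def tmap_correlation(map_a: np.ndarray, map_b: np.ndarray) -> tuple[float, float]:
    """Spatial correlation of two channel-wise t-maps with a two-sided p.

    The p-value comes from the t transform of r with df = channels - 2.
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("maps must share the channel set")
    if a.size < 3:
        raise ValueError("need at least 3 channels")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("zero-variance t-map")
    res = sp_stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
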