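"""Circular statistics and cluster-based permutation correction.

Rayleigh test for non-uniformity of angles; Watson–Williams one-way test for
equal mean directions of two concentrated circular samples; and a generic
cluster-mass permutation correction over units (frequency bins or
electrodes) with an injected per-unit statistic and null generator, following
the usual EEG cluster-correction scheme: supra-threshold units are grouped by
adjacency, cluster mass is the sum of |statistic|, and the corrected p-value
compares each observed mass to the permutation distribution of the maximum
cluster mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .io import logger


@dataclass
class CircTestResult:
    statistic: float
    p: float
    n: tuple[int, ...]


@dataclass
class Cluster:
    members: list[int]
    mass: float
    p_corrected: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold_used: float
    n_permutations: int


# ---------------------------------------------------------------------------
# Circular tests
# ---------------------------------------------------------------------------

def _resultant(angles_deg: np.ndarray) -> tuple[float, float]:
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    v = np.sum(np.exp(1j * th))
    return float(np.abs(v)), float(np.angle(v))


def rayleigh_test(angles_deg: Sequence[float]) -> CircTestResult:
    """Rayleigh test of circular uniformity.

    Statistic is the mean resultant length R̄; the p-value uses the standard
    approximation p = exp(√(1+4n+4(n²−R²)) − (1+2n)) with R = nR̄.
    """
    angles = np.asarray(angles_deg, dtype=float)
    n = angles.size
    if n < 3:
        raise ValueError("Rayleigh test needs at least 3 angles")
    R, _ = _resultant(angles)
    rbar = R / n
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - R ** 2)) - (1 + 2 * n)))
    return CircTestResult(statistic=rbar, p=min(p, 1.0), n=(n,))


def _kappa_from_rbar(rbar: float) -> float:
    # Fisher's approximation of the vM concentration from R̄
    if rbar < 0.53:
        return 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)


def watson_williams(angles_a: Sequence[float], angles_b: Sequence[float]
                    ) -> CircTestResult:
    """Watson–Williams two-sample test for equal circular means.

    Assumes both samples are concentrated (warns when the pooled mean
    resultant length falls below 0.45, where the F approximation degrades).
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each group needs at least 5 angles")
    n, m = a.size, b.size
    N = n + m
    Ra, _ = _resultant(a)
    Rb, _ = _resultant(b)
    Rt, _ = _resultant(np.r_[a, b])
    rw = (Ra + Rb) / N
    if rw < 0.45:
        logger.warning("Watson-Williams: pooled R̄=%.2f < 0.45; the "
                       "F approximation is unreliable", rw)
    kappa = _kappa_from_rbar(rw)
    corr = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    denom = N - Ra - Rb
    if denom <= 0:
        return CircTestResult(statistic=0.0, p=1.0, n=(n, m))
    F = corr * (N - 2) * (Ra + Rb - Rt) / denom
    F = max(F, 0.0)
    p = float(sps.f.sf(F, 1, N - 2))
    return CircTestResult(statistic=float(F), p=p, n=(n, m))


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------

def frequency_adjacency(freqs: Sequence[float]) -> list[tuple[int, int]]:
    """Chain adjacency over a sorted frequency axis."""
    f = np.asarray(freqs, dtype=float)
    if f.size < 2:
        raise ValueError("need at least 2 frequencies")
    if np.any(np.diff(f) <= 0):
        raise ValueError("frequencies must be sorted and unique")
    return [(i, i + 1) for i in range(f.size - 1)]


def electrode_adjacency(xy_coords: np.ndarray, max_dist: float | None = None
                        ) -> list[tuple[int, int]]:
    """Neighbor pairs of 2-D electrode positions within ``max_dist``
    (default 1.5 × the median nearest-neighbor distance)."""
    xy = np.asarray(xy_coords, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("coordinates must be (n, 2)")
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 electrodes")
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    off = d + np.diag(np.full(len(xy), np.inf))
    if np.any(off == 0):
        raise ValueError("duplicate electrode coordinates")
    if max_dist is None:
        max_dist = 1.5 * float(np.median(off.min(axis=1)))
    return [(i, j) for i in range(len(xy)) for j in range(i + 1, len(xy))
            if d[i, j] <= max_dist]


# ---------------------------------------------------------------------------
# Cluster permutation
# ---------------------------------------------------------------------------

def _find_clusters(stats_arr: np.ndarray, neighbors: list[set],
                   threshold: float, two_sided: bool
                   ) -> list[tuple[list[int], float]]:
    vals = np.abs(stats_arr) if two_sided else stats_arr
    supra = vals > threshold
    seen = np.zeros(stats_arr.size, dtype=bool)
    clusters = []
    for u in range(stats_arr.size):
        if not supra[u] or seen[u]:
            continue
        stack, members = [u], []
        seen[u] = True
        while stack:
            v = stack.pop()
            members.append(v)
            for w in neighbors[v]:
                if supra[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        clusters.append((sorted(members), float(vals[members].sum())))
    return clusters


def cluster_correct(unit_stats: np.ndarray,
                    adjacency: list[tuple[int, int]],
                    null_generator: Callable[[np.random.Generator], np.ndarray],
                    stat_threshold: float,
                    n_permutations: int = 500,
                    seed: int = 0,
                    two_sided: bool = True) -> ClusterResult:
    """Cluster-mass permutation correction.

    ``null_generator(rng)`` must return one permuted unit-statistic array per
    call (e.g. group-label shuffles of subject-level data).  Corrected
    p-values use the (1 + exceedances)/(1 + n_permutations) convention.
    """
    unit_stats = np.asarray(unit_stats, dtype=float)
    U = unit_stats.size
    neighbors: list[set] = [set() for _ in range(U)]
    for i, j in adjacency:
        if i == j:
            continue
        neighbors[i].add(j)
        neighbors[j].add(i)
    observed = _find_clusters(unit_stats, neighbors, stat_threshold, two_sided)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = np.asarray(null_generator(rng), dtype=float)
        cl = _find_clusters(perm, neighbors, stat_threshold, two_sided)
        null_max[p] = max((m for _, m in cl), default=0.0)
    clusters = [
        Cluster(members=mem, mass=mass,
                p_corrected=float((1 + np.sum(null_max >= mass))
                                  / (1 + n_permutations)))
        for mem, mass in observed
    ]
    return ClusterResult(clusters=clusters, threshold_used=stat_threshold,
                         n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# Default per-unit statistic and label-shuffle null
# ---------------------------------------------------------------------------

def welch_t_units(group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Welch two-sample t per unit; inputs are (n_subjects, n_units)."""
    t, _ = sps.ttest_ind(group_a, group_b, axis=0, equal_var=False)
    return np.asarray(t)


def label_shuffle_null(data: np.ndarray, n_a: int
                       ) -> Callable[[np.random.Generator], np.ndarray]:
    """Null generator shuffling group labels of stacked subject data
    (``data`` is (n_a + n_b, n_units))."""
    data = np.asarray(data, dtype=float)

    def gen(rng: np.random.Generator) -> np.ndarray:
        perm = rng.permutation(data.shape[0])
        return welch_t_units(data[perm[:n_a]], data[perm[n_a:]])

    return gen


def t_threshold(df: float, alpha: float = 0.05) -> float:
    """Two-sided cluster-forming |t| threshold at the given alpha."""
    return float(sps.t.ppf(1 - alpha / 2, df))
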