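"""Spatiotemporal cluster formation and random-permutation inference for ERPs.

The test statistic for a cluster is the sum of pointwise paired t values
over its member (electrode, time point) pairs.  Two points are connected
when they share an electrode and are adjacent samples, or share a sample
and are adjacent electrodes (Euclidean distance at most ``max_dist``,
default 45 mm); there is no diagonal (simultaneous time-and-electrode)
adjacency.  The permutation null swaps each subject's condition labels
independently — equivalently, sign-flips that subject's paired difference —
and retains the largest cluster sum of each permutation.  Permutation
p-values use the (1 + count) / (1 + n_permutations) estimator, so they are
never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .epochs import EvokedSet, window_to_samples
from .montage import Montage
from .erp import difference_wave

__all__ = [
    "AdjacencyGraph",
    "SpatioTemporalCluster",
    "ClusterPermutationTest",
    "ClusterTestResult",
    "build_adjacency",
    "pointwise_paired_t",
    "form_clusters",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Electrode neighborhood under a maximum-distance rule."""

    neighbors: tuple[frozenset, ...]
    max_dist: float
    labels: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return len(self.neighbors)

    @property
    def mean_degree(self) -> float:
        return float(np.mean([len(s) for s in self.neighbors]))

    def pairs(self) -> np.ndarray:
        """(n_pairs, 2) array of neighbor index pairs with i < j."""
        out = [(i, j) for i, s in enumerate(self.neighbors) for j in s if i < j]
        return np.array(out, dtype=int).reshape(-1, 2)


def build_adjacency(montage: Montage, max_dist: float = 45.0) -> AdjacencyGraph:
    """Neighbors are distinct electrodes within ``max_dist`` mm (inclusive)."""
    d = montage.distances()
    adj = (d > 0) & (d <= max_dist)
    neighbors = tuple(frozenset(np.flatnonzero(row)) for row in adj)
    return AdjacencyGraph(neighbors, max_dist, montage.labels)


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t over axis 0; zero-variance points get t = 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    var = diffs.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[var == 0] = 0.0
    return t


def pointwise_paired_t(evoked: EvokedSet, window: tuple[float, float],
                       tail: str = "greater"):
    """Per-point paired t and one-tailed p maps for JOL minus no-JOL.

    Returns ``(t_map, p_map)`` of shape (channels, samples in window).
    Zero-variance points get t = 0 and p = 1 so they never enter clusters.
    """
    if evoked.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    idx = window_to_samples(evoked.time, *window)
    diffs = difference_wave(evoked)[:, :, idx.start:idx.stop]
    t = _paired_t(diffs)
    df = evoked.n_subjects - 1
    if tail == "greater":
        p = stats.t.sf(t, df)
    elif tail == "less":
        p = stats.t.cdf(t, df)
    elif tail == "two":
        p = 2 * stats.t.sf(np.abs(t), df)
    else:
        raise ValueError("tail must be 'greater', 'less' or 'two'")
    p[t == 0] = 1.0
    return t, p


@dataclass
class SpatioTemporalCluster:
    """A connected set of supra-threshold (electrode, sample) points."""

    points: np.ndarray          # (k, 2) of (channel index, sample index in window)
    t_sum: float
    channel_labels: tuple[str, ...]
    sample_offset: int          # window start as sample index into the epoch
    step_ms: float
    t_start_window_ms: float    # epoch time of sample_offset
    p_rand: float | None = None

    @property
    def electrodes(self) -> tuple[str, ...]:
        return tuple(self.channel_labels[i] for i in sorted(set(self.points[:, 0])))

    @property
    def time_window_ms(self) -> tuple[float, float]:
        s = self.points[:, 1]
        return (self.t_start_window_ms + s.min() * self.step_ms,
                self.t_start_window_ms + s.max() * self.step_ms)

    @property
    def n_points(self) -> int:
        return len(self.points)


def _component_sums(t_map: np.ndarray, supra: np.ndarray,
                    adj_pairs: np.ndarray):
    """Connected components of the supra-threshold mask and their t sums.

    Connectivity: same channel + adjacent samples, or same sample +
    adjacent channels.  Returns (labels_per_point, point_index_pairs,
    sums) where point indices are positions in ``np.flatnonzero(supra)``.
    """
    flat_idx = np.flatnonzero(supra.ravel())
    n_pts = flat_idx.size
    if n_pts == 0:
        return np.empty(0, dtype=int), flat_idx, np.empty(0)
    n_ch, n_sp = supra.shape
    # edge list in flat coordinates
    rows = []
    cols = []
    temporal = supra[:, :-1] & supra[:, 1:]
    r = np.flatnonzero(temporal.ravel())
    if r.size:
        src = (r // (n_sp - 1)) * n_sp + (r % (n_sp - 1))
        rows.append(src)
        cols.append(src + 1)
    for i, j in adj_pairs:
        both = np.flatnonzero(supra[i] & supra[j])
        if both.size:
            rows.append(i * n_sp + both)
            cols.append(j * n_sp + both)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        # compress to supra-point indices
        lookup = -np.ones(n_ch * n_sp, dtype=int)
        lookup[flat_idx] = np.arange(n_pts)
        g = sparse.coo_matrix(
            (np.ones(rows.size, dtype=np.int8), (lookup[rows], lookup[cols])),
            shape=(n_pts, n_pts))
        _, labels = connected_components(g, directed=False)
    else:
        labels = np.arange(n_pts)
    sums = np.bincount(labels, weights=t_map.ravel()[flat_idx])
    return labels, flat_idx, sums


def form_clusters(t_map: np.ndarray, p_map: np.ndarray,
                  adjacency: AdjacencyGraph, cluster_alpha: float = 0.05,
                  tail: str = "greater", *, sample_offset: int = 0,
                  step_ms: float = 2.0, t_start_window_ms: float = 0.0
                  ) -> list[SpatioTemporalCluster]:
    """Group supra-threshold points into connected clusters with t sums."""
    if t_map.shape != p_map.shape:
        raise ValueError("t and p maps must share shape")
    if tail == "greater":
        supra = (p_map < cluster_alpha) & (t_map > 0)
    elif tail == "less":
        supra = (p_map < cluster_alpha) & (t_map < 0)
    elif tail == "two":
        supra = p_map < cluster_alpha
    else:
        raise ValueError("tail must be 'greater', 'less' or 'two'")
    labels, flat_idx, sums = _component_sums(t_map, supra, adjacency.pairs())
    n_sp = t_map.shape[1]
    clusters = []
    for lab in range(len(sums)):
        pts_flat = flat_idx[labels == lab]
        pts = np.stack([pts_flat // n_sp, pts_flat % n_sp], axis=1)
        clusters.append(SpatioTemporalCluster(
            pts, float(sums[lab]), adjacency.labels, sample_offset,
            step_ms, t_start_window_ms))
    clusters.sort(key=lambda c: abs(c.t_sum), reverse=True)
    return clusters


@dataclass
class ClusterTestResult:
    """Observed clusters with permutation p-values and the max-sum null."""

    clusters: list[SpatioTemporalCluster]
    null_max_sums: np.ndarray
    n_permutations: int
    tail: str
    cluster_alpha: float
    window: tuple[float, float]
    t_map: np.ndarray = field(repr=False, default=None)
    p_map: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[SpatioTemporalCluster]:
        return [c for c in self.clusters if c.p_rand is not None and c.p_rand < alpha]

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, c in enumerate(self.clusters):
            lo, hi = c.time_window_ms
            rows.append(dict(
                cluster=k, n_points=c.n_points, t_sum=c.t_sum, p_rand=c.p_rand,
                t_start_ms=lo, t_end_ms=hi, n_electrodes=len(c.electrodes),
                electrodes=",".join(c.electrodes)))
        return pd.DataFrame(rows, columns=["cluster", "n_points", "t_sum", "p_rand",
                                           "t_start_ms", "t_end_ms", "n_electrodes",
                                           "electrodes"])


class ClusterPermutationTest:
    """Spatiotemporal cluster permutation test of a paired ERP contrast.

    Parameters
    ----------
    evoked
        Group :class:`EvokedSet` (both conditions per subject).
    window
        Endpoint-inclusive analysis window in ms (e.g. ``(0, 300)`` for the
        P200 search, ``(300, 1400)`` for the LPC search).
    adjacency
        Electrode :class:`AdjacencyGraph`; built from the evoked montage
        with the 45 mm rule when omitted.
    tail
        ``"greater"`` tests JOL minus no-JOL > 0 (the ERP direction).
    cluster_alpha
        Pointwise cluster-forming threshold.
    """

    def __init__(self, evoked: EvokedSet, window: tuple[float, float],
                 adjacency: AdjacencyGraph | None = None,
                 tail: str = "greater", cluster_alpha: float = 0.05):
        if adjacency is None:
            adjacency = build_adjacency(evoked.montage)
        if adjacency.labels != evoked.montage.labels:
            raise ValueError("adjacency labels do not match evoked montage")
        self.evoked = evoked
        self.window = tuple(window)
        self.adjacency = adjacency
        self.tail = tail
        self.cluster_alpha = cluster_alpha

    def fit(self, n_permutations: int = 5000, seed: int | None = None,
            batch_size: int = 200) -> ClusterTestResult:
        """Run the permutation test.

        ``seed`` is required for a reproducible null distribution; fewer
        than 100 permutations triggers a warning.
        """
        import warnings

        if n_permutations < 100:
            warnings.warn("fewer than 100 permutations: p-values are coarse",
                          stacklevel=2)
        if seed is None:
            warnings.warn("no seed given: permutation null is irreproducible",
                          stacklevel=2)
        rng = np.random.default_rng(seed)

        ev = self.evoked
        idx = window_to_samples(ev.time, *self.window)
        diffs = difference_wave(ev)[:, :, idx.start:idx.stop]
        n_subj, n_ch, n_sp = diffs.shape
        df = n_subj - 1

        t_map, p_map = pointwise_paired_t(ev, self.window, tail=self.tail)
        clusters = form_clusters(
            t_map, p_map, self.adjacency, self.cluster_alpha, self.tail,
            sample_offset=idx.start, step_ms=ev.time.step_ms,
            t_start_window_ms=ev.time.t_start_ms + idx.start * ev.time.step_ms)

        # orient so that "interesting" sums are positive
        sign = -1.0 if self.tail == "less" else 1.0
        adj_pairs = self.adjacency.pairs()
        if self.tail == "two":
            t_thresh = stats.t.ppf(1 - self.cluster_alpha / 2, df)
        else:
            t_thresh = stats.t.ppf(1 - self.cluster_alpha, df)

        X = diffs.reshape(n_subj, -1)
        ss = (X ** 2).sum(axis=0)  # invariant under per-subject sign flips
        null = np.empty(n_permutations)
        done = 0
        while done < n_permutations:
            b = min(batch_size, n_permutations - done)
            signs = rng.choice([-1.0, 1.0], size=(b, n_subj))
            means = signs @ X / n_subj
            with np.errstate(divide="ignore", invalid="ignore"):
                t_perm = means / np.sqrt(
                    np.maximum(ss - n_subj * means ** 2, 0.0)
                    / (df * n_subj))
            t_perm[~np.isfinite(t_perm)] = 0.0
            for k in range(b):
                tm = (sign * t_perm[k]).reshape(n_ch, n_sp)
                if self.tail == "two":
                    supra = np.abs(tm) > t_thresh
                else:
                    supra = tm > t_thresh
                if not supra.any():
                    null[done + k] = 0.0
                    continue
                _, _, sums = _component_sums(tm, supra, adj_pairs)
                if self.tail == "two":
                    null[done + k] = np.abs(sums).max()
                else:
                    null[done + k] = sums.max()
            done += b

        for c in clusters:
            obs = abs(c.t_sum) if self.tail == "two" else sign * c.t_sum
            # tolerance so permutations tying the observed statistic (e.g. the
            # identity sign pattern) count as >= despite round-off
            tol = 1e-9 * max(1.0, abs(obs))
            c.p_rand = float((1 + np.sum(null >= obs - tol))
                             / (1 + n_permutations))
        return ClusterTestResult(clusters, null, n_permutations, self.tail,
                                 self.cluster_alpha, self.window, t_map, p_map)
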