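"""Two-step time-frequency cluster inference.

Step 1 tests the electrode-averaged TSE maps: per time-frequency bin a
one-tailed-left paired t (power decreases under JOL), clusters by
4-connectivity on the bin grid, max-cluster-sum permutation null from
per-subject condition swaps.  Step 2 takes each significant cluster's
bounding box (maximum time range x maximum frequency range), averages the
per-electrode TSE over that rectangle, and reports an uncorrected paired t
per electrode — no second cluster correction, to avoid circularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .tfr import TSEMap

__all__ = [
    "TFCluster",
    "TFClusterResult",
    "TimeFrequencyClusterTest",
    "stack_tse",
    "electrode_average",
    "spatial_followup",
    "cluster_power_mediator",
]

_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity


def stack_tse(tse_maps: list[TSEMap]) -> tuple[list[str], np.ndarray, TSEMap]:
    """Stack per-subject TSE maps: (subjects, 2, channels, freqs, bins)."""
    if not tse_maps:
        raise ValueError("no TSE maps given")
    first = tse_maps[0]
    for m in tse_maps:
        if (m.channel_labels != first.channel_labels
                or not np.array_equal(m.freqs, first.freqs)
                or not np.array_equal(m.bin_starts_ms, first.bin_starts_ms)):
            raise ValueError("TSE maps have mismatched grids")
    subjects = [m.subject_id for m in tse_maps]
    return subjects, np.stack([m.tse for m in tse_maps]), first


def electrode_average(stacked: np.ndarray) -> np.ndarray:
    """Average the channel axis: (subjects, 2, freqs, bins)."""
    return stacked.mean(axis=2)


@dataclass
class TFCluster:
    """Connected supra-threshold time-frequency bins."""

    points: np.ndarray           # (k, 2) of (freq index, bin index) in the window
    t_sum: float
    freqs: np.ndarray            # full analysis frequency axis (Hz)
    bin_starts_ms: np.ndarray    # full analysis bin axis
    bin_ms: float
    p_rand: float | None = None

    @property
    def freq_range_hz(self) -> tuple[float, float]:
        f = self.points[:, 0]
        return float(self.freqs[f.min()]), float(self.freqs[f.max()])

    @property
    def time_range_ms(self) -> tuple[float, float]:
        b = self.points[:, 1]
        return (float(self.bin_starts_ms[b.min()]),
                float(self.bin_starts_ms[b.max()] + self.bin_ms))

    @property
    def bounding_box(self) -> tuple[slice, slice]:
        """(freq slice, bin slice) of the maximum time x frequency rectangle."""
        f, b = self.points[:, 0], self.points[:, 1]
        return (slice(f.min(), f.max() + 1), slice(b.min(), b.max() + 1))


def _grid_cluster_sums(t_map: np.ndarray, supra: np.ndarray):
    labels, n = ndimage.label(supra, structure=_STRUCTURE)
    if n == 0:
        return labels, np.empty(0)
    sums = ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1))
    return labels, sums


@dataclass
class TFClusterResult:
    clusters: list[TFCluster]
    null_max_sums: np.ndarray
    n_permutations: int
    tail: str
    cluster_alpha: float
    t_map: np.ndarray
    freqs: np.ndarray
    bin_starts_ms: np.ndarray

    def significant(self, alpha: float = 0.05) -> list[TFCluster]:
        return [c for c in self.clusters if c.p_rand is not None and c.p_rand < alpha]

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, c in enumerate(self.clusters):
            (f_lo, f_hi), (t_lo, t_hi) = c.freq_range_hz, c.time_range_ms
            rows.append(dict(cluster=k, n_bins=len(c.points), t_sum=c.t_sum,
                             p_rand=c.p_rand, t_lo_ms=t_lo, t_hi_ms=t_hi,
                             f_lo_hz=f_lo, f_hi_hz=f_hi))
        return pd.DataFrame(rows, columns=["cluster", "n_bins", "t_sum", "p_rand",
                                           "t_lo_ms", "t_hi_ms", "f_lo_hz", "f_hi_hz"])


class TimeFrequencyClusterTest:
    """Non-spatial cluster permutation test on electrode-averaged TSE maps.

    Parameters
    ----------
    tse_maps
        Per-subject :class:`TSEMap` objects on a common grid.
    window, freq_range
        Analysis limits in ms (bin start labels, inclusive) and Hz.
    tail
        ``"less"`` (default) tests JOL minus no-JOL < 0: stronger power
        decrease under JOL.
    """

    def __init__(self, tse_maps: list[TSEMap], window: tuple[float, float] = (0.0, 1400.0),
                 freq_range: tuple[float, float] = (2.0, 30.0),
                 tail: str = "less", cluster_alpha: float = 0.05):
        subjects, stacked, ref = stack_tse(tse_maps)
        if len(subjects) < 2:
            raise ValueError("need at least 2 subjects")
        self.subjects = subjects
        self._f_sel = np.flatnonzero((ref.freqs >= freq_range[0] - 1e-9)
                                     & (ref.freqs <= freq_range[1] + 1e-9))
        self._b_sel = np.flatnonzero((ref.bin_starts_ms >= window[0] - 1e-9)
                                     & (ref.bin_starts_ms <= window[1] + 1e-9))
        avg = electrode_average(stacked)
        diff = avg[:, 0] - avg[:, 1]  # JOL minus no-JOL
        self.diffs = diff[:, self._f_sel][:, :, self._b_sel]
        self.freqs = ref.freqs[self._f_sel]
        self.bin_starts_ms = ref.bin_starts_ms[self._b_sel]
        self.bin_ms = ref.bin_ms
        self.tail = tail
        self.cluster_alpha = cluster_alpha

    def fit(self, n_permutations: int = 5000, seed: int | None = None) -> TFClusterResult:
        if n_permutations < 100:
            warnings.warn("fewer than 100 permutations: p-values are coarse",
                          stacklevel=2)
        rng = np.random.default_rng(seed)
        X = self.diffs
        n_subj = X.shape[0]
        df = n_subj - 1
        sign = -1.0 if self.tail == "less" else 1.0
        t_thresh = stats.t.ppf(1 - self.cluster_alpha, df)

        def t_of(d):
            m = d.mean(axis=0)
            v = d.var(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = m / np.sqrt(v / n_subj)
            t[v == 0] = 0.0
            return t

        t_map = t_of(X)
        oriented = sign * t_map
        labels, sums = _grid_cluster_sums(oriented, oriented > t_thresh)
        clusters = []
        for lab in range(1, labels.max() + 1):
            pts = np.argwhere(labels == lab)
            clusters.append(TFCluster(pts, float(sign * sums[lab - 1]),
                                      self.freqs, self.bin_starts_ms, self.bin_ms))
        clusters.sort(key=lambda c: abs(c.t_sum), reverse=True)

        null = np.empty(n_permutations)
        for k in range(n_permutations):
            flips = rng.choice([-1.0, 1.0], size=(n_subj, 1, 1))
            tp = sign * t_of(X * flips)
            _, s = _grid_cluster_sums(tp, tp > t_thresh)
            null[k] = s.max() if s.size else 0.0
        for c in clusters:
            obs = sign * c.t_sum
            tol = 1e-9 * max(1.0, abs(obs))  # count round-off ties as >=
            c.p_rand = float((1 + np.sum(null >= obs - tol))
                             / (1 + n_permutations))
        return TFClusterResult(clusters, null, n_permutations, self.tail,
                               self.cluster_alpha, t_map, self.freqs,
                               self.bin_starts_ms)


def _box_means(stacked: np.ndarray, f_sel: np.ndarray, b_sel: np.ndarray,
               cluster: TFCluster) -> np.ndarray:
    """Per subject x condition x electrode mean over the cluster bounding box."""
    fsl, bsl = cluster.bounding_box
    f_idx = f_sel[fsl]
    b_idx = b_sel[bsl]
    sub = stacked[:, :, :, f_idx][:, :, :, :, b_idx]
    return sub.mean(axis=(3, 4))


def spatial_followup(tse_maps: list[TSEMap], cluster: TFCluster,
                     window: tuple[float, float] = (0.0, 1400.0),
                     freq_range: tuple[float, float] = (2.0, 30.0),
                     tail: str = "less", alpha: float = 0.05) -> pd.DataFrame:
    """Per-electrode paired t over the cluster's bounding-box average.

    Returns a topography table (electrode, mean_diff, t, p, significant);
    p-values are uncorrected by design.
    """
    subjects, stacked, ref = stack_tse(tse_maps)
    f_sel = np.flatnonzero((ref.freqs >= freq_range[0] - 1e-9)
                           & (ref.freqs <= freq_range[1] + 1e-9))
    b_sel = np.flatnonzero((ref.bin_starts_ms >= window[0] - 1e-9)
                           & (ref.bin_starts_ms <= window[1] + 1e-9))
    vals = _box_means(stacked, f_sel, b_sel, cluster)  # (S, 2, C)
    diff = vals[:, 0] - vals[:, 1]
    n = diff.shape[0]
    m = diff.mean(axis=0)
    v = diff.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(v / n)
    t[v == 0] = 0.0
    if tail == "less":
        p = stats.t.cdf(t, n - 1)
    elif tail == "greater":
        p = stats.t.sf(t, n - 1)
    else:
        raise ValueError("tail must be 'less' or 'greater'")
    p = np.where(v == 0, 1.0, p)
    return pd.DataFrame(dict(electrode=list(ref.channel_labels), mean_diff=m,
                             t=t, p=p, significant=p < alpha))


def cluster_power_mediator(tse_maps: list[TSEMap], cluster: TFCluster,
                           electrodes: list[str],
                           window: tuple[float, float] = (0.0, 1400.0),
                           freq_range: tuple[float, float] = (2.0, 30.0)) -> pd.DataFrame:
    """Band-power mediator: mean TSE over significant electrodes x bounding box.

    Returns rows (subject, condition, value) for the mediation models.
    """
    if not electrodes:
        raise ValueError("no electrodes given")
    subjects, stacked, ref = stack_tse(tse_maps)
    ch_idx = [ref.channel_labels.index(e) for e in electrodes]
    f_sel = np.flatnonzero((ref.freqs >= freq_range[0] - 1e-9)
                           & (ref.freqs <= freq_range[1] + 1e-9))
    b_sel = np.flatnonzero((ref.bin_starts_ms >= window[0] - 1e-9)
                           & (ref.bin_starts_ms <= window[1] + 1e-9))
    vals = _box_means(stacked[:, :, ch_idx], f_sel, b_sel, cluster)  # (S, 2, k)
    vals = vals.mean(axis=2)
    rows = []
    for si, subject in enumerate(subjects):
        for ci, cond in enumerate(ref.conditions):
            rows.append(dict(subject=subject, condition=cond, value=vals[si, ci]))
    return pd.DataFrame(rows)
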