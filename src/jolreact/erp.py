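"""Evoked (ERP) averaging, difference waves and cluster-amplitude mediators."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epochs import CONDITIONS, EpochsSet, EvokedSet, baseline_correct

__all__ = [
    "condition_evoked",
    "combine_evoked",
    "difference_wave",
    "evoked_to_frame",
    "extract_cluster_amplitude",
]


def condition_evoked(epochs: EpochsSet,
                     baseline: tuple[float, float] | None = (-300.0, 0.0)) -> EvokedSet:
    """Per-condition trial average for one subject, then baseline correction.

    Trials are equally weighted.  Pass ``baseline=None`` to skip correction
    (e.g. when the average is used for single-trial evoked subtraction).
    """
    waves = []
    for cond in CONDITIONS:
        mask = epochs.condition_mask(cond)
        if not mask.any():
            raise ValueError(f"no trials for condition {cond!r}")
        waves.append(epochs.data[mask].mean(axis=0))
    evoked = EvokedSet([epochs.subject_id], np.asarray(waves)[None, ...],
                       epochs.time, epochs.montage)
    if baseline is not None:
        evoked = baseline_correct(evoked, baseline)
    return evoked


def combine_evoked(evokeds: list[EvokedSet]) -> EvokedSet:
    """Stack per-subject EvokedSets into one group container."""
    if not evokeds:
        raise ValueError("no evoked sets given")
    first = evokeds[0]
    subjects: list[str] = []
    data = []
    for ev in evokeds:
        if ev.time != first.time or ev.montage.labels != first.montage.labels:
            raise ValueError("evoked sets have mismatched time axis or montage")
        if ev.baseline != first.baseline:
            raise ValueError("evoked sets have mismatched baseline status")
        subjects.extend(ev.subjects)
        data.append(ev.data)
    if len(subjects) != len(set(subjects)):
        raise ValueError("duplicate subjects across evoked sets")
    return EvokedSet(subjects, np.concatenate(data, axis=0), first.time,
                     first.montage, baseline=first.baseline)


def difference_wave(evoked: EvokedSet, a: str = "JOL", b: str = "no-JOL") -> np.ndarray:
    """Per-subject condition difference a - b: (n_subjects, channels, samples)."""
    conds = list(evoked.conditions)
    if a not in conds or b not in conds:
        raise ValueError(f"conditions must be among {conds}")
    return evoked.data[:, conds.index(a)] - evoked.data[:, conds.index(b)]


def evoked_to_frame(evoked: EvokedSet) -> pd.DataFrame:
    """Long-format export: subject, condition, channel, time_ms, microvolts."""
    times = evoked.time.times
    records = []
    for si, subject in enumerate(evoked.subjects):
        for ci, cond in enumerate(evoked.conditions):
            for chi, label in enumerate(evoked.montage.labels):
                records.append(pd.DataFrame({
                    "subject": subject, "condition": cond, "channel": label,
                    "time_ms": times, "microvolts": evoked.data[si, ci, chi],
                }))
    return pd.concat(records, ignore_index=True)


def extract_cluster_amplitude(evoked: EvokedSet, cluster,
                              use_mask: bool = False) -> pd.DataFrame:
    """Mean ERP amplitude over a significant cluster, per subject x condition.

    By default averages over the rectangular region spanned by the
    cluster's significant electrodes and its full time window, matching how
    the cluster-mean mediator is defined for the mediation models.  With
    ``use_mask=True`` only the exact (electrode, sample) member points are
    averaged.

    ``cluster`` is a :class:`jolreact.cluster.SpatioTemporalCluster`.
    """
    if len(cluster.points) == 0:
        raise ValueError("empty cluster")
    ch_idx = np.unique(cluster.points[:, 0])
    labels = [cluster.channel_labels[i] for i in ch_idx]
    ch_rows = np.array([evoked.montage.index(l) for l in labels])

    rows = []
    if use_mask:
        samp_abs = cluster.sample_offset + cluster.points[:, 1]
        mont_rows = np.array([evoked.montage.index(cluster.channel_labels[c])
                              for c in cluster.points[:, 0]])
        for si, subject in enumerate(evoked.subjects):
            for ci, cond in enumerate(evoked.conditions):
                val = evoked.data[si, ci][mont_rows, samp_abs].mean()
                rows.append(dict(subject=subject, condition=cond, value=val))
    else:
        lo = cluster.sample_offset + cluster.points[:, 1].min()
        hi = cluster.sample_offset + cluster.points[:, 1].max()
        for si, subject in enumerate(evoked.subjects):
            for ci, cond in enumerate(evoked.conditions):
                val = evoked.data[si, ci][ch_rows, lo:hi + 1].mean()
                rows.append(dict(subject=subject, condition=cond, value=val))
    return pd.DataFrame(rows)
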