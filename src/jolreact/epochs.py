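"""Epoched EEG containers, time-axis bookkeeping and baseline correction.

Conventions used throughout the package:

* time is in milliseconds relative to stimulus onset; sample ``k`` of an
  epoch occurs at ``t_start + k * 1000 / sfreq`` ms;
* window selection ``[t_lo, t_hi]`` is endpoint-inclusive, so a 0-300 ms
  window at 500 Hz selects 151 samples;
* potentials are in microvolts;
* the two experimental conditions are labelled ``"JOL"`` and ``"no-JOL"``
  and coded 0 and 1 respectively wherever a numeric code is needed.

Epochs are stored on disk as a directory containing a JSON sidecar
(``epochs.json``), a raw little-endian float32 array (``epochs.dat``,
dimension order trial x channel x sample) and two TSV tables
(``trials.tsv``, ``channels.tsv``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .montage import Montage

__all__ = [
    "CONDITIONS",
    "CONDITION_CODE",
    "TimeAxis",
    "EpochsSet",
    "EvokedSet",
    "window_to_samples",
    "baseline_correct",
    "read_epochs",
    "write_epochs",
]

CONDITIONS: tuple[str, str] = ("JOL", "no-JOL")
#: numeric coding used in mediation models: JOL = 0, no-JOL = 1
CONDITION_CODE: dict[str, int] = {"JOL": 0, "no-JOL": 1}

_TIME_TOL_MS = 1e-6


@dataclass(frozen=True)
class TimeAxis:
    """Uniform sampling grid: ``sfreq`` Hz starting at ``t_start_ms``."""

    sfreq: float
    t_start_ms: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.sfreq <= 0 or self.n_samples < 1:
            raise ValueError("sfreq must be positive and n_samples >= 1")

    @property
    def step_ms(self) -> float:
        return 1000.0 / self.sfreq

    @property
    def t_end_ms(self) -> float:
        return self.t_start_ms + (self.n_samples - 1) * self.step_ms

    @property
    def times(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.n_samples) * self.step_ms


def window_to_samples(time: TimeAxis, t_lo: float, t_hi: float) -> range:
    """Sample index range for the endpoint-inclusive window [t_lo, t_hi] ms."""
    if t_lo > t_hi:
        raise ValueError(f"t_lo ({t_lo}) must not exceed t_hi ({t_hi})")
    if t_lo < time.t_start_ms - _TIME_TOL_MS or t_hi > time.t_end_ms + _TIME_TOL_MS:
        raise ValueError(
            f"window [{t_lo}, {t_hi}] ms outside epoch "
            f"[{time.t_start_ms}, {time.t_end_ms}] ms"
        )
    first = int(np.ceil((t_lo - time.t_start_ms) / time.step_ms - _TIME_TOL_MS))
    last = int(np.floor((t_hi - time.t_start_ms) / time.step_ms + _TIME_TOL_MS))
    if last < first:
        raise ValueError(f"window [{t_lo}, {t_hi}] ms contains no sample")
    return range(first, last + 1)


@dataclass
class EpochsSet:
    """Single-subject epoched EEG: trials x channels x samples, microvolts."""

    subject_id: str
    data: np.ndarray
    conditions: np.ndarray  # (n_trials,) of str, values in CONDITIONS
    time: TimeAxis
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("epochs data must be trials x channels x samples")
        n_tr, n_ch, n_sp = self.data.shape
        if n_ch != self.montage.n_channels:
            raise ValueError(
                f"{n_ch} channels in data but montage has {self.montage.n_channels}"
            )
        if n_sp != self.time.n_samples:
            raise ValueError("sample count does not match time axis")
        if len(self.conditions) != n_tr:
            raise ValueError("one condition label per trial required")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        if set(self.conditions) != set(CONDITIONS):
            raise ValueError("both conditions must be present")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epochs contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def condition_mask(self, condition: str) -> np.ndarray:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return np.array([c == condition for c in self.conditions])


@dataclass
class EvokedSet:
    """Per subject x condition mean waveforms: (n_subjects, 2, channels, samples).

    Condition axis follows :data:`CONDITIONS` order (JOL first).
    """

    subjects: list[str]
    data: np.ndarray
    time: TimeAxis
    montage: Montage
    baseline: tuple[float, float] | None = None
    conditions: tuple[str, str] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (len(self.subjects), 2, self.montage.n_channels, self.time.n_samples)
        if self.data.shape != expected:
            raise ValueError(f"evoked data shape {self.data.shape}, expected {expected}")
        if tuple(self.conditions) != CONDITIONS:
            raise ValueError(f"condition axis must be {CONDITIONS}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def baseline_corrected(self) -> bool:
        return self.baseline is not None


def baseline_correct(obj, baseline: tuple[float, float] = (-300.0, 0.0)):
    """Subtract the per-trial (or per-waveform), per-channel baseline mean.

    Works on :class:`EpochsSet` and :class:`EvokedSet`; returns a new object
    of the same type.  After correction the mean over the baseline window is
    zero for every trial/waveform and channel.
    """
    idx = window_to_samples(obj.time, *baseline)
    sl = slice(idx.start, idx.stop)
    corrected = obj.data - obj.data[..., sl].mean(axis=-1, keepdims=True)
    if isinstance(obj, EvokedSet):
        return replace(obj, data=corrected, baseline=tuple(baseline))
    return replace(obj, data=corrected)


# ---------------------------------------------------------------------------
# On-disk container


def write_epochs(epochs: EpochsSet, path: str | Path) -> None:
    """Write an epochs container directory (JSON + raw float32 + TSV)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n_tr, n_ch, n_sp = epochs.data.shape
    meta = {
        "subject_id": epochs.subject_id,
        "sfreq_hz": epochs.time.sfreq,
        "t_start_ms": epochs.time.t_start_ms,
        "n_trials": n_tr,
        "n_channels": n_ch,
        "n_samples": n_sp,
        "dtype": "float32-le",
        "dim_order": "trial,channel,sample",
    }
    (path / "epochs.json").write_text(json.dumps(meta, indent=1))
    epochs.data.astype("<f4").tofile(path / "epochs.dat")
    trials = "\n".join(
        f"{i}\t{c}" for i, c in enumerate(epochs.conditions)
    )
    (path / "trials.tsv").write_text("trial_index\tcondition\n" + trials + "\n")
    chans = "\n".join(f"{i}\t{l}" for i, l in enumerate(epochs.montage.labels))
    (path / "channels.tsv").write_text("index\tlabel\n" + chans + "\n")


def read_epochs(path: str | Path, montage: Montage) -> EpochsSet:
    """Read an epochs container written by :func:`write_epochs`.

    The montage supplies electrode positions; its labels must match the
    container's ``channels.tsv`` in order.
    """
    path = Path(path)
    meta = json.loads((path / "epochs.json").read_text())
    shape = (meta["n_trials"], meta["n_channels"], meta["n_samples"])
    data = np.fromfile(path / "epochs.dat", dtype="<f4")
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"epochs.dat has {data.size} values, sidecar promises {np.prod(shape)}"
        )
    data = data.reshape(shape).astype(np.float64)

    chan_lines = (path / "channels.tsv").read_text().splitlines()[1:]
    labels = tuple(line.split("\t")[1] for line in chan_lines if line.strip())
    if labels != montage.labels:
        raise ValueError("channel labels in container do not match montage")

    trial_lines = (path / "trials.tsv").read_text().splitlines()[1:]
    conditions = [line.split("\t")[1] for line in trial_lines if line.strip()]
    time = TimeAxis(meta["sfreq_hz"], meta["t_start_ms"], meta["n_samples"])
    return EpochsSet(meta["subject_id"], data, np.array(conditions, dtype=object), time, montage)
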