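"""Synthetic multi-subject EEG and recognition behavior with known ground truth.

The generator emulates the statistical structure of a two-condition
(JOL vs. no-JOL) word-list study: 27 subjects, two 100-word study lists
per condition, a 400-old/200-new recognition test on a 4-point scale,
and 40-channel epoched EEG (-1000..2000 ms at 500 Hz) containing

* 1/f background noise, independent per channel;
* phase-locked evoked components — a fronto-central P200-like bump and a
  sustained centro-parietal LPC-like deflection — whose amplitudes are
  larger under JOL;
* induced alpha (10 Hz) and beta (20 Hz) oscillations with random phase
  per trial whose envelope drops after stimulus onset (ERD), more deeply
  under JOL.

A latent per-subject engagement factor ``u`` scales the EEG condition
effects and, with weight ``coupling``, the subject's behavioral d'
advantage, so a nonzero true indirect (mediated) effect exists whenever
``coupling > 0``.  All outputs are reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import score_recognition
from .epochs import CONDITIONS, EpochsSet, TimeAxis
from .montage import Montage, standard_montage_40

__all__ = [
    "EvokedComponentSpec",
    "InducedComponentSpec",
    "BehaviorParams",
    "SimulationConfig",
    "GroundTruth",
    "StudyData",
    "draw_subject_truth",
    "simulate_behavior",
    "simulate_epochs",
    "simulate_mediator_table",
    "simulate_study",
]


@dataclass(frozen=True)
class EvokedComponentSpec:
    """A phase-locked Gaussian-envelope deflection."""

    name: str
    center_ms: float
    fwhm_ms: float
    peak_electrode: str
    spatial_sigma_mm: float
    amplitudes_uv: dict  # condition -> peak µV

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes_uv.values()):
            raise ValueError("evoked amplitudes must be non-negative")


@dataclass(frozen=True)
class InducedComponentSpec:
    """A narrow-band oscillation with random phase and post-stimulus ERD.

    ``post_ratio`` gives the post-stimulus amplitude as a fraction of the
    pre-stimulus amplitude per condition (1 = no change, < 1 = ERD); the
    envelope ramps linearly over ``ramp_ms`` at onset and offset.
    """

    name: str
    freq_hz: float
    baseline_amp_uv: float
    post_ratio: dict  # condition -> ratio in (0, 2]
    onset_ms: float
    offset_ms: float
    peak_electrode: str
    spatial_sigma_mm: float
    ramp_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.baseline_amp_uv < 0:
            raise ValueError("baseline amplitude must be non-negative")
        if any(not 0 < r <= 2 for r in self.post_ratio.values()):
            raise ValueError("post-stimulus ratios must lie in (0, 2]")
        if self.onset_ms >= self.offset_ms:
            raise ValueError("onset must precede offset")


@dataclass(frozen=True)
class BehaviorParams:
    """Subject-level recognition model.

    Per-condition mean d' defaults are the study values (1.400 JOL, 0.832
    no-JOL).  A subject's no-JOL d' is the condition mean plus a shared
    memory-ability deviation (SD ``d_base_sd``); the JOL advantage is
    ``diff = mean difference + coupling * u + noise(diff_sd)`` where ``u``
    is the latent engagement factor shared with the EEG effects.
    """

    d_mean: dict = field(default_factory=lambda: {"JOL": 1.400, "no-JOL": 0.832})
    d_base_sd: float = 0.60
    diff_sd: float = 0.25
    criterion_mean: float = 0.20
    criterion_sd: float = 0.20


def _default_evoked() -> tuple:
    return (
        EvokedComponentSpec("P200", center_ms=205.0, fwhm_ms=90.0,
                            peak_electrode="FC3", spatial_sigma_mm=45.0,
                            amplitudes_uv={"JOL": 3.0, "no-JOL": 1.8}),
        EvokedComponentSpec("LPC", center_ms=705.0, fwhm_ms=560.0,
                            peak_electrode="CP1", spatial_sigma_mm=60.0,
                            amplitudes_uv={"JOL": 4.0, "no-JOL": 2.8}),
    )


def _default_induced() -> tuple:
    return (
        InducedComponentSpec("alpha", freq_hz=10.0, baseline_amp_uv=5.0,
                             post_ratio={"JOL": 0.5, "no-JOL": 0.72},
                             onset_ms=500.0, offset_ms=1450.0,
                             peak_electrode="C3", spatial_sigma_mm=70.0),
        InducedComponentSpec("beta", freq_hz=20.0, baseline_amp_uv=2.5,
                             post_ratio={"JOL": 0.6, "no-JOL": 0.8},
                             onset_ms=550.0, offset_ms=1400.0,
                             peak_electrode="C4", spatial_sigma_mm=55.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Design constants and effect sizes of the synthetic study."""

    n_subjects: int = 27
    trials_per_condition: int = 200   # two 100-word lists per condition
    n_new_test: int = 200
    #: EEG epochs kept per condition (None = all studied trials); fewer than
    #: trials_per_condition emulates epoch loss to artifact rejection
    eeg_trials_per_condition: int | None = None
    sfreq: float = 500.0
    t_start_ms: float = -1000.0
    n_samples: int = 1500             # -1000 .. +1998 ms
    montage: Montage | None = None    # default: shipped 40-channel montage
    noise_exponent: float = 1.0
    noise_rms_uv: float = 10.0
    evoked: tuple = field(default_factory=_default_evoked)
    induced: tuple = field(default_factory=_default_induced)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    coupling: float = 0.25            # weight of u on the d' difference
    eeg_scale_sd: float = 0.40        # SD of the per-subject EEG effect scale
    mediator_noise: float = 0.35      # measurement noise of subject-level mediators
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_condition < 1 or self.n_new_test < 1:
            raise ValueError("counts must be positive")
        if self.montage is None:
            object.__setattr__(self, "montage", standard_montage_40())

    @property
    def n_old_test(self) -> int:
        return 2 * self.trials_per_condition

    @property
    def time(self) -> TimeAxis:
        return TimeAxis(self.sfreq, self.t_start_ms, self.n_samples)


@dataclass
class GroundTruth:
    """Latent per-subject parameters and the coupling model's implied paths."""

    subjects: pd.DataFrame  # subject, u, eeg_scale, d_jol, d_nojol, diff, criterion
    coupling: float
    eeg_scale_sd: float
    implied_paths: dict     # true a (mediator scale) and implied b where defined

    def to_json_dict(self) -> dict:
        return dict(subjects=self.subjects.to_dict(orient="list"),
                    coupling=self.coupling, eeg_scale_sd=self.eeg_scale_sd,
                    implied_paths=self.implied_paths)


@dataclass
class StudyData:
    config: SimulationConfig
    truth: GroundTruth
    epochs: list          # per-subject EpochsSet
    behavior_trials: pd.DataFrame
    behavior_table: pd.DataFrame


def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def draw_subject_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw the latent subject parameters that couple EEG and behavior."""
    beh = config.behavior
    n = config.n_subjects
    u = rng.standard_normal(n)
    base = rng.normal(0.0, beh.d_base_sd, size=n)
    mean_diff = beh.d_mean["JOL"] - beh.d_mean["no-JOL"]
    diff = mean_diff + config.coupling * u + rng.normal(0.0, beh.diff_sd, size=n)
    d_nojol = beh.d_mean["no-JOL"] + base
    d_jol = d_nojol + diff
    crit = rng.normal(beh.criterion_mean, beh.criterion_sd, size=n)
    eeg_scale = np.clip(1.0 + config.eeg_scale_sd * u, 0.1, None)

    # implied paths for the default (P200-amplitude) mediator, raw scale:
    # a = E[M | no-JOL] - E[M | JOL] = -(condition amplitude difference)
    p200 = config.evoked[0]
    delta_m = p200.amplitudes_uv["JOL"] - p200.amplitudes_uv["no-JOL"]
    if delta_m > 0 and config.eeg_scale_sd > 0:
        implied_b = config.coupling / (delta_m * config.eeg_scale_sd)
    else:
        implied_b = 0.0
    paths = dict(a=-delta_m, b=implied_b, indirect=-delta_m * implied_b)

    subjects = pd.DataFrame(dict(
        subject=_subject_ids(n), u=u, eeg_scale=eeg_scale,
        d_jol=d_jol, d_nojol=d_nojol, diff=diff, criterion=crit))
    return GroundTruth(subjects, config.coupling, config.eeg_scale_sd, paths)


# ---------------------------------------------------------------------------
# Behavior


def simulate_behavior(config: SimulationConfig, rng: np.random.Generator,
                      truth: GroundTruth | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the recognition test; returns (trials, scored table, truth).

    Old-item strengths are Normal(d'_i,cond, 1), new-item strengths
    Normal(0, 1); the 4-point response uses thresholds at lambda - 0.5,
    lambda, lambda + 0.5 where lambda = mean d'_i / 2 + criterion_i, so a
    response of 3 or 4 ("old") corresponds to strength above lambda and
    the recovered d' is unbiased for the generating d' at any criterion.
    New items are studied in neither condition and are shared between the
    two conditions' false-alarm counts (condition field "new").
    """
    if truth is None:
        truth = draw_subject_truth(config, rng)
    rows = []
    for rec in truth.subjects.itertuples():
        lam = (rec.d_jol + rec.d_nojol) / 4.0 + rec.criterion
        thresholds = np.array([lam - 0.5, lam, lam + 0.5])
        for cond, d in (("JOL", rec.d_jol), ("no-JOL", rec.d_nojol)):
            strength = rng.normal(d, 1.0, size=config.trials_per_condition)
            resp = np.searchsorted(thresholds, strength) + 1
            rows.append(pd.DataFrame(dict(
                subject=rec.subject, condition=cond, item_status="old",
                response=resp)))
        strength = rng.normal(0.0, 1.0, size=config.n_new_test)
        resp = np.searchsorted(thresholds, strength) + 1
        rows.append(pd.DataFrame(dict(
            subject=rec.subject, condition="new", item_status="new",
            response=resp)))
    trials = pd.concat(rows, ignore_index=True)
    table = score_recognition(trials)
    return trials, table, truth


# ---------------------------------------------------------------------------
# EEG


def _one_over_f_noise(shape: tuple, exponent: float, rms: float, sfreq: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise along the last axis, target RMS."""
    if rms == 0.0:
        return np.zeros(shape)
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / sfreq)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n, axis=-1)
    scale = shaped.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return shaped / scale * rms


def _spatial_map(montage: Montage, peak: str, sigma_mm: float) -> np.ndarray:
    d = np.linalg.norm(montage.positions - montage.positions[montage.index(peak)],
                       axis=1)
    return np.exp(-0.5 * (d / sigma_mm) ** 2)


def _erd_envelope(times_ms: np.ndarray, ratio: float, onset: float,
                  offset: float, ramp: float) -> np.ndarray:
    env = np.ones_like(times_ms)
    down = (times_ms > onset) & (times_ms < onset + ramp)
    env[down] = 1.0 + (ratio - 1.0) * (times_ms[down] - onset) / ramp
    flat = (times_ms >= onset + ramp) & (times_ms <= offset - ramp)
    env[flat] = ratio
    up = (times_ms > offset - ramp) & (times_ms < offset)
    env[up] = ratio + (1.0 - ratio) * (times_ms[up] - (offset - ramp)) / ramp
    return env


def simulate_epochs(config: SimulationConfig, subject: str,
                    rng: np.random.Generator,
                    eeg_scale: float = 1.0) -> EpochsSet:
    """Simulate one subject's epochs (trials x channels x samples, µV).

    ``eeg_scale`` multiplies the condition *difference* of every evoked
    amplitude and ERD depth (the subject's latent engagement scale); the
    no-JOL level is left at its configured value.
    """
    time = config.time
    t_ms = time.times
    t_s = t_ms / 1000.0
    montage = config.montage
    n_per = config.eeg_trials_per_condition or config.trials_per_condition
    n_tr = 2 * n_per
    conditions = np.array(
        [CONDITIONS[i] for i in rng.permutation(
            np.repeat([0, 1], n_per))], dtype=object)

    data = _one_over_f_noise((n_tr, montage.n_channels, time.n_samples),
                             config.noise_exponent, config.noise_rms_uv,
                             time.sfreq, rng)

    for spec in config.evoked:
        sigma = spec.fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        wave = np.exp(-0.5 * ((t_ms - spec.center_ms) / sigma) ** 2)
        smap = _spatial_map(montage, spec.peak_electrode, spec.spatial_sigma_mm)
        base = spec.amplitudes_uv["no-JOL"]
        delta = spec.amplitudes_uv["JOL"] - base
        for cond in CONDITIONS:
            amp = base + (delta * eeg_scale if cond == "JOL" else 0.0)
            if amp == 0.0:
                continue
            mask = conditions == cond
            data[mask] += amp * smap[None, :, None] * wave[None, None, :]

    for spec in config.induced:
        smap = _spatial_map(montage, spec.peak_electrode, spec.spatial_sigma_mm)
        for cond in CONDITIONS:
            if spec.baseline_amp_uv == 0.0:
                continue
            ratio = spec.post_ratio[cond]
            if cond == "JOL":
                base_ratio = spec.post_ratio["no-JOL"]
                ratio = base_ratio + (ratio - base_ratio) * eeg_scale
            ratio = float(np.clip(ratio, 0.05, 2.0))
            env = _erd_envelope(t_ms, ratio, spec.onset_ms, spec.offset_ms,
                                spec.ramp_ms)
            mask = np.flatnonzero(conditions == cond)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=mask.size)
            osc = np.cos(2.0 * np.pi * spec.freq_hz * t_s[None, :]
                         + phases[:, None]) * env[None, :]
            data[mask] += spec.baseline_amp_uv * smap[None, :, None] * osc[:, None, :]

    # store at float32 precision so the on-disk container round-trips bit-exactly
    data = data.astype(np.float32).astype(np.float64)
    return EpochsSet(subject, data, conditions, time, montage)


# ---------------------------------------------------------------------------
# Subject-level mediator shortcut and the full study


def simulate_mediator_table(config: SimulationConfig, rng: np.random.Generator,
                            truth: GroundTruth) -> pd.DataFrame:
    """Subject-level mediator values implied by the coupling model.

    Emulates the P200 cluster-amplitude mediator without simulating EEG:
    the JOL value exceeds the no-JOL value by the evoked amplitude
    difference scaled by the subject's engagement factor, plus measurement
    noise.  Rows: subject, condition, value.
    """
    p200 = config.evoked[0]
    base = p200.amplitudes_uv["no-JOL"]
    delta = p200.amplitudes_uv["JOL"] - base
    rows = []
    for rec in truth.subjects.itertuples():
        for cond in CONDITIONS:
            val = base + (delta * rec.eeg_scale if cond == "JOL" else 0.0)
            val += rng.normal(0.0, config.mediator_noise)
            rows.append(dict(subject=rec.subject, condition=cond, value=val))
    return pd.DataFrame(rows)


def simulate_study(config: SimulationConfig, seed: int | None = None) -> StudyData:
    """Full study: per-subject epochs, recognition behavior, ground truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = draw_subject_truth(config, rng)
    trials, table, _ = simulate_behavior(config, rng, truth)
    epochs = [
        simulate_epochs(config, rec.subject, rng, eeg_scale=rec.eeg_scale)
        for rec in truth.subjects.itertuples()
    ]
    return StudyData(config, truth, epochs, trials, table)
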