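"""Complex-demodulation time-frequency analysis and TSE (ERS/ERD) maps.

Power at frequency f is extracted by multiplying the signal with
``exp(-i 2 pi f t)`` and low-pass filtering with a Gaussian FIR kernel
whose squared-magnitude (power) impulse response has a configurable full
width at half maximum (default 78.8 ms).  Power is ``|2 y(t)|**2`` so a
stationary unit-amplitude sinusoid at f yields power 1.  Powers are then
smoothed across the frequency axis with a Gaussian of power FWHM 1.42 Hz,
averaged over trials per condition, and averaged into 50 ms x 1 Hz bins.

The temporal spectral evolution (TSE) expresses trial-averaged power as
percent change from the mean power of a pre-stimulus baseline interval:
negative values are event-related desynchronization (ERD), positive values
synchronization (ERS).  Evoked (phase-locked) activity is removed before
demodulation by subtracting each condition's mean waveform from its single
trials, so the TSE reflects induced activity only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .epochs import CONDITIONS, EpochsSet, EvokedSet, TimeAxis

__all__ = [
    "DemodParams",
    "read_tse",
    "write_tse",
    "TFRSet",
    "TSEMap",
    "subtract_evoked",
    "complex_demodulate",
    "tfr_transform",
    "tse_percent",
]


@dataclass(frozen=True)
class DemodParams:
    """Resolution and binning of the demodulation transform."""

    freqs: tuple = tuple(range(2, 31))  # Hz
    time_res_fwhm: float = 78.8         # ms, power FWHM of temporal smoothing
    freq_res_fwhm: float = 1.42         # Hz, power FWHM of frequency smoothing
    bin_ms: float = 50.0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.freqs):
            raise ValueError("analysis frequencies must be positive")
        if self.time_res_fwhm <= 0 or self.freq_res_fwhm <= 0 or self.bin_ms <= 0:
            raise ValueError("resolutions must be positive")


def subtract_evoked(epochs: EpochsSet, evoked: EvokedSet | None = None) -> EpochsSet:
    """Remove phase-locked activity: each trial minus its condition's mean.

    When ``evoked`` is omitted the condition means of ``epochs`` themselves
    are used, in which case residual trial means are exactly zero per
    condition, channel and sample.  A supplied ``evoked`` must be a
    single-subject, non-baseline-corrected average on the same grid.
    """
    if evoked is not None:
        if evoked.n_subjects != 1 or evoked.subjects[0] != epochs.subject_id:
            raise ValueError("evoked must contain exactly this subject")
        if evoked.time != epochs.time or evoked.montage.labels != epochs.montage.labels:
            raise ValueError("evoked grid does not match epochs")
        means = {c: evoked.data[0, k] for k, c in enumerate(evoked.conditions)}
    else:
        means = {c: epochs.data[epochs.condition_mask(c)].mean(axis=0)
                 for c in CONDITIONS}
    out = epochs.data.copy()
    for cond in CONDITIONS:
        mask = epochs.condition_mask(cond)
        out[mask] -= means[cond]
    return EpochsSet(epochs.subject_id, out, epochs.conditions, epochs.time,
                     epochs.montage)


def _gaussian_kernel(sigma_samples: float) -> np.ndarray:
    """Unit-sum Gaussian FIR kernel truncated at +-3 sigma."""
    half = max(1, int(np.ceil(3.0 * sigma_samples)))
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / sigma_samples) ** 2)
    return k / k.sum()


def _power_fwhm_to_sigma(fwhm: float) -> float:
    # power profile g(t)^2 of amplitude Gaussian g has FWHM = 2 sigma sqrt(ln 2)
    return fwhm / (2.0 * np.sqrt(np.log(2.0)))


def _iter_demodulated(x: np.ndarray, freqs, sfreq: float,
                      time_res_fwhm: float):
    """Yield band power per frequency, sharing one forward FFT.

    Uses the identity ``conv(x e_f, k) = e_f(t) conv(x, k e_f*)``: the
    signal spectrum is computed once and each frequency costs one spectral
    multiply and one inverse FFT with the modulated kernel.  Yields arrays
    of ``x.shape`` (one per frequency, in order).
    """
    from scipy import fft as sp_fft

    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    sigma = _power_fwhm_to_sigma(time_res_fwhm) / 1000.0 * sfreq  # samples
    kernel = _gaussian_kernel(sigma)
    m = kernel.size
    if m > n:
        raise ValueError("signal shorter than the smoothing kernel support")
    half = m // 2
    nfft = sp_fft.next_fast_len(n + m - 1)
    X = sp_fft.fft(x, nfft, axis=-1)
    # kernel mass inside the signal (edge renormalization), frequency-independent
    coverage = np.convolve(np.ones(n), kernel, mode="full")[half:half + n]
    u = np.arange(m) - half
    for f in freqs:
        if f >= sfreq / 2.0:
            raise ValueError(f"frequency {f} Hz at or above Nyquist ({sfreq / 2} Hz)")
        kf = kernel * np.exp(2j * np.pi * f * u / sfreq)
        Kf = sp_fft.fft(kf, nfft)
        y = sp_fft.ifft(X * Kf, axis=-1)[..., half:half + n]
        y /= coverage
        yield np.abs(2.0 * y) ** 2


def complex_demodulate(signal: np.ndarray, freq: float, sfreq: float,
                       time_res_fwhm: float = 78.8) -> np.ndarray:
    """Instantaneous band power of ``signal`` at ``freq`` Hz.

    Multiplies the signal by ``exp(-i 2 pi freq t)`` and low-pass filters
    with the Gaussian FIR kernel (power FWHM ``time_res_fwhm`` ms); power
    is ``|2 y|**2``.  ``signal`` may have any shape; the last axis is
    time.  Edge samples are corrected by renormalizing the kernel over the
    available support.
    """
    return next(_iter_demodulated(signal, [freq], sfreq, time_res_fwhm))


@dataclass
class TFRSet:
    """Trial-averaged binned power for one subject: (2, channels, freqs, bins)."""

    subject_id: str
    power: np.ndarray
    freqs: np.ndarray           # Hz, bin centers (1 Hz grid)
    bin_starts_ms: np.ndarray   # label = bin start time
    bin_ms: float
    channel_labels: tuple[str, ...]
    conditions: tuple[str, str] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        expected = (2, len(self.channel_labels), len(self.freqs),
                    len(self.bin_starts_ms))
        if self.power.shape != expected:
            raise ValueError(f"power shape {self.power.shape}, expected {expected}")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class TSEMap:
    """Percent power change from baseline: (2, channels, freqs, bins)."""

    subject_id: str
    tse: np.ndarray
    freqs: np.ndarray
    bin_starts_ms: np.ndarray
    bin_ms: float
    channel_labels: tuple[str, ...]
    baseline: tuple[float, float]
    conditions: tuple[str, str] = field(default=CONDITIONS)


def _bin_edges(time: TimeAxis, bin_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Bin start labels and per-sample bin assignment covering the epoch."""
    starts = np.arange(time.t_start_ms, time.t_end_ms + 1e-9, bin_ms)
    sample_bins = np.floor((time.times - time.t_start_ms) / bin_ms).astype(int)
    return starts, sample_bins


def tfr_transform(epochs: EpochsSet, params: DemodParams = DemodParams()) -> TFRSet:
    """Demodulate residual epochs into a binned time-frequency power set.

    Per frequency: demodulate every trial and channel, average power over
    trials within condition; then smooth power across the frequency axis
    (Gaussian, power FWHM ``freq_res_fwhm``); then average samples into
    ``bin_ms`` bins spanning the whole epoch.
    """
    time = epochs.time
    freqs = np.asarray(params.freqs, dtype=float)
    n_ch = epochs.montage.n_channels

    cond_power = np.empty((2, n_ch, len(freqs), time.n_samples))
    masks = [epochs.condition_mask(c) for c in CONDITIONS]
    it = _iter_demodulated(epochs.data, freqs, time.sfreq, params.time_res_fwhm)
    for fi, p in enumerate(it):
        for ci, mask in enumerate(masks):
            cond_power[ci, :, fi, :] = p[mask].mean(axis=0)

    # cross-frequency Gaussian smoothing of power (edge-renormalized)
    df = float(np.diff(freqs).min()) if len(freqs) > 1 else 1.0
    sigma_bins = (params.freq_res_fwhm / (2 * np.sqrt(2 * np.log(2)))) / df
    if len(freqs) > 1 and sigma_bins > 1e-6:
        kern = _gaussian_kernel(sigma_bins)
        sm = fftconvolve(cond_power, kern.reshape(1, 1, -1, 1), mode="same", axes=2)
        cov = fftconvolve(np.ones(len(freqs)), kern, mode="same")
        cond_power = sm / cov.reshape(1, 1, -1, 1)

    starts, sample_bins = _bin_edges(time, params.bin_ms)
    n_bins = len(starts)
    counts = np.bincount(sample_bins, minlength=n_bins)
    binned = np.zeros(cond_power.shape[:-1] + (n_bins,))
    for b in range(n_bins):
        binned[..., b] = cond_power[..., sample_bins == b].mean(axis=-1)
    del counts
    binned = np.maximum(binned, 0.0)
    return TFRSet(epochs.subject_id, binned, freqs, starts, params.bin_ms,
                  epochs.montage.labels)


def write_tse(tse: TSEMap, path) -> None:
    """Write a TSE map directory: JSON sidecar + raw little-endian float32."""
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(subject_id=tse.subject_id, conditions=list(tse.conditions),
                channels=list(tse.channel_labels), freqs_hz=list(tse.freqs),
                bin_starts_ms=list(tse.bin_starts_ms), bin_ms=tse.bin_ms,
                baseline_ms=list(tse.baseline), dtype="float32-le",
                dim_order="condition,channel,freq,bin")
    (path / "tse.json").write_text(json.dumps(meta, indent=1))
    tse.tse.astype("<f4").tofile(path / "tse.dat")


def read_tse(path) -> TSEMap:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads((path / "tse.json").read_text())
    shape = (len(meta["conditions"]), len(meta["channels"]),
             len(meta["freqs_hz"]), len(meta["bin_starts_ms"]))
    data = np.fromfile(path / "tse.dat", dtype="<f4").astype(np.float64)
    if data.size != int(np.prod(shape)):
        raise ValueError("tse.dat size does not match sidecar")
    return TSEMap(meta["subject_id"], data.reshape(shape),
                  np.asarray(meta["freqs_hz"], dtype=float),
                  np.asarray(meta["bin_starts_ms"], dtype=float),
                  meta["bin_ms"], tuple(meta["channels"]),
                  tuple(meta["baseline_ms"]), tuple(meta["conditions"]))


def tse_percent(tfr: TFRSet, baseline: tuple[float, float] = (-300.0, 0.0)) -> TSEMap:
    """TSE(t, f) = 100 (P(t, f) - Pb(f)) / Pb(f), Pb = mean baseline power.

    Baseline bins are those fully inside the baseline window.  Pb must be
    strictly positive at every electrode and frequency.
    """
    lo, hi = baseline
    sel = (tfr.bin_starts_ms >= lo - 1e-9) & (tfr.bin_starts_ms + tfr.bin_ms <= hi + 1e-9)
    if not sel.any():
        raise ValueError("no complete bins inside the baseline window")
    pb = tfr.power[..., sel].mean(axis=-1, keepdims=True)
    if np.any(pb <= 0):
        raise ValueError("baseline power must be positive everywhere")
    tse = 100.0 * (tfr.power - pb) / pb
    return TSEMap(tfr.subject_id, tse, tfr.freqs, tfr.bin_starts_ms, tfr.bin_ms,
                  tfr.channel_labels, (lo, hi))
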