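"""Analysis configuration shared by the pipeline stages."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Parameters of the full analysis pipeline.

    Defaults reproduce the study conventions: 45 mm electrode adjacency,
    0.05 cluster-forming alpha, 5000 permutations, the P200 (0-300 ms) and
    LPC (300-1400 ms) search windows, a 0-1400 ms / 2-30 Hz time-frequency
    grid in 50 ms x 1 Hz bins, a -300..0 ms baseline, and complex
    demodulation with 78.8 ms / 1.42 Hz power-FWHM resolution.
    """

    adjacency_max_dist: float = 45.0  # mm
    cluster_alpha: float = 0.05
    n_permutations: int = 5000
    erp_windows: dict = field(
        default_factory=lambda: {"P200": (0.0, 300.0), "LPC": (300.0, 1400.0)}
    )
    tf_window: tuple = (0.0, 1400.0)
    tf_freq_lo: float = 2.0
    tf_freq_hi: float = 30.0
    tf_freq_step: float = 1.0
    tf_bin_ms: float = 50.0
    baseline: tuple = (-300.0, 0.0)
    time_res_fwhm: float = 78.8  # ms, power FWHM of the demodulation low-pass
    freq_res_fwhm: float = 1.42  # Hz, power FWHM of cross-frequency smoothing
    mc_samples: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cluster_alpha < 1.0:
            raise ValueError("cluster_alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        for name, (lo, hi) in {**self.erp_windows,
                               "tf": self.tf_window,
                               "baseline": self.baseline}.items():
            if lo > hi:
                raise ValueError(f"window {name} has t_lo > t_hi")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "erp_windows" in d:
            d["erp_windows"] = {k: tuple(v) for k, v in d["erp_windows"].items()}
        for key in ("tf_window", "baseline"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
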