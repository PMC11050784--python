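"""Electrode montages: labelled 3-D sensor positions.

A montage is an *ordered* list of electrodes; its order defines channel
order in every epochs array, evoked waveform and topography table produced
by this package.  Positions are in millimetres.  Files use the common
whitespace-separated ``label x y z`` dialect (one electrode per line,
".sfp" style).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["Montage", "read_montage", "write_montage", "standard_montage_40"]


@dataclass(frozen=True)
class Montage:
    """Ordered electrode set with 3-D positions in mm."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), mm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.labels) < 2:
            raise ValueError("a montage needs at least 2 electrodes")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate electrode labels: {dupes}")
        if pos.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("electrode positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix (mm)."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(d, axis=-1)

    def subset(self, labels: list[str]) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx])


def read_montage(path: str | Path) -> Montage:
    """Read a ``label x y z`` electrode-position file (mm)."""
    labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'label x y z', got {line!r}")
        labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinate in {line!r}") from None
    return Montage(tuple(labels), np.array(rows, dtype=float))


def write_montage(montage: Montage, path: str | Path) -> None:
    lines = [
        f"{lab}\t{x:.3f}\t{y:.3f}\t{z:.3f}"
        for lab, (x, y, z) in zip(montage.labels, montage.positions)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def standard_montage_40() -> Montage:
    """The 40-channel analysis montage shipped with the package.

    Standard 10-10 template angular positions for the 40 fronto-central to
    parieto-occipital labels used in the analysis, radially projected onto
    an 85 mm sphere.
    """
    with resources.as_file(
        resources.files("jolreact.data").joinpath("standard40.sfp")
    ) as p:
        return read_montage(p)
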