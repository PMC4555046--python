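"""Schematic 10-10-style EEG montages with annotated channel neighborhoods.

Channel positions are schematic grid coordinates (left hemisphere x < 0,
anterior y > 0, one unit per electrode row/column), not digitized electrode
locations.  They are sufficient for the two things the pipeline needs from a
montage: a deterministic neighborhood relation (e.g. "C3 and its neighboring
channels" for classic mu/beta features) and 2-D coordinates for topography
CSV export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Row layout of the 64-channel standard montage: (y, ((label, x), ...)).
_ROWS: tuple[tuple[float, tuple[tuple[str, float], ...]], ...] = (
    (4.0, (("Fp1", -1.0), ("Fpz", 0.0), ("Fp2", 1.0))),
    (3.0, (("AF7", -3.0), ("AF3", -1.0), ("AFz", 0.0), ("AF4", 1.0), ("AF8", 3.0))),
    (2.0, tuple(zip(("F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"),
                    map(float, range(-4, 5))))),
    (1.0, tuple(zip(("FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"),
                    map(float, range(-4, 5))))),
    (0.0, tuple(zip(("T9", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "T10"),
                    map(float, range(-5, 6))))),
    (-1.0, tuple(zip(("TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"),
                     map(float, range(-4, 5))))),
    (-2.0, tuple(zip(("P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"),
                     map(float, range(-4, 5))))),
    (-3.0, (("PO7", -3.0), ("PO3", -1.0), ("POz", 0.0), ("PO4", 1.0), ("PO8", 3.0))),
    (-4.0, (("O1", -1.0), ("Oz", 0.0), ("O2", 1.0))),
    (-5.0, (("Iz", 0.0),)),
)


@dataclass(frozen=True)
class Montage:
    """Labeled 2-D electrode layout with a neighborhood relation."""

    labels: tuple[str, ...]
    xy: np.ndarray  # (n_channels, 2) schematic coordinates
    neighbors: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        if self.xy.shape != (len(self.labels), 2):
            raise ValueError("montage_xy must be (n_channels, 2)")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None


def _grid_neighbors(labels: tuple[str, ...], xy: np.ndarray) -> dict[str, tuple[str, ...]]:
    """Neighborhood = Chebyshev distance <= 1 on the schematic grid (8-adjacency)."""
    out: dict[str, tuple[str, ...]] = {}
    for i, lab in enumerate(labels):
        d = np.abs(xy - xy[i]).max(axis=1)
        near = [labels[j] for j in np.nonzero((d <= 1.0) & (d > 0.0))[0]]
        out[lab] = tuple(near)
    return out


def standard_montage() -> Montage:
    """The default 64-channel 10-10-style montage (C3 has exactly 8 neighbors)."""
    labels: list[str] = []
    coords: list[tuple[float, float]] = []
    for y, row in _ROWS:
        for lab, x in row:
            labels.append(lab)
            coords.append((x, y))
    xy = np.asarray(coords, dtype=float)
    labs = tuple(labels)
    return Montage(labels=labs, xy=xy, neighbors=_grid_neighbors(labs, xy))


def grid_montage(n_channels: int) -> Montage:
    """Generic rectangular montage for channel counts other than 64.

    Labels are E01, E02, ... laid out row-major on a near-square grid.  No
    canonical C3 exists here, so classic mu/beta channel selection is not
    available on this montage.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    ncol = int(np.ceil(np.sqrt(n_channels)))
    width = max(ncol - 1, 1)
    coords = []
    for i in range(n_channels):
        r, c = divmod(i, ncol)
        coords.append((float(c) - width / 2.0, -float(r)))
    labels = tuple(f"E{i + 1:02d}" for i in range(n_channels))
    xy = np.asarray(coords, dtype=float)
    return Montage(labels=labels, xy=xy, neighbors=_grid_neighbors(labels, xy))


def make_montage(n_channels: int) -> Montage:
    """Standard 64-channel layout when possible, generic grid otherwise."""
    if n_channels == 64:
        return standard_montage()
    return grid_montage(n_channels)
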