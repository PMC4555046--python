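"""Cross-condition discriminability (point-biserial r²) and channel selection.

The channel-wise statistic is

    r = sqrt(n1 n2) / (n1 + n2) * (mean(w1) - mean(w2)) / std_pop(w1 u w2)

with the population standard deviation of the pooled samples, which makes r
exactly the Pearson correlation between the pooled feature values and a 0/1
condition indicator (the point-biserial correlation).  Channels are ranked by
r² per condition pair and the top ranks (union across pairs) become feature
channels; classic mu/beta features instead use C3 and its montage neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage
from .spectral import BandPowerTable
from .specpca import ProjectionTable


@dataclass
class RsqMap:
    """Per-channel signed r and r² for one (feature, condition-pair)."""

    r: np.ndarray  # (n_channels,)
    r2: np.ndarray
    channel_labels: tuple[str, ...]
    montage_xy: np.ndarray
    pair: tuple[str, str]
    feature: str = ""


@dataclass
class ChannelSelection:
    """Ordered feature-channel list with the pairs that contributed each channel."""

    channels: tuple[str, ...]
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.channels) != len(set(self.channels)):
            raise ValueError("selected channels must be unique")


def r_squared(w1, w2) -> tuple[float, float]:
    """Point-biserial r and r² between two feature-value groups."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    n1, n2 = w1.size, w2.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([w1, w2])
    std = pooled.std()  # population convention (divide by n1 + n2)
    if std == 0:
        raise ValueError("zero pooled variance: r² is undefined")
    r = np.sqrt(n1 * n2) / (n1 + n2) * (w1.mean() - w2.mean()) / std
    return float(r), float(r * r)


def _rsq_channels(values: np.ndarray, mask1: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    """Vectorized signed r per channel; zero-variance channels get r = 0."""
    w1 = values[mask1]
    w2 = values[mask2]
    n1, n2 = w1.shape[0], w2.shape[0]
    pooled = np.concatenate([w1, w2], axis=0)
    std = pooled.std(axis=0)
    diff = w1.mean(axis=0) - w2.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(std > 0, np.sqrt(n1 * n2) / (n1 + n2) * diff / std, 0.0)
    return r


def feature_values(features: ProjectionTable | BandPowerTable,
                   k_or_band: int | str | None = None) -> tuple[np.ndarray, str]:
    """(n_segments, n_channels) value matrix and a feature name.

    For a ProjectionTable, ``k_or_band`` selects the component: 1-based int
    or a name like ``"PC2"``.  For a BandPowerTable the band name (or None)
    must match the table.
    """
    if isinstance(features, ProjectionTable):
        if k_or_band is None:
            raise ValueError("projection features need a component (e.g. 1 or 'PC1')")
        k = int(str(k_or_band).upper().removeprefix("PC"))
        if not 1 <= k <= features.n_components:
            raise ValueError(f"component {k} outside 1..{features.n_components}")
        return features.weights[:, :, k - 1], f"PC{k}"
    if isinstance(features, BandPowerTable):
        if k_or_band is not None and str(k_or_band) != features.band:
            raise ValueError(f"band mismatch: table holds {features.band!r}")
        return features.values, features.band
    raise TypeError("features must be a ProjectionTable or BandPowerTable")


def rsq_topography(features: ProjectionTable | BandPowerTable,
                   labels: np.ndarray, pair: tuple[str, str],
                   k_or_band: int | str | None = None) -> RsqMap:
    """Per-channel r² map of one feature between two conditions."""
    values, name = feature_values(features, k_or_band)
    labels = np.asarray(labels)
    cond_a, cond_b = pair
    mask1 = labels == cond_a
    mask2 = labels == cond_b
    for cond, mask in ((cond_a, mask1), (cond_b, mask2)):
        if not mask.any():
            raise ValueError(f"condition {cond!r} not present in labels")
    r = _rsq_channels(values, mask1, mask2)
    return RsqMap(r=r, r2=r * r, channel_labels=features.channel_labels,
                  montage_xy=features.montage_xy, pair=(cond_a, cond_b), feature=name)


def select_channels(maps: list[RsqMap] | RsqMap, top_n: int = 10) -> ChannelSelection:
    """Top-``top_n`` channels by r² per map; union across maps.

    Ranking ties break by channel index (stable sort), and the union keeps
    first-appearance order over (map order, rank order).  ``top_n`` larger
    than the montage returns all channels.
    """
    if isinstance(maps, RsqMap):
        maps = [maps]
    if not maps:
        raise ValueError("need at least one r² map")
    chosen: list[str] = []
    provenance: dict[str, list[str]] = {}
    for mp in maps:
        order = np.argsort(-mp.r2, kind="stable")[:top_n]
        key = f"{mp.feature}:{mp.pair[0]}|{mp.pair[1]}"
        for idx in order:
            ch = mp.channel_labels[idx]
            if ch not in provenance:
                chosen.append(ch)
                provenance[ch] = []
            provenance[ch].append(key)
    return ChannelSelection(channels=tuple(chosen),
                            provenance={ch: tuple(v) for ch, v in provenance.items()})


def mu_beta_channels(montage: Montage, hand: str = "right") -> ChannelSelection:
    """Classic rhythm feature channels: the hand-contralateral C3/C4 plus neighbors."""
    if hand not in ("right", "left"):
        raise ValueError("hand must be 'right' or 'left'")
    center = "C3" if hand == "right" else "C4"
    if center not in montage.labels:
        raise ValueError(f"montage does not define channel {center}")
    if not montage.neighbors or center not in montage.neighbors:
        raise ValueError(f"montage lacks neighbor annotations for {center}")
    channels = (center, *montage.neighbors[center])
    return ChannelSelection(channels=channels,
                            provenance={ch: (f"{center}-neighborhood",) for ch in channels})
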