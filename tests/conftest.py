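import numpy as np
import pytest

from motorspec.montage import standard_montage
from motorspec.preprocess import SegmentSet
from motorspec.synth import Session


@pytest.fixture(scope="session")
def montage64():
    return standard_montage()


def make_session(data: np.ndarray, fs: int = 250, trials=None,
                 fingers=("thumb", "index", "middle", "ring", "little")) -> Session:
    """Wrap a raw (channels x samples) array as a Session for filter tests."""
    n_ch = data.shape[0]
    labels = tuple(f"E{i + 1:02d}" for i in range(n_ch))
    xy = np.column_stack([np.arange(n_ch, dtype=float), np.zeros(n_ch)])
    return Session(data=np.asarray(data, dtype=float), sampling_rate_hz=fs,
                   channel_labels=labels, montage_xy=xy,
                   trials=list(trials or []), fingers=tuple(fingers))


def make_segments(data: np.ndarray, labels, fs: int = 250) -> SegmentSet:
    """Wrap an (M x N x T) array as a SegmentSet."""
    n_ch = data.shape[1]
    ch = tuple(f"E{i + 1:02d}" for i in range(n_ch))
    xy = np.column_stack([np.arange(n_ch, dtype=float), np.zeros(n_ch)])
    return SegmentSet(data=np.asarray(data, dtype=float),
                      labels=np.asarray(labels, dtype=object),
                      sampling_rate_hz=fs, channel_labels=ch, montage_xy=xy)
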