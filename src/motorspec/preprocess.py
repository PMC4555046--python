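"""Continuous-recording preprocessing: filtering, re-referencing, segmentation.

All filters are applied forward and backward (zero phase).  Segmentation
takes, from each 6-s trial, the middle second of the fixation window (labeled
``rest``) and the middle second of the movement-cue window (labeled with the
trial's finger); rest segments from all trials form one pooled condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .synth import REST_LABEL, Session


@dataclass
class SegmentSet:
    """Labeled 1-s segments: (n_segments, n_channels, samples_per_segment)."""

    data: np.ndarray
    labels: np.ndarray  # (n_segments,) condition strings
    sampling_rate_hz: int
    channel_labels: tuple[str, ...]
    montage_xy: np.ndarray

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def highpass_sos(sampling_rate_hz: float, cutoff_hz: float = 0.3) -> np.ndarray:
    """Order-4 elliptic high-pass (0.01 dB ripple, 40 dB stopband) as SOS.

    The tiny passband ripple keeps the doubled (forward+backward) response
    within 1% of unity throughout the passband; 0.1 Hz is attenuated well
    beyond 20 dB.
    """
    nyq = sampling_rate_hz / 2.0
    if not 0.0 < cutoff_hz < nyq:
        raise ValueError("cutoff_hz must lie strictly between 0 and Nyquist")
    return signal.ellip(4, 0.01, 40.0, cutoff_hz, btype="highpass",
                        fs=sampling_rate_hz, output="sos")


def notch_sos(sampling_rate_hz: float, center_hz: float = 60.0,
              transition_hz: float = 0.3) -> np.ndarray:
    """Elliptic band-stop around ``center_hz``.

    The stopband spans center +/- transition/2 with a transition band of
    ``transition_hz`` on each side; minimal order via ellipord, 40 dB
    stopband, 0.01 dB passband ripple.
    """
    nyq = sampling_rate_hz / 2.0
    if not 0.0 < center_hz < nyq:
        raise ValueError("center_hz must lie strictly between 0 and Nyquist")
    half = transition_hz / 2.0
    ws = (center_hz - half, center_hz + half)
    wp = (center_hz - half - transition_hz, center_hz + half + transition_hz)
    order, wn = signal.ellipord(wp, ws, gpass=0.01, gstop=40.0, fs=sampling_rate_hz)
    return signal.ellip(order, 0.01, 40.0, wn, btype="bandstop",
                        fs=sampling_rate_hz, output="sos")


def _zero_phase(sos: np.ndarray, session: Session) -> Session:
    # generous reflect padding: the narrow-band filters have impulse
    # responses lasting seconds, far beyond scipy's default pad length
    padlen = min(session.n_samples - 1, 10 * session.sampling_rate_hz)
    filtered = signal.sosfiltfilt(sos, session.data, axis=1, padlen=padlen)
    return replace(session, data=filtered)


def highpass(session: Session, cutoff_hz: float = 0.3) -> Session:
    """Zero-phase elliptic high-pass (removes drift and DC)."""
    return _zero_phase(highpass_sos(session.sampling_rate_hz, cutoff_hz), session)


def notch(session: Session, center_hz: float = 60.0,
          transition_hz: float = 0.3) -> Session:
    """Zero-phase band-stop for power-line noise (>= 40 dB at the line frequency)."""
    return _zero_phase(notch_sos(session.sampling_rate_hz, center_hz, transition_hz),
                       session)


def car(session: Session) -> Session:
    """Common average reference: subtract the instantaneous cross-channel mean."""
    if session.n_channels < 2:
        raise ValueError("CAR requires at least 2 channels")
    return replace(session, data=session.data - session.data.mean(axis=0, keepdims=True))


def extract_segments(session: Session,
                     exclude_trials: tuple[int, ...] = ()) -> SegmentSet:
    """Middle-1-s rest and movement segments from every (non-excluded) trial.

    With 0-based onset ``o`` at rate ``r``, the rest segment covers samples
    ``[o + 2.5r, o + 3.5r)`` (middle of the fixation window) and the movement
    segment ``[o + 4.5r, o + 5.5r)`` (middle of the cue window).  Output
    order: all rest segments in trial order, then all movement segments in
    trial order.
    """
    fs = session.sampling_rate_hz
    seg_len = fs  # 1 s
    trial_len = 6 * fs
    excluded = set(int(i) for i in exclude_trials)
    rest_rows, move_rows, move_labels = [], [], []
    for i, (onset, label) in enumerate(session.trials):
        if i in excluded:
            continue
        if onset < 0 or onset + trial_len > session.n_samples:
            raise ValueError(f"trial {i} (onset {onset}) extends past the recording")
        if label not in session.fingers:
            raise ValueError(f"trial {i} has unknown finger label {label!r}")
        rest_start = onset + (5 * fs) // 2
        move_start = onset + (9 * fs) // 2
        rest_rows.append(session.data[:, rest_start:rest_start + seg_len])
        move_rows.append(session.data[:, move_start:move_start + seg_len])
        move_labels.append(label)
    if not rest_rows:
        raise ValueError("no trials to segment")
    data = np.stack(rest_rows + move_rows)
    labels = np.asarray([REST_LABEL] * len(rest_rows) + move_labels, dtype=object)
    return SegmentSet(data=data, labels=labels, sampling_rate_hz=fs,
                      channel_labels=session.channel_labels,
                      montage_xy=session.montage_xy)
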