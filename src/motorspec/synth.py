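"""Seeded synthetic EEG sessions with planted, recoverable spectral structure.

The generator emulates a cued finger-movement session: 6-s trials (2 s blank,
2 s fixation, 2 s movement cue), five fingers in seeded-random order, at
250 Hz on a 64-channel 10-10-style montage.

Generative model (per channel ``n`` and condition ``c``), as a one-sided
power spectral density in µV²/Hz::

    S_nc(f) = exp(s_nc) * B(f)
              + (g_nc * A_alpha,n)^2 * G_alpha(f)
              + (g_nc * A_beta,n)^2  * G_beta(f)

where ``B(f) = background_scale * f**-chi`` is the 1/f background,
``G`` are unit-peak Gaussian bumps at the configured rhythm centers, the
rhythm amplitudes ``A_n`` place the peaks ``log_amp * rhythm_map[n]`` natural
log units above the background at the peak center, ``g_nc`` is the
event-related desynchronization (ERD) amplitude attenuation (1 at rest), and
``s_nc`` is the movement-related broadband log-power offset (0 at rest).
Per-finger signatures perturb ``(g, s)`` on small channel sets (by default
broadband-only duos sliding along the left premotor/parietal rows), giving
each finger a distinct spatial fingerprint.  The rhythm component
additionally waxes and wanes spontaneously: each 2-s block draws a
per-channel log-amplitude jitter applied jointly to the alpha and beta
bumps, the coupled cross-frequency fluctuation that spectral PCA is designed
to expose.

Signals are realized block-wise (one 2-s block per trial phase) as colored
noise: the target amplitude spectrum with seeded random phases is inverse-FFT
transformed, blocks are joined with a 10-ms equal-power raised-cosine
cross-fade, and a 60-Hz line sinusoid plus white sensor noise are added.
Identical ``(config, seed)`` give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .montage import Montage, make_montage

DEFAULT_FINGERS: tuple[str, ...] = ("thumb", "index", "middle", "ring", "little")
REST_LABEL = "rest"

#: analysis frequency grid of the downstream pipeline, Hz
ANALYSIS_FREQS = np.arange(1, 71, dtype=float)

# Default spatial maps (64-channel montage).  Right-hand movements: rhythm
# generators over both sensorimotor hand areas (contralateral left stronger)
# plus posterior visual alpha; ERD only over sensorimotor channels; the
# movement-related broadband offset over left premotor + parietal channels,
# deliberately mostly disjoint from the ERD set so the two planted spectral
# structures vary independently across observations.
_C3_GROUP = ("C3", "C5", "C1", "FC5", "FC3", "FC1", "CP5", "CP3", "CP1")
_C4_GROUP = ("C4", "C6", "C2", "FC6", "FC4", "FC2", "CP6", "CP4", "CP2")
_POSTERIOR = ("PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2")
_BROADBAND_SET = ("F5", "F3", "F1", "FT7", "P5", "P3", "P1", "TP7")
_FINGER_SETS: dict[str, tuple[str, ...]] = {
    "thumb": ("FT7", "F5"),
    "index": ("F5", "F3"),
    "middle": ("F3", "F1"),
    "ring": ("P5", "P3"),
    "little": ("P3", "P1"),
}


def default_rhythm_map() -> dict[str, float]:
    out = {ch: 1.0 for ch in _C3_GROUP}
    out.update({ch: 0.7 for ch in _C4_GROUP})
    out.update({ch: 0.8 for ch in _POSTERIOR})
    return out


def default_erd_map() -> dict[str, float]:
    out = {ch: 0.55 for ch in _C3_GROUP}
    out.update({ch: 0.75 for ch in _C4_GROUP})
    return out


def default_broadband_shift() -> dict[str, float]:
    return {ch: 0.4 for ch in _BROADBAND_SET}


def default_finger_effect() -> dict[str, dict[str, tuple[float, float]]]:
    """Somatotopic per-finger signatures: (erd_delta, broadband_delta) per channel.

    Defaults perturb only the broadband offset (erd_delta = 0) on a small,
    finger-specific channel duo sliding across the left sensorimotor strip.
    """
    return {fin: {ch: (0.0, 0.35) for ch in chans} for fin, chans in _FINGER_SETS.items()}


@dataclass
class SynthConfig:
    """Parameters of the synthetic finger-movement EEG session."""

    n_channels: int = 64
    sampling_rate_hz: int = 250
    trials_per_finger: int = 80
    fingers: tuple[str, ...] = DEFAULT_FINGERS
    background_exponent: float = 1.0
    background_scale: float = 20.0  # µV²/Hz at 1 Hz
    alpha_peak: tuple[float, float, float] = (10.0, 2.0, 2.2)  # (center, bw, log-amp)
    beta_peak: tuple[float, float, float] = (20.0, 2.5, 1.2)
    rhythm_map: dict[str, float] | None = None
    rhythm_jitter_sd: float = 0.3  # log-amplitude sd of spontaneous rhythm waxing/waning
    erd_map: dict[str, float] | None = None
    broadband_shift: dict[str, float] | None = None
    finger_effect: dict[str, dict[str, tuple[float, float]]] | None = None
    line_noise_hz: float = 60.0
    line_noise_amp: float = 2.0  # µV
    noise_sd: float = 1.0  # µV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels == 64:
            if self.rhythm_map is None:
                self.rhythm_map = default_rhythm_map()
            if self.erd_map is None:
                self.erd_map = default_erd_map()
            if self.broadband_shift is None:
                self.broadband_shift = default_broadband_shift()
            if self.finger_effect is None:
                self.finger_effect = default_finger_effect()
        else:
            self.rhythm_map = self.rhythm_map or {}
            self.erd_map = self.erd_map or {}
            self.broadband_shift = self.broadband_shift or {}
            self.finger_effect = self.finger_effect or {}

    def neutral(self) -> "SynthConfig":
        """Copy of the config with every condition effect switched off."""
        return replace(self, erd_map={}, broadband_shift={}, finger_effect={})


@dataclass
class Session:
    """A continuous multichannel recording plus its trial manifest."""

    data: np.ndarray  # (n_channels, n_samples), µV
    sampling_rate_hz: int
    channel_labels: tuple[str, ...]
    montage_xy: np.ndarray  # (n_channels, 2)
    trials: list[tuple[int, str]]  # (onset_sample, finger_label)
    fingers: tuple[str, ...] = DEFAULT_FINGERS

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GroundTruth:
    """Planted spectral profiles and expected log-power curves (recovery oracle)."""

    freqs: np.ndarray  # (70,)
    broadband_profile: np.ndarray  # (70,), unit norm
    rhythm_profile: np.ndarray  # (70,), unit norm, peaks at the rhythm centers
    expected_log_power: dict[str, np.ndarray]  # condition -> (n_channels, 70)


def validate_config(config: SynthConfig) -> None:
    """Raise ValueError naming the offending field for invalid configs."""
    if int(config.trials_per_finger) < 1:
        raise ValueError("trials_per_finger must be >= 1")
    if config.n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    rate = config.sampling_rate_hz
    if rate % 2 != 0 or rate <= 140:
        raise ValueError("sampling_rate_hz must be even and > 140")
    if not config.fingers or len(set(config.fingers)) != len(config.fingers):
        raise ValueError("fingers must be a non-empty list of unique labels")
    if REST_LABEL in config.fingers:
        raise ValueError(f"fingers must not contain the reserved label {REST_LABEL!r}")
    for name, peak in (("alpha_peak", config.alpha_peak), ("beta_peak", config.beta_peak)):
        center, bw, _amp = peak
        if bw <= 0:
            raise ValueError(f"{name} bandwidth must be > 0")
        if not 0 < center < rate / 2:
            raise ValueError(f"{name} center must lie below the Nyquist frequency")
    for ch, g in (config.erd_map or {}).items():
        if not 0.0 < g <= 1.0:
            raise ValueError(f"erd_map[{ch!r}] must be in (0, 1]")
    for fin in config.finger_effect or {}:
        if fin not in config.fingers:
            raise ValueError(f"finger_effect key {fin!r} is not a configured finger")
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if config.rhythm_jitter_sd < 0:
        raise ValueError("rhythm_jitter_sd must be >= 0")
    if config.line_noise_amp < 0:
        raise ValueError("line_noise_amp must be >= 0")


def _channel_vector(mapping: dict[str, float], montage: Montage, default: float) -> np.ndarray:
    out = np.full(len(montage), default, dtype=float)
    for ch, val in mapping.items():
        out[montage.index(ch)] = val
    return out


def _condition_fields(config: SynthConfig, montage: Montage,
                      condition: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (erd attenuation g, broadband log offset s) for one condition."""
    n = len(montage)
    if condition == REST_LABEL:
        return np.ones(n), np.zeros(n)
    g = _channel_vector(config.erd_map or {}, montage, 1.0)
    s = _channel_vector(config.broadband_shift or {}, montage, 0.0)
    for ch, (dg, ds) in (config.finger_effect or {}).get(condition, {}).items():
        i = montage.index(ch)
        g[i] = float(np.clip(g[i] + dg, 1e-6, 1.0))
        s[i] += ds
    return g, s


def _rhythm_amp_sq(config: SynthConfig, montage: Montage) -> tuple[np.ndarray, np.ndarray]:
    """Squared rhythm amplitudes (linear power at the bump peak) per channel."""
    m = _channel_vector(config.rhythm_map or {}, montage, 0.0)
    out = []
    for center, _bw, amp in (config.alpha_peak, config.beta_peak):
        back = config.background_scale * center ** -config.background_exponent
        out.append(back * np.expm1(amp * m))
    return out[0], out[1]


def _psd_parts(config: SynthConfig, freqs: np.ndarray, condition: str,
               montage: Montage) -> tuple[np.ndarray, np.ndarray]:
    """Background and rhythm PSD components, each (n_channels, len(freqs))."""
    f = np.asarray(freqs, dtype=float)
    back = config.background_scale * f ** -config.background_exponent
    a2_alpha, a2_beta = _rhythm_amp_sq(config, montage)
    g, s = _condition_fields(config, montage, condition)
    ca, bwa, _ = config.alpha_peak
    cb, bwb, _ = config.beta_peak
    bump_a = np.exp(-0.5 * ((f - ca) / bwa) ** 2)
    bump_b = np.exp(-0.5 * ((f - cb) / bwb) ** 2)
    gg = g ** 2
    background = np.exp(s)[:, None] * back[None, :]
    rhythm = ((gg * a2_alpha)[:, None] * bump_a[None, :]
              + (gg * a2_beta)[:, None] * bump_b[None, :])
    return background, rhythm


def target_psd(config: SynthConfig, freqs: np.ndarray, condition: str,
               montage: Montage | None = None) -> np.ndarray:
    """Planted one-sided PSD (n_channels, len(freqs)) in µV²/Hz, noise floor excluded.

    This is the median spectrum: the spontaneous rhythm-amplitude jitter
    multiplies the rhythm component around 1 block by block.
    """
    montage = montage or make_montage(config.n_channels)
    background, rhythm = _psd_parts(config, freqs, condition, montage)
    return background + rhythm


def _noise_floor(config: SynthConfig) -> float:
    # white noise of variance sd^2 spread over [0, Nyquist] as one-sided density
    return 2.0 * config.noise_sd ** 2 / config.sampling_rate_hz


def ground_truth_profiles(config: SynthConfig) -> GroundTruth:
    """Planted unit-norm spectral profiles and expected per-condition log spectra.

    The broadband profile is flat across the analysis grid (a uniform
    log-power offset).  The rhythm profile is the log-power direction along
    which a coupled alpha+beta amplitude change (spontaneous waxing/waning or
    movement-related ERD) moves the spectrum on the most rhythmic channel:
    ``d ln S / d ln A = 2 R(f) / (B(f) + R(f))`` — peaks at the configured
    rhythm centers, ~0 away from them.  Because a uniform log-power component
    of a rhythm modulation cannot be told apart from broadband modulation by
    any orthogonal decomposition, the rhythm profile is reported with its
    flat component removed (still peaked at the centers, unit norm).
    """
    validate_config(config)
    montage = make_montage(config.n_channels)
    freqs = ANALYSIS_FREQS.copy()
    flat = np.ones_like(freqs)
    broadband = flat / np.linalg.norm(flat)

    m = _channel_vector(config.rhythm_map or {}, montage, 0.0)
    background, rhythm_part = _psd_parts(config, freqs, REST_LABEL, montage)
    if m.max() > 0:
        ref = int(np.argmax(m))
        raw = 2.0 * rhythm_part[ref] / (background[ref] + rhythm_part[ref])
    else:  # no rhythm anywhere: fall back to the configured bump shapes
        ca, bwa, _ = config.alpha_peak
        cb, bwb, _ = config.beta_peak
        raw = (np.exp(-0.5 * ((freqs - ca) / bwa) ** 2)
               + np.exp(-0.5 * ((freqs - cb) / bwb) ** 2))
    raw = raw - raw.mean()  # remove the broadband-degenerate flat component
    rhythm = raw / np.linalg.norm(raw)
    if rhythm[np.abs(rhythm).argmax()] < 0:
        rhythm = -rhythm

    floor = _noise_floor(config)
    expected = {REST_LABEL: np.log(background + rhythm_part + floor)}
    for fin in config.fingers:
        expected[fin] = np.log(target_psd(config, freqs, fin, montage) + floor)
    return GroundTruth(freqs=freqs, broadband_profile=broadband,
                       rhythm_profile=rhythm, expected_log_power=expected)


def generate_session(config: SynthConfig) -> tuple[Session, GroundTruth]:
    """Generate one seeded session and its ground truth.

    Trial layout: ``trials_per_finger`` trials per finger in seeded-random
    order; each 6-s trial is three 2-s blocks — blank (rest spectrum),
    fixation (rest spectrum), cue (movement spectrum of the trial's finger).
    """
    validate_config(config)
    montage = make_montage(config.n_channels)
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    block = 2 * fs  # samples per 2-s block
    ramp = max(2, int(round(0.01 * fs)))  # 10-ms cross-fade
    nfft = block + ramp
    n_bins = nfft // 2 - 1  # bins 1..n_bins; DC and Nyquist stay zero
    df = fs / nfft
    fgrid = np.arange(1, n_bins + 1) * df

    conditions = [REST_LABEL, *config.fingers]
    # per-condition background / rhythm power parts on the synthesis grid
    parts = {c: _psd_parts(config, fgrid, c, montage) for c in conditions}

    order = rng.permutation(np.repeat(np.asarray(config.fingers, dtype=object),
                                      config.trials_per_finger))
    n_trials = order.size
    n_blocks = 3 * n_trials
    total = n_blocks * block
    n_ch = len(montage)

    line_phase = rng.uniform(0.0, 2.0 * np.pi, n_ch)

    up = np.sin(0.5 * np.pi * (np.arange(ramp) + 0.5) / ramp)
    down = np.cos(0.5 * np.pi * (np.arange(ramp) + 0.5) / ramp)

    data = np.zeros((n_ch, total + ramp))
    spec = np.zeros((n_ch, nfft // 2 + 1), dtype=complex)
    block_conditions = [c for lab in order for c in (REST_LABEL, REST_LABEL, lab)]
    for j, cond in enumerate(block_conditions):
        background, rhythm = parts[cond]
        jitter = np.exp(2.0 * rng.normal(0.0, config.rhythm_jitter_sd, (n_ch, 1)))
        power = background + jitter * rhythm
        # |X_k| such that the one-sided periodogram density of the block matches S
        amp = nfft * np.sqrt(power * df / 2.0)
        phases = rng.uniform(0.0, 2.0 * np.pi, (n_ch, n_bins))
        spec[:, 1:n_bins + 1] = amp * np.exp(1j * phases)
        x = np.fft.irfft(spec, n=nfft, axis=1)
        if j > 0:
            x[:, :ramp] *= up
        if j < n_blocks - 1:
            x[:, -ramp:] *= down
        start = j * block
        data[:, start:start + nfft] += x
    data = data[:, :total]

    t = np.arange(total) / fs
    for n in range(n_ch):  # per channel to bound peak memory
        if config.line_noise_amp > 0:
            data[n] += config.line_noise_amp * np.sin(
                2.0 * np.pi * config.line_noise_hz * t + line_phase[n])
        if config.noise_sd > 0:
            data[n] += rng.normal(0.0, config.noise_sd, total)

    trials = [(3 * i * block, str(lab)) for i, lab in enumerate(order)]
    session = Session(data=data, sampling_rate_hz=fs, channel_labels=montage.labels,
                      montage_xy=montage.xy.copy(), trials=trials,
                      fingers=tuple(config.fingers))
    return session, ground_truth_profiles(config)
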