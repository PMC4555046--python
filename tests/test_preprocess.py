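"""Filter contracts, CAR algebra, and segmentation bookkeeping."""

import numpy as np
import pytest

from motorspec.preprocess import (car, extract_segments, highpass, highpass_sos,
                                  notch, notch_sos)
from conftest import make_session

FS = 250


def sos_response(sos: np.ndarray, freq_hz: float, fs: float = FS) -> complex:
    """Independent polynomial evaluation of an SOS cascade at one frequency."""
    z = np.exp(-1j * 2 * np.pi * freq_hz / fs)
    h = 1.0 + 0.0j
    for b0, b1, b2, a0, a1, a2 in sos:
        h *= (b0 + b1 * z + b2 * z * z) / (a0 + a1 * z + a2 * z * z)
    return h


def sine(freq, seconds=8, fs=FS, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestHighpass:
    def test_dc_input_is_removed(self):
        session = make_session(np.full((2, 4 * FS), 5.0))
        out = highpass(session)
        assert np.abs(out.data[:, FS:]).max() < 5.0 * 1e-3

    def test_10hz_passband_rms_within_one_percent(self):
        x = sine(10.0)
        out = highpass(make_session(np.stack([x, x])))
        core = out.data[0, FS:-FS]  # ignore filter edges
        ref = x[FS:-FS]
        assert np.sqrt(np.mean(core ** 2)) == pytest.approx(
            np.sqrt(np.mean(ref ** 2)), rel=0.01)

    def test_designed_response_below_minus_20db_at_0p1hz(self):
        h = sos_response(highpass_sos(FS, 0.3), 0.1)
        assert 20 * np.log10(abs(h)) < -20.0

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(make_session(np.zeros((2, FS))), cutoff_hz=125.0)

    def test_zero_phase_preserves_pulse_symmetry(self):
        data = np.zeros((2, 8 * FS))
        data[:, 4 * FS] = 1.0  # symmetric impulse mid-recording
        out = highpass(make_session(data)).data[0]
        left = out[4 * FS - 200:4 * FS]
        right = out[4 * FS + 1:4 * FS + 201][::-1]
        np.testing.assert_allclose(left, right, atol=1e-4)


class TestNotch:
    # a 0.3-Hz-wide notch rings for seconds, so steady-state probes are
    # 30 s long with 10 s trimmed from each edge
    CORE = slice(10 * FS, -10 * FS)

    def test_60hz_attenuated_to_one_percent(self):
        out = notch(make_session(np.stack([sine(60.0, seconds=30)] * 2)))
        assert np.sqrt(np.mean(out.data[0, self.CORE] ** 2)) <= 0.01 * np.sqrt(0.5)

    def test_passband_tones_survive_within_one_percent(self):
        for freq in (10.0, 30.0):
            x = sine(freq, seconds=30)
            out = notch(make_session(np.stack([x, x])))
            core = out.data[0, self.CORE]
            assert np.sqrt(np.mean(core ** 2)) == pytest.approx(
                np.sqrt(np.mean(x[self.CORE] ** 2)), rel=0.01)

    def test_mixed_tone_reduces_to_the_10hz_component(self):
        x10, x60 = sine(10.0, seconds=30), sine(60.0, seconds=30)
        out = notch(make_session(np.stack([x10 + x60, x10 + x60])))
        resid = out.data[0, self.CORE] - x10[self.CORE]
        assert np.sqrt(np.mean(resid ** 2)) < 0.02 * np.sqrt(np.mean(x10 ** 2))

    def test_stopband_and_passband_of_designed_filter(self):
        sos = notch_sos(FS)
        assert 20 * np.log10(abs(sos_response(sos, 60.0))) <= -40.0
        for freq in (10.0, 30.0):
            assert abs(20 * np.log10(abs(sos_response(sos, freq)))) < 1.0


class TestCar:
    def test_two_channel_example(self):
        out = car(make_session(np.array([[3.0], [1.0]])))
        np.testing.assert_allclose(out.data, [[1.0], [-1.0]])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        session = make_session(rng.normal(size=(8, 100)))
        once = car(session)
        twice = car(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-14)

    def test_column_means_vanish(self):
        rng = np.random.default_rng(1)
        out = car(make_session(rng.normal(size=(8, 100))))
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            car(make_session(np.zeros((1, 10))))


class TestExtractSegments:
    def trial_session(self, n_trials=4):
        data = np.tile(np.arange(n_trials * 6 * FS, dtype=float), (2, 1))
        trials = [(i * 6 * FS, "thumb" if i % 2 == 0 else "index")
                  for i in range(n_trials)]
        return make_session(data, trials=trials)

    def test_segment_windows_hit_the_stated_sample_ranges(self):
        session = self.trial_session(2)
        segs = extract_segments(session)
        # rest of trial 0 covers samples [625, 875); movement [1125, 1375)
        np.testing.assert_allclose(segs.data[0, 0], np.arange(625, 875))
        np.testing.assert_allclose(segs.data[2, 0], np.arange(1125, 1375))
        o = 6 * FS
        np.testing.assert_allclose(segs.data[1, 0], np.arange(o + 625, o + 875))
        np.testing.assert_allclose(segs.data[3, 0], np.arange(o + 1125, o + 1375))

    def test_counts_and_label_partition(self):
        segs = extract_segments(self.trial_session(4))
        assert segs.n_segments == 8
        assert (segs.labels == "rest").sum() == 4
        assert (segs.labels == "thumb").sum() == 2
        assert (segs.labels == "index").sum() == 2

    def test_exclusion_list_drops_trials(self):
        segs = extract_segments(self.trial_session(4), exclude_trials=(1, 3))
        assert segs.n_segments == 4
        assert set(segs.labels) == {"rest", "thumb"}

    def test_trial_past_recording_end_is_identified(self):
        session = self.trial_session(2)
        session.trials.append((11 * FS, "ring"))
        with pytest.raises(ValueError, match="trial 2"):
            extract_segments(session)
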