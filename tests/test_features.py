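import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurokws import dsp
from neurokws import features as ft
from neurokws.recording_io import SYLLABLES, Recording


def make_recording(signal, rate=1000.0, mic=None):
    signal = np.atleast_2d(signal)
    n_ch, n = signal.shape
    return Recording(
        signal=signal,
        rate=rate,
        channel_labels=[f"ch{i}" for i in range(n_ch)],
        roi=np.array(["vSMC"] * n_ch, dtype=object),
        excluded=np.zeros(n_ch, bool),
        mic=np.zeros(n) if mic is None else mic,
    )


def make_events(onsets):
    onsets = np.asarray(onsets, dtype=float)
    return pd.DataFrame(
        {
            "trial": np.arange(len(onsets)),
            "stimulus_onset": onsets,
            "label": [SYLLABLES[i % 12] for i in range(len(onsets))],
            "block": np.zeros(len(onsets), dtype=int),
            "voice_onset": np.full(len(onsets), np.nan),
        }
    )


class TestStft:
    @given(n=st.integers(min_value=128, max_value=20_000))
    @settings(max_examples=25, deadline=None)
    def test_frame_count_formula(self, n):
        x = np.sin(np.arange(n) * 0.01)
        logpow, freqs, times = ft.stft_log_power(x, 1000.0)
        assert logpow.shape[1] == (n - 128) // 16 + 1

    def test_frame_times_are_last_sample_16ms_spacing(self, rng):
        x = rng.standard_normal(2000)
        _, _, times = ft.stft_log_power(x, 1000.0)
        assert times[0] == pytest.approx(127 / 1000.0)
        np.testing.assert_allclose(np.diff(times), 0.016)

    def test_band_bins(self):
        freqs = np.fft.rfftfreq(128, d=1e-3)
        in_band = (freqs >= 70) & (freqs <= 110)
        assert in_band.sum() == 6  # 70.3 .. 109.4 Hz at 7.8125 Hz spacing


class TestExtractHighGamma:
    def test_baseline_self_normalized(self, rng):
        x = rng.standard_normal((3, 30_000))
        events = make_events([5.0, 10.0, 15.0, 20.0, 25.0])
        stream, stats = ft.extract_high_gamma(make_recording(x), events)
        bl = stream.z[:, stream.baseline_frames]
        assert np.all(np.abs(bl.mean(axis=1)) < 0.05)
        assert np.all((bl.std(axis=1) > 0.95) & (bl.std(axis=1) < 1.05))

    def test_sinusoid_switch_detected_within_one_window(self, rng):
        # oracle: the 90 Hz bin must carry the tone, so the band feature
        # steps up within 128 ms of the switch
        n = 30_000
        t = np.arange(n) / 1000.0
        x = rng.standard_normal(n)
        switch = 20.0
        x[t >= switch] += 10.0 * np.sin(2 * np.pi * 90.0 * t[t >= switch])
        events = make_events([5.0, 10.0, 15.0])
        stream, _ = ft.extract_high_gamma(make_recording(x), events)
        pre = stream.z[0, stream.frame_times < switch - 0.2]
        post = stream.z[0, stream.frame_times > switch + 0.128]
        assert np.abs(pre.mean()) < 1.0
        assert post.mean() > 5.0
        first_big = stream.frame_times[np.flatnonzero(stream.z[0] > 5.0)[0]]
        assert switch <= first_big <= switch + 0.128 + 0.016

    def test_white_noise_null_exceedance(self, rng):
        x = rng.standard_normal((2, 60_000))
        events = make_events(np.arange(3.0, 58.0, 5.0))
        stream, _ = ft.extract_high_gamma(make_recording(x), events)
        assert np.mean(np.abs(stream.z) > 4.0) < 0.01

    def test_no_baseline_frames_raises(self, rng):
        x = rng.standard_normal((1, 5000))
        with pytest.raises(ValueError, match="baseline"):
            ft.extract_high_gamma(make_recording(x), make_events([0.05]))

    def test_excluded_channel_dropped(self, rng):
        rec = make_recording(rng.standard_normal((3, 20_000)))
        rec.excluded[1] = True
        stream, _ = ft.extract_high_gamma(rec, make_events([5.0, 10.0]))
        assert stream.z.shape[0] == 2
        assert stream.channel_labels == ["ch0", "ch2"]

    def test_causality(self, rng):
        x = rng.standard_normal((2, 20_000))
        events = make_events([3.0, 6.0])
        stream_a, _ = ft.extract_high_gamma(make_recording(x.copy()), events)
        cut = 15_000  # after the last baseline window
        y = x.copy()
        y[:, cut:] += 25.0 * rng.standard_normal((2, x.shape[1] - cut))
        stream_b, _ = ft.extract_high_gamma(make_recording(y), events)
        safe = stream_a.frame_times < (cut / 1000.0) - 1e-9
        np.testing.assert_allclose(
            stream_a.z[:, safe], stream_b.z[:, safe], atol=1e-10
        )
        assert not np.allclose(stream_a.z[:, ~safe], stream_b.z[:, ~safe])


class TestMicVoiceOnsets:
    def _mic_recording(self, bursts, n=20_000, rate=1000.0, band=(250.0, 450.0), seed=0):
        rng = np.random.default_rng(seed)
        mic = 0.05 * rng.standard_normal(n)
        for t0 in bursts:
            i0 = int(t0 * rate)
            dur = int(0.3 * rate)
            carrier = dsp.bandlimited_noise(dur, rate, band[0], band[1], rng)
            mic[i0 : i0 + dur] += 1.0 * carrier
        return make_recording(rng.standard_normal((1, n)), rate=rate, mic=mic)

    def test_planted_burst_detected_within_16ms(self):
        rec = self._mic_recording([12.4])
        events = make_events([3.0, 6.0, 9.0, 11.8])
        onsets = ft.mic_voice_onsets(rec, events)
        assert np.isfinite(onsets[3])
        assert abs(onsets[3] - 12.4) <= 0.016

    def test_silent_trial_missing(self):
        rec = self._mic_recording([12.4])
        events = make_events([3.0, 6.0, 9.0, 11.8])
        onsets = ft.mic_voice_onsets(rec, events)
        assert np.isnan(onsets[0]) and np.isnan(onsets[1])

    def test_out_of_band_burst_not_detected(self):
        rng = np.random.default_rng(1)
        n = 20_000
        mic = 0.05 * rng.standard_normal(n)
        i0 = int(12.4 * 1000)
        t = np.arange(int(0.3 * 1000)) / 1000.0
        mic[i0 : i0 + len(t)] += 1.0 * np.sin(2 * np.pi * 100.0 * t)
        rec = make_recording(rng.standard_normal((1, n)), mic=mic)
        onsets = ft.mic_voice_onsets(rec, make_events([3.0, 6.0, 9.0, 11.8]))
        assert np.isnan(onsets[3])


class TestEpoch:
    def _stream(self, z, rate=62.5):
        n = z.shape[1]
        times = 0.127 + np.arange(n) * 0.016
        return ft.FeatureStream(
            z=z, frame_times=times, frame_rate=rate,
            channel_labels=[f"c{i}" for i in range(z.shape[0])],
            roi=np.array(["vSMC"] * z.shape[0], dtype=object),
            baseline_frames=np.arange(10),
        )

    def test_center_frame_value(self, rng):
        z = rng.standard_normal((2, 200))
        stream = self._stream(z)
        t_center = stream.frame_times[100]
        epochs, kept = ft.epoch(stream, [t_center])
        assert kept.tolist() == [0]
        np.testing.assert_array_equal(epochs[0, :, ft.EPOCH_HALF], z[:, 100])
        assert epochs.shape == (1, 2, 63)

    def test_counts_and_drops(self, rng):
        z = rng.standard_normal((1, 300))
        stream = self._stream(z)
        good = stream.frame_times[50:170]  # 120 usable
        aligns = np.concatenate([[stream.frame_times[2]], good, [np.nan]])
        epochs, kept = ft.epoch(stream, aligns)
        assert epochs.shape[0] == 120
        assert 0 not in kept and len(aligns) - 1 not in kept

    def test_constant_stream_identical_epochs(self):
        z = np.full((2, 300), 3.14)
        stream = self._stream(z)
        epochs, _ = ft.epoch(stream, stream.frame_times[80:90])
        assert np.ptp(epochs) == 0.0


class TestPersistence:
    def test_round_trip(self, tmp_path, rng):
        z = rng.standard_normal((3, 50)).astype(np.float32).astype(float)
        stream = ft.FeatureStream(
            z=z, frame_times=0.127 + np.arange(50) * 0.016, frame_rate=62.5,
            channel_labels=["a", "b", "c"],
            roi=np.array(["vSMC", "STG", "vSMC"], dtype=object),
            baseline_frames=np.arange(5),
        )
        path = tmp_path / "f.h5"
        ft.save_features(stream, path)
        back = ft.load_features(path)
        np.testing.assert_allclose(back.z, stream.z, atol=1e-6)
        assert back.channel_labels == stream.channel_labels
        assert list(back.roi) == list(stream.roi)
        assert back.frame_rate == 62.5
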