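"""Causal high-gamma feature extraction, microphone voice-onset detection, epoching.

Features are computed in 128 ms analysis windows advanced by 16 ms (62.5
frames/s).  Each frame is stamped with the time of the LAST sample in its
window, so frame t depends only on samples at or before that time.  Spectral
log-power is z-scored per channel per frequency against a pooled baseline
(the union of frames whose window lies entirely within the 1 s before each
stimulus), band-averaged over 70-110 Hz, then re-z-scored per channel
against the same baseline frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import dsp
from .recording_io import Recording

WINDOW_S = 0.128
HOP_S = 0.016
FRAME_RATE = 1.0 / HOP_S  # 62.5 frames/s
HIGH_GAMMA_BAND = (70.0, 110.0)
EPOCH_HALF = 31          # frames on each side of the alignment frame
EPOCH_LEN = 2 * EPOCH_HALF + 1


@dataclass
class BaselineStats:
    """Pooled-baseline normalization constants.

    ``spec_mean``/``spec_sd`` are per channel per frequency bin over the
    log-power spectrogram; ``band_mean``/``band_sd`` are per channel over the
    band-averaged (already per-frequency-z-scored) feature.
    """

    spec_mean: np.ndarray  # (channels, bins)
    spec_sd: np.ndarray
    band_mean: np.ndarray  # (channels,)
    band_sd: np.ndarray
    baseline_frames: np.ndarray  # frame indices that defined the pool


@dataclass
class FeatureStream:
    """Normalized high-gamma stream: channels x frames at 62.5 frames/s."""

    z: np.ndarray                 # (channels, frames)
    frame_times: np.ndarray       # (frames,) time of last sample in each window
    frame_rate: float
    channel_labels: list[str]
    roi: np.ndarray
    baseline_frames: np.ndarray   # indices into the frame axis

    @property
    def n_frames(self) -> int:
        return self.z.shape[1]

    def frame_index(self, t: float) -> int:
        """Index of the frame whose timestamp is nearest ``t``."""
        return int(np.argmin(np.abs(self.frame_times - t)))


def stft_log_power(
    x: np.ndarray, rate: float, window_s: float = WINDOW_S, hop_s: float = HOP_S
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window log power spectrogram with a hamming taper.

    Returns ``(logpow, freqs, frame_times)`` where ``logpow`` has shape
    (channels, frames, bins) and ``frame_times[i]`` is the time of the last
    sample in window i. Frame count is ``floor((n - win)/hop) + 1``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    win = round(rate * window_s)
    hop = round(rate * hop_s)
    if x.shape[1] < win:
        raise ValueError("signal shorter than one analysis window")
    frames = np.lib.stride_tricks.sliding_window_view(x, win, axis=1)[:, ::hop, :]
    taper = np.hamming(win)
    spec = np.fft.rfft(frames * taper, axis=2)
    power = np.abs(spec) ** 2
    logpow = np.log(power + 1e-300)
    freqs = np.fft.rfftfreq(win, d=1.0 / rate)
    starts = np.arange(frames.shape[1]) * hop
    frame_times = (starts + win - 1) / rate
    return logpow.astype(np.float64), freqs, frame_times


def baseline_frame_indices(
    frame_times: np.ndarray,
    stimulus_onsets: np.ndarray,
    rate: float,
    window_s: float = WINDOW_S,
    pre_s: float = 1.0,
) -> np.ndarray:
    """Frames whose full analysis window lies within [onset - pre_s, onset)."""
    win_span = (round(rate * window_s) - 1) / rate
    start_times = frame_times - win_span
    mask = np.zeros(len(frame_times), dtype=bool)
    for onset in np.asarray(stimulus_onsets, dtype=float):
        mask |= (start_times >= onset - pre_s) & (frame_times < onset)
    return np.flatnonzero(mask)


def extract_high_gamma(
    recording: Recording,
    events: pd.DataFrame,
    band: tuple[float, float] = HIGH_GAMMA_BAND,
    window_s: float = WINDOW_S,
    hop_s: float = HOP_S,
) -> tuple[FeatureStream, BaselineStats]:
    """Normalized high-gamma feature stream for the non-excluded channels.

    Raises if no baseline frames exist or if any channel has zero baseline
    variance.
    """
    if recording.rate < 256:
        raise ValueError("sampling rate must be at least 256 Hz")
    keep = np.flatnonzero(~recording.excluded)
    logpow, freqs, frame_times = stft_log_power(
        recording.signal[keep], recording.rate, window_s, hop_s
    )
    bl = baseline_frame_indices(
        frame_times, events["stimulus_onset"].to_numpy(), recording.rate, window_s
    )
    if bl.size == 0:
        raise ValueError("no baseline frames: events start too early for a 1 s pre-stimulus pool")

    spec_mean = logpow[:, bl, :].mean(axis=1)
    spec_sd = logpow[:, bl, :].std(axis=1)
    zero_sd = np.flatnonzero((spec_sd <= 0).any(axis=1))
    if zero_sd.size:
        name = recording.channel_labels[keep[zero_sd[0]]]
        raise ValueError(f"zero baseline spectral SD on channel {name!r}")
    z_spec = (logpow - spec_mean[:, None, :]) / spec_sd[:, None, :]

    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError("no frequency bins inside the requested band")
    band_feat = z_spec[:, :, in_band].mean(axis=2)

    band_mean = band_feat[:, bl].mean(axis=1)
    band_sd = band_feat[:, bl].std(axis=1)
    zero_sd = np.flatnonzero(band_sd <= 0)
    if zero_sd.size:
        name = recording.channel_labels[keep[zero_sd[0]]]
        raise ValueError(f"zero baseline band SD on channel {name!r}")
    z = (band_feat - band_mean[:, None]) / band_sd[:, None]

    stream = FeatureStream(
        z=z,
        frame_times=frame_times,
        frame_rate=1.0 / hop_s,
        channel_labels=[recording.channel_labels[i] for i in keep],
        roi=recording.roi[keep].copy(),
        baseline_frames=bl,
    )
    stats = BaselineStats(spec_mean, spec_sd, band_mean, band_sd, bl)
    return stream, stats


def mic_voice_onsets(
    recording: Recording,
    events: pd.DataFrame,
    band: tuple[float, float] = (250.0, 450.0),
    threshold_sd: float = 5.0,
    smooth_s: float = 0.02,
) -> np.ndarray:
    """Per-trial voice-onset times from the microphone band power.

    The 250-450 Hz log band power of the mic track is causally smoothed and
    z-scored against the pooled 1 s pre-stimulus baseline; the first
    threshold crossing after each stimulus (and before the next trial)
    is that trial's onset. Log power keeps the baseline tail light so a
    5 SD threshold is conservative. Reported times are compensated for the
    smoother's centroid delay (never earlier than the stimulus). Trials
    with no crossing get NaN.
    """
    rate = recording.rate
    sos = dsp.bandpass_sos(band[0], band[1], rate)
    banded = sps.sosfilt(sos, recording.mic)
    # compensate the bandpass group delay at band center when reporting times
    b, a_coef = sps.sos2tf(sos)
    w, gd = sps.group_delay((b, a_coef), w=np.array([(band[0] + band[1]) / 2.0]), fs=rate)
    gd_s = float(gd[0]) / rate
    kernel = dsp.hamming_kernel(smooth_s, rate)
    power = np.log(dsp.causal_smooth(banded**2, kernel) + 1e-300)
    delay_s = dsp.kernel_delay(kernel) / rate

    onsets_stim = events["stimulus_onset"].to_numpy(dtype=float)
    t = np.arange(recording.n_samples) / rate
    bl_mask = np.zeros(recording.n_samples, dtype=bool)
    for onset in onsets_stim:
        bl_mask |= (t >= onset - 1.0) & (t < onset)
    if not bl_mask.any():
        raise ValueError("no pre-stimulus microphone baseline samples")
    mu, sd = power[bl_mask].mean(), power[bl_mask].std()
    if sd <= 0:
        raise ValueError("zero microphone baseline SD")
    zp = (power - mu) / sd
    band_rms = banded[bl_mask].std()

    bounds = np.append(onsets_stim[1:], t[-1] + 1.0 / rate)
    voice = np.full(len(onsets_stim), np.nan)
    for i, (a, b) in enumerate(zip(onsets_stim, bounds)):
        lo, hi = int(np.ceil(a * rate)), min(int(np.floor(b * rate)), recording.n_samples)
        if lo >= hi:
            continue
        hits = np.flatnonzero(zp[lo:hi] > threshold_sd)
        if not hits.size:
            continue
        cross = lo + hits[0]
        # refine: earliest strong raw band excursion just before the
        # (smoother-delayed) coarse crossing
        r0 = max(lo, cross - int(0.08 * rate))
        strong = np.flatnonzero(np.abs(banded[r0:cross + 1]) > 4.0 * band_rms)
        if strong.size:
            voice[i] = max((r0 + strong[0]) / rate - gd_s, a)
        else:
            voice[i] = max(cross / rate - delay_s, a)
    return voice


def save_features(stream: FeatureStream, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("features")
        g.create_dataset("z", data=stream.z.astype(np.float32))
        g.create_dataset("frame_times", data=stream.frame_times)
        g.create_dataset("baseline_frames", data=stream.baseline_frames)
        g.create_dataset("label", data=[s.encode() for s in stream.channel_labels])
        g.create_dataset("roi", data=[str(s).encode() for s in stream.roi])
        g.attrs["frame_rate"] = stream.frame_rate


def load_features(path) -> FeatureStream:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["features"]
        return FeatureStream(
            z=g["z"][()].astype(np.float64),
            frame_times=g["frame_times"][()],
            frame_rate=float(g.attrs["frame_rate"]),
            channel_labels=[s.decode() for s in g["label"][()]],
            roi=np.array([s.decode() for s in g["roi"][()]], dtype=object),
            baseline_frames=g["baseline_frames"][()],
        )


def epoch(
    stream: FeatureStream,
    align_times: np.ndarray,
    half_width: int = EPOCH_HALF,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract fixed-length windows centered on the frame nearest each align time.

    Returns ``(epochs, kept)``: epochs of shape (n_kept, channels, 2*half_width+1)
    and the indices of the align times that fit inside the stream. Align times
    that are NaN or whose window would overrun the stream are dropped.
    """
    align_times = np.asarray(align_times, dtype=float)
    L = 2 * half_width + 1
    kept, out = [], []
    for i, a in enumerate(align_times):
        if not np.isfinite(a):
            continue
        c = stream.frame_index(a)
        if c - half_width < 0 or c + half_width >= stream.n_frames:
            continue
        kept.append(i)
        out.append(stream.z[:, c - half_width : c + half_width + 1])
    if not out:
        return np.empty((0, stream.z.shape[0], L)), np.array([], dtype=int)
    return np.stack(out), np.array(kept, dtype=int)
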