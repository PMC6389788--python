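"""Ground-truthed synthetic sessions: neural channels, microphone track, events.

Sessions mimic block-randomized consonant-vowel syllable tasks: every block
presents each of the 12 utterances the same number of times in shuffled
order, with 2-3 s intertrial intervals.  Neural channels are pink noise plus
per-trial 70-110 Hz noise bursts whose amplitude and latency follow a
channel selectivity map (place of articulation coded by which channels
burst, consonant voicing by burst timing, vowel by relative amplitude on
auditory channels).  The microphone track carries a 250-450 Hz burst
starting at each trial's true voice onset.

Burst amplitudes are calibrated empirically so that a planted burst of
``burst_snr`` produces a high-gamma feature z-score of about that value.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from . import dsp
from .features import baseline_frame_indices, stft_log_power
from .recording_io import SYLLABLES, Recording, validate_events

PLACES = ("bilabial", "alveolar", "velar")
PLACE_OF = {s: PLACES["bdg ptk".replace(" ", "").index(s[1]) % 3] for s in SYLLABLES}
VOICED = {s: s[1] in "bdg" for s in SYLLABLES}
VOWEL_OF = {s: s[2] for s in SYLLABLES}  # 'a' or 'i'

NEURAL_BAND = (70.0, 110.0)
MIC_BAND = (250.0, 450.0)


class ConfigurationError(ValueError):
    """A simulator configuration cannot realize the requested effects."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic session.

    ``burst_snr`` is the target peak high-gamma feature z of planted bursts;
    ``voicing_shift`` is the burst-center timing difference between voiced
    and unvoiced trials on voicing-coding channels; ``vowel_contrast`` is
    the amplitude ratio of the non-preferred to preferred vowel on auditory
    vowel channels; ``mic_snr`` is the in-band power ratio of microphone
    bursts to microphone noise.
    """

    n_channels_vsmc: int = 12
    n_channels_stg: int = 6
    rate: float = 1000.0
    n_blocks: int = 2
    trials_per_block: int = 60
    iti_range: tuple[float, float] = (2.0, 3.0)
    stim_duration: float = 1.0
    response_latency_mean: float = 0.8
    response_latency_jitter: float = 0.1
    burst_snr: float = 5.0
    burst_duration: float = 0.4
    voicing_shift: float = 0.16
    vowel_contrast: float = 0.2
    mic_snr: float = 25.0
    common_mode_amp: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_block % len(SYLLABLES) != 0:
            raise ConfigurationError("trials_per_block must be divisible by 12")
        if self.rate < 500:
            raise ConfigurationError("rate must be >= 500 Hz (mic band below Nyquist)")
        for name in ("stim_duration", "burst_duration", "response_latency_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 < self.iti_range[0] <= self.iti_range[1]):
            raise ConfigurationError("iti_range must be positive and ordered")
        if self.n_channels_vsmc < 4:
            raise ConfigurationError(
                "need at least 4 vSMC channels (one per place of articulation plus "
                "one nonselective channel)"
            )
        if self.n_channels_stg < 0:
            raise ConfigurationError("n_channels_stg must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.n_channels_vsmc + self.n_channels_stg

    def session_id(self) -> str:
        h = hashlib.sha1(repr(self).encode()).hexdigest()[:12]
        return f"sim-{h}"


@dataclass
class SelectivityMap:
    """Per-channel effect profile: burst amplitude (feature-z units) and
    burst-center latency offset (s) for each of the 12 utterances."""

    amplitude: np.ndarray       # (channels, 12) target z
    latency_offset: np.ndarray  # (channels, 12) seconds
    roi: np.ndarray             # (channels,) str
    role: list[str]             # per channel: 'vad', place name, or 'vowel-a'/'vowel-i'


@dataclass
class GroundTruth:
    """The simulator's truth record for one session."""

    voice_onsets: np.ndarray     # (n_trials,) seconds, strictly increasing
    selectivity: SelectivityMap
    config: SimConfig


def syllable_effect_profiles(config: SimConfig) -> SelectivityMap:
    """Assign per-channel selectivity.

    Every fourth vSMC channel is nonselective ("VAD-like": bursts for every
    utterance, anchoring utterance timing); the others cycle over
    place-of-articulation preferences and code consonant voicing as a
    timing offset.  STG channels alternate between /a/- and /i/-preferring,
    with the non-preferred vowel scaled by ``vowel_contrast``.
    """
    n = config.n_channels
    amp = np.zeros((n, len(SYLLABLES)))
    lat = np.zeros((n, len(SYLLABLES)))
    roi = np.array(["vSMC"] * config.n_channels_vsmc + ["STG"] * config.n_channels_stg,
                   dtype=object)
    role: list[str] = []

    half_shift = config.voicing_shift / 2.0
    for c in range(config.n_channels_vsmc):
        if c % 4 == 0:
            role.append("vad")
            amp[c, :] = config.burst_snr
            continue
        place = PLACES[(c % 4) - 1]
        role.append(place)
        for j, s in enumerate(SYLLABLES):
            if PLACE_OF[s] == place:
                amp[c, j] = config.burst_snr
                lat[c, j] = -half_shift if VOICED[s] else half_shift

    for k in range(config.n_channels_stg):
        c = config.n_channels_vsmc + k
        pref = "a" if k % 2 == 0 else "i"
        role.append(f"vowel-{pref}")
        for j, s in enumerate(SYLLABLES):
            amp[c, j] = config.burst_snr * (1.0 if VOWEL_OF[s] == pref
                                            else config.vowel_contrast)
    return SelectivityMap(amplitude=amp, latency_offset=lat, roi=roi, role=role)


@lru_cache(maxsize=8)
def _gain_calibration(rate: float, burst_duration: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Map linear burst gain -> peak high-gamma feature z over pink noise.

    Plants hamming-enveloped band bursts of each candidate gain in pink
    noise, measures the resulting band-feature z at burst centers against a
    noise-only pooled baseline, and returns the (gain, z) grid for monotone
    interpolation.  Deterministic (fixed internal seed).
    """
    rng = np.random.default_rng(123456789)
    dur = 120.0
    n = int(dur * rate)
    spacing = 2.0
    centers = np.arange(3.0, dur - 3.0, spacing)
    env_n = round(burst_duration * rate)
    env = np.hamming(env_n)

    noise = dsp.pink_noise(n, rng)[0]
    logpow, freqs, frame_times = stft_log_power(noise, rate)
    in_band = (freqs >= NEURAL_BAND[0]) & (freqs <= NEURAL_BAND[1])
    # baseline windows fall between bursts: [center+0.5, center+1.5) stays
    # clear of the burst envelopes at center +- burst_duration/2
    bl = baseline_frame_indices(frame_times, centers + 1.5, rate)
    mu_f = logpow[0][bl].mean(axis=0)
    sd_f = logpow[0][bl].std(axis=0)

    def band_z(x: np.ndarray) -> np.ndarray:
        lp, _, _ = stft_log_power(x, rate)
        zf = (lp[0] - mu_f) / sd_f
        feat = zf[:, in_band].mean(axis=1)
        m, s = feat[bl].mean(), feat[bl].std()
        return (feat - m) / s

    carrier = dsp.bandlimited_noise(n, rate, *NEURAL_BAND, rng)
    gains = np.geomspace(0.05, 8.0, 14)
    zs = []
    for g in gains:
        x = noise.copy()
        for ctr in centers:
            i0 = int(ctr * rate) - env_n // 2
            x[i0 : i0 + env_n] += g * env * carrier[i0 : i0 + env_n]
        z = band_z(x)
        idx = [np.argmin(np.abs(frame_times - c)) for c in centers]
        zs.append(float(np.median(z[idx])))
    return tuple(gains.tolist()), tuple(zs)


def _gain_for_z(target_z: np.ndarray, rate: float, burst_duration: float) -> np.ndarray:
    gains, zs = _gain_calibration(rate, burst_duration)
    return np.interp(target_z, zs, gains, left=0.0)


def generate_session(config: SimConfig) -> tuple[Recording, pd.DataFrame, GroundTruth]:
    """Simulate one session: (Recording, EventTable, GroundTruth).

    Bit-identical outputs for identical configs (including seed).
    """
    rng = np.random.default_rng(config.seed)
    sel = syllable_effect_profiles(config)
    rate = config.rate
    n_trials = config.n_blocks * config.trials_per_block
    reps = config.trials_per_block // len(SYLLABLES)

    labels: list[str] = []
    blocks: list[int] = []
    for b in range(config.n_blocks):
        block_labels = list(SYLLABLES) * reps
        rng.shuffle(block_labels)
        labels.extend(block_labels)
        blocks.extend([b] * config.trials_per_block)

    lead_in, tail = 3.0, 3.0
    stim_onsets = np.empty(n_trials)
    t = lead_in
    for i in range(n_trials):
        stim_onsets[i] = t
        t += config.stim_duration + rng.uniform(*config.iti_range)
    latency = config.response_latency_mean + config.response_latency_jitter * rng.standard_normal(n_trials)
    latency = np.clip(latency, 0.2, config.response_latency_mean + 4 * config.response_latency_jitter)
    voice_onsets = stim_onsets + latency

    n_samples = int(np.ceil((stim_onsets[-1] + config.stim_duration + tail) * rate))
    n_ch = config.n_channels

    signal = dsp.pink_noise(n_samples, rng, n_rows=n_ch)
    if config.common_mode_amp > 0:
        signal += config.common_mode_amp * dsp.pink_noise(n_samples, rng)[0]

    gains = _gain_for_z(sel.amplitude, rate, config.burst_duration)
    env_n = round(config.burst_duration * rate)
    env = np.hamming(env_n)
    for i in range(n_trials):
        j = SYLLABLES.index(labels[i])
        for c in range(n_ch):
            g = gains[c, j]
            if g <= 0:
                continue
            ctr = voice_onsets[i] + sel.latency_offset[c, j]
            i0 = int(round(ctr * rate)) - env_n // 2
            if i0 < 0 or i0 + env_n > n_samples:
                continue
            carrier = dsp.bandlimited_noise(env_n, rate, *NEURAL_BAND, rng)
            signal[c, i0 : i0 + env_n] += g * env * carrier

    mic = rng.standard_normal(n_samples)
    band_fraction = (MIC_BAND[1] - MIC_BAND[0]) / (rate / 2.0)
    burst_sd = np.sqrt(config.mic_snr * band_fraction)
    mic_env_n = round(0.4 * rate)
    ramp = max(2, round(0.002 * rate))
    mic_env = np.ones(mic_env_n)
    mic_env[:ramp] = np.linspace(0, 1, ramp)
    mic_env[-ramp:] = np.linspace(1, 0, ramp)
    for i in range(n_trials):
        i0 = int(round(voice_onsets[i] * rate))
        if i0 + mic_env_n > n_samples:
            continue
        carrier = dsp.bandlimited_noise(mic_env_n, rate, *MIC_BAND, rng)
        mic[i0 : i0 + mic_env_n] += burst_sd * mic_env * carrier

    labels_arr = np.array(labels, dtype=object)
    recording = Recording(
        signal=signal,
        rate=rate,
        channel_labels=[f"{sel.roi[c]}-{c:03d}" for c in range(n_ch)],
        roi=sel.roi,
        excluded=np.zeros(n_ch, dtype=bool),
        mic=mic,
        session_id=config.session_id(),
    )
    events = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "stimulus_onset": stim_onsets,
            "label": labels_arr,
            "block": np.array(blocks),
            "voice_onset": np.full(n_trials, np.nan),
        }
    )
    validate_events(events)
    truth = GroundTruth(voice_onsets=voice_onsets, selectivity=sel, config=config)
    return recording, events, truth
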