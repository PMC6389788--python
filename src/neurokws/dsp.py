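"""Shared signal-processing primitives: causal smoothers, noise generators, bandpass filters."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps


def hamming_kernel(duration_s: float, rate: float) -> np.ndarray:
    """Unit-sum hamming window of ``round(duration_s * rate)`` taps (minimum 1)."""
    n = max(1, int(np.floor(duration_s * rate + 0.5)))  # 1.0 s @ 62.5 -> 63 taps
    k = np.hamming(n) if n > 1 else np.ones(1)
    return k / k.sum()


def causal_smooth(x: np.ndarray, kernel: np.ndarray, axis: int = -1) -> np.ndarray:
    """Causal FIR smoothing: output at t depends on inputs at t-len+1..t only.

    Group delay for a symmetric kernel is (len-1)/2 samples.
    """
    return sps.lfilter(kernel, [1.0], x, axis=axis)


def kernel_delay(kernel: np.ndarray) -> float:
    """Centroid delay of a causal FIR kernel, in samples."""
    return float(np.sum(np.arange(len(kernel)) * kernel) / np.sum(kernel))


def pink_noise(n_samples: int, rng: np.random.Generator, n_rows: int = 1) -> np.ndarray:
    """1/f-amplitude-shaped gaussian noise, unit variance per row. Shape (n_rows, n_samples)."""
    n_freq = n_samples // 2 + 1
    spec = rng.standard_normal((n_rows, n_freq)) + 1j * rng.standard_normal((n_rows, n_freq))
    f = np.arange(n_freq, dtype=float)
    f[0] = 1.0  # no DC blow-up
    spec /= np.sqrt(f)
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def bandpass_sos(low_hz: float, high_hz: float, rate: float, order: int = 4):
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate, output="sos")


def bandlimited_noise(
    n_samples: int,
    rate: float,
    low_hz: float,
    high_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-phase band-limited gaussian noise, normalized to unit standard deviation."""
    sos = bandpass_sos(low_hz, high_hz, rate)
    pad = min(n_samples, 4 * int(rate))
    x = rng.standard_normal(n_samples + pad)
    y = sps.sosfiltfilt(sos, x)[pad // 2 : pad // 2 + n_samples]
    sd = y.std()
    return y / sd if sd > 0 else y
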