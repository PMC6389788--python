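"""Spatiotemporal template construction and causal matched filtering.

A template is a channels x L (=63 frame, ~1 s) pattern. The *response*
template is the grand mean over all training epochs; a *discrimination*
template for a contrast is the condition mean minus the response template,
temporally smoothed (hamming, 0.1 s) and significance-masked (condition-mean
z < 3.0 zeroed). The *VAD* template is the response template restricted to
vSMC channels.

Filtering slides each template causally over the feature stream and emits,
per frame, the Pearson correlation between the template and the trailing
L-frame window, computed over the template's unmasked entries only. The
contrast series are smoothed with a causal hamming of 0.25 s; the VAD
series is the squared correlation smoothed with a causal hamming of 1.0 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from . import dsp
from .features import EPOCH_HALF, FRAME_RATE, FeatureStream
from .recording_io import SYLLABLES

TEMPLATE_SMOOTH_S = 0.1
OUTPUT_SMOOTH_S = 0.25
VAD_SMOOTH_S = 1.0
MASK_Z = 3.0

PLACE_CONTRASTS = {
    "bilabial": {"/ba/", "/pa/", "/bi/", "/pi/"},
    "alveolar": {"/da/", "/ta/", "/di/", "/ti/"},
    "velar": {"/ga/", "/ka/", "/gi/", "/ki/"},
}
VOICING_CONTRASTS = {
    "voiced": {s for s in SYLLABLES if s[1] in "bdg"},
    "unvoiced": {s for s in SYLLABLES if s[1] in "ptk"},
}
VOWEL_CONTRASTS = {
    "/a/": {s for s in SYLLABLES if s[2] == "a"},
    "/i/": {s for s in SYLLABLES if s[2] == "i"},
}


def contrast_definitions() -> dict[str, set[str]]:
    """The 19 contrasts: 12 keywords, 3 places, 2 voicings, 2 vowels."""
    out: dict[str, set[str]] = {s: {s} for s in SYLLABLES}
    out.update(PLACE_CONTRASTS)
    out.update(VOICING_CONTRASTS)
    out.update(VOWEL_CONTRASTS)
    return out


@dataclass
class TemplateSet:
    """Response, discrimination, and VAD templates over a fixed channel set."""

    channel_labels: list[str]
    roi: np.ndarray
    response: np.ndarray                       # (channels, L)
    discrimination: dict[str, np.ndarray]      # contrast -> (channels, L), masked
    masks: dict[str, np.ndarray]               # contrast -> bool (channels, L)
    vad: np.ndarray                            # (n_vsmc, L)
    vad_channels: np.ndarray                   # indices into the channel axis
    frame_rate: float = FRAME_RATE

    @property
    def length(self) -> int:
        return self.response.shape[1]

    @property
    def contrasts(self) -> list[str]:
        return list(self.discrimination)


@dataclass
class FilterOutputs:
    """Per-contrast correlation series and the VAD series on the input frame grid.

    ``y_delay_s`` / ``v_delay_s`` convert a peak frame time into the event
    (epoch-center) time it represents: window-center offset (31 frames) plus
    the causal smoother's centroid delay.
    """

    contrasts: list[str]
    y: np.ndarray              # (n_contrasts, frames)
    v: np.ndarray              # (frames,), >= 0
    frame_times: np.ndarray
    frame_rate: float
    y_delay_s: float
    v_delay_s: float
    baseline_frames: np.ndarray
    v_raw: np.ndarray | None = None       # squared correlation before VAD smoothing
    v_raw_delay_s: float = 0.0            # window-center offset only

    def frame_for_event_time(self, t: float) -> int:
        """Frame whose (delay-corrected) contrast output refers to event time ``t``."""
        return int(np.argmin(np.abs(self.frame_times - (t + self.y_delay_s))))

    def event_time_of_vad_frame(self, idx: int) -> float:
        return float(self.frame_times[idx] - self.v_delay_s)


def build_templates(
    train_epochs: np.ndarray,
    labels: np.ndarray,
    roi: np.ndarray,
    channel_labels: list[str] | None = None,
    mask_z: float = MASK_Z,
    smooth_s: float = TEMPLATE_SMOOTH_S,
    frame_rate: float = FRAME_RATE,
) -> TemplateSet:
    """Build the full template set from training epochs.

    Parameters
    ----------
    train_epochs : ndarray, (n_trials, channels, L)
        Response-window epochs of the normalized high-gamma stream.
    labels : array of str, (n_trials,)
        Utterance label per epoch.
    roi : array of str, (channels,)

    Notes
    -----
    The significance mask z-scores the condition mean against the pooled
    baseline: features are unit-variance over baseline frames, so the
    standard error of an n-trial condition mean is 1/sqrt(n) and the mask
    statistic is ``condition_mean * sqrt(n)``. Elements with z < ``mask_z``
    are zeroed. Smoothing is applied to (condition mean - response) before
    masking.
    """
    epochs = np.asarray(train_epochs, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if epochs.ndim != 3:
        raise ValueError("train_epochs must be (trials, channels, L)")
    if len(labels) != epochs.shape[0]:
        raise ValueError("labels length must match epoch count")
    if len(set(labels)) < 2:
        raise ValueError("need at least two conditions to build discrimination templates")

    response = epochs.mean(axis=0)
    kernel = dsp.hamming_kernel(smooth_s, frame_rate)

    discrimination: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for name, members in contrast_definitions().items():
        sel = np.isin(labels, list(members))
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"contrast {name!r} has no trials; omitted", stacklevel=2)
            continue
        cond = epochs[sel].mean(axis=0)
        mask = cond * np.sqrt(n) >= mask_z
        smoothed = dsp.causal_smooth(cond - response, kernel, axis=-1)
        discrimination[name] = np.where(mask, smoothed, 0.0)
        masks[name] = mask

    vad_channels = np.flatnonzero(np.asarray(roi, dtype=object) == "vSMC")
    if vad_channels.size == 0:
        raise ValueError("no vSMC channels available for the VAD template")
    vad = response[vad_channels]

    return TemplateSet(
        channel_labels=list(channel_labels) if channel_labels is not None
        else [f"ch{c}" for c in range(epochs.shape[1])],
        roi=np.asarray(roi, dtype=object),
        response=response,
        discrimination=discrimination,
        masks=masks,
        vad=vad,
        vad_channels=vad_channels,
        frame_rate=frame_rate,
    )


def save_templates(tset: TemplateSet, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("response", data=tset.response)
        f.create_dataset("vad", data=tset.vad)
        f.create_dataset("vad_channels", data=tset.vad_channels)
        f.create_dataset("label", data=[s.encode() for s in tset.channel_labels])
        f.create_dataset("roi", data=[str(s).encode() for s in tset.roi])
        f.attrs["frame_rate"] = tset.frame_rate
        gt = f.create_group("templates")
        gm = f.create_group("masks")
        for name in tset.contrasts:
            key = name.replace("/", "|")  # h5py treats '/' as a path separator
            gt.create_dataset(key, data=tset.discrimination[name])
            gm.create_dataset(key, data=tset.masks[name].astype(np.uint8))


def load_templates(path) -> TemplateSet:
    import h5py

    with h5py.File(path, "r") as f:
        return TemplateSet(
            channel_labels=[s.decode() for s in f["label"][()]],
            roi=np.array([s.decode() for s in f["roi"][()]], dtype=object),
            response=f["response"][()],
            discrimination={k.replace("|", "/"): v[()] for k, v in f["templates"].items()},
            masks={k.replace("|", "/"): v[()].astype(bool) for k, v in f["masks"].items()},
            vad=f["vad"][()],
            vad_channels=f["vad_channels"][()],
            frame_rate=float(f.attrs["frame_rate"]),
        )


def _sliding_pearson(
    z: np.ndarray, template: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Pearson correlation of template vs every trailing window of ``z``.

    Output length equals ``z.shape[1]``; frames earlier than L-1 are zero.
    Correlation is over unmasked entries only; zero-variance windows (or
    templates) give 0.
    """
    C, L = template.shape
    F = z.shape[1]
    if F < L:
        raise ValueError("stream shorter than the template")
    m = mask.astype(float)
    n_m = m.sum()
    if n_m < 2:
        return np.zeros(F)
    t_masked = np.where(mask, template, 0.0)
    t_mean = t_masked.sum() / n_m
    t_cent = np.where(mask, template - t_mean, 0.0)
    ss_t = (t_cent**2).sum()
    if ss_t <= 0:
        return np.zeros(F)

    # cross-correlation via per-channel convolution with the reversed kernel
    def corr(sig: np.ndarray, ker: np.ndarray) -> np.ndarray:
        out = fftconvolve(sig, ker[:, ::-1], mode="valid", axes=1)
        return out.sum(axis=0)

    num = corr(z, t_cent)                      # sum of t_cent * window
    s_w = corr(z, m)                           # masked window sum
    s_w2 = corr(z**2, m)                       # masked window sum of squares
    var_w = np.clip(s_w2 - s_w**2 / n_m, 0.0, None)
    denom = np.sqrt(ss_t * var_w)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 1e-12, num / denom, 0.0)
    out = np.zeros(F)
    out[L - 1 :] = r
    return out


def _sliding_boxcar(z: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Mean of every trailing window: the rectangular-template ablation.

    A constant template has no Pearson correlation, so the ablated filter
    reduces to plain rectangular smoothing of the feature stream.
    """
    C, L = shape
    F = z.shape[1]
    if F < L:
        raise ValueError("stream shorter than the template")
    ones = np.ones((C, L))
    s_w = fftconvolve(z, ones[:, ::-1], mode="valid", axes=1).sum(axis=0)
    out = np.zeros(F)
    out[L - 1 :] = s_w / (C * L)
    return out


def matched_filter(
    stream: FeatureStream,
    template_set: TemplateSet,
    ablate_rectangular: bool = False,
) -> FilterOutputs:
    """Causally filter a feature stream with a template set.

    Requires the stream's channels to match the template set's channel
    order (templates are built from the same selected-channel streams).
    """
    if stream.z.shape[0] != len(template_set.channel_labels):
        raise ValueError("stream channel count does not match template set")
    if stream.n_frames < template_set.length:
        raise ValueError("stream shorter than the template length")

    L = template_set.length
    frame_rate = stream.frame_rate
    out_kernel = dsp.hamming_kernel(OUTPUT_SMOOTH_S, frame_rate)
    vad_kernel = dsp.hamming_kernel(VAD_SMOOTH_S, frame_rate)

    names = template_set.contrasts
    y = np.empty((len(names), stream.n_frames))
    for i, name in enumerate(names):
        if ablate_rectangular:
            raw = _sliding_boxcar(stream.z, template_set.discrimination[name].shape)
        else:
            raw = _sliding_pearson(
                stream.z, template_set.discrimination[name], template_set.masks[name]
            )
        y[i] = dsp.causal_smooth(raw, out_kernel)

    zv = stream.z[template_set.vad_channels]
    if ablate_rectangular:
        raw_v = _sliding_boxcar(zv, template_set.vad.shape) ** 2
    else:
        raw_v = _sliding_pearson(
            zv, template_set.vad, np.ones_like(template_set.vad, dtype=bool)
        ) ** 2
    v = dsp.causal_smooth(raw_v, vad_kernel)

    hop = 1.0 / frame_rate
    y_delay = (EPOCH_HALF + dsp.kernel_delay(out_kernel)) * hop
    v_delay = (EPOCH_HALF + dsp.kernel_delay(vad_kernel)) * hop
    return FilterOutputs(
        contrasts=names,
        y=y,
        v=v,
        frame_times=stream.frame_times.copy(),
        frame_rate=frame_rate,
        y_delay_s=y_delay,
        v_delay_s=v_delay,
        baseline_frames=stream.baseline_frames.copy(),
        v_raw=raw_v,
        v_raw_delay_s=EPOCH_HALF * hop,
    )
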