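"""Session container I/O, channel bookkeeping, and spatial re-referencing.

A *session* bundles a multichannel neural recording, a synchronized
single-channel microphone track, per-channel metadata (label, region of
interest, excluded flag), and a per-trial event table.  Sessions persist
to a single HDF5 file::

    /signal    float32, channels x samples     attrs: (root) rate, session_id
    /mic       float32, samples
    /channels  group: label, roi, excluded
    /events    group: trial, stimulus_onset, label, block, voice_onset

Event tables round-trip to CSV as well.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

#: The 12 consonant-vowel utterance labels (place x voicing x vowel design).
SYLLABLES: tuple[str, ...] = (
    "/ba/", "/da/", "/ga/", "/pa/", "/ta/", "/ka/",
    "/bi/", "/di/", "/gi/", "/pi/", "/ti/", "/ki/",
)

ROIS: tuple[str, ...] = ("vSMC", "STG", "other")

EVENT_COLUMNS = ("trial", "stimulus_onset", "label", "block", "voice_onset")


class FormatError(ValueError):
    """A session container or event table violates the expected layout."""


@dataclass
class Recording:
    """Multichannel signal plus per-channel metadata and a microphone track.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Neural signal in microvolts.
    rate : float
        Sampling rate in Hz, shared by ``signal`` and ``mic``.
    channel_labels : list of str
    roi : ndarray of str
        Per-channel region tag, one of ``ROIS``.
    excluded : ndarray of bool
        Channels flagged as bad; they are carried along but ignored by
        referencing and downstream analysis.
    mic : ndarray, shape (n_samples,)
        Synchronized microphone track.
    session_id : str
        Opaque identifier used by train/test leakage guards.
    """

    signal: np.ndarray
    rate: float
    channel_labels: list[str]
    roi: np.ndarray
    excluded: np.ndarray
    mic: np.ndarray
    session_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.mic = np.asarray(self.mic, dtype=np.float64)
        self.roi = np.asarray(self.roi, dtype=object)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.signal.ndim != 2:
            raise FormatError("signal must be 2-D (channels x samples)")
        c = self.signal.shape[0]
        if not (len(self.channel_labels) == len(self.roi) == len(self.excluded) == c):
            raise FormatError("channel metadata length mismatch")
        if self.mic.shape != (self.signal.shape[1],):
            raise FormatError("mic length must equal signal length")
        if not self.rate > 0:
            raise FormatError("rate must be positive")
        bad = set(self.roi) - set(ROIS)
        if bad:
            raise FormatError(f"unknown roi tags: {sorted(bad)}")
        if self.excluded.all():
            raise FormatError("at least one channel must be non-excluded")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy(self) -> "Recording":
        return Recording(
            signal=self.signal.copy(),
            rate=self.rate,
            channel_labels=list(self.channel_labels),
            roi=self.roi.copy(),
            excluded=self.excluded.copy(),
            mic=self.mic.copy(),
            session_id=self.session_id,
        )


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check an event table against the schema; returns the table unchanged."""
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise FormatError(f"event table missing required column: {col!r}")
    onsets = events["stimulus_onset"].to_numpy(dtype=float)
    if len(onsets) and not np.all(np.diff(onsets) > 0):
        raise FormatError("stimulus onsets must be strictly increasing")
    bad = sorted(set(events["label"]) - set(SYLLABLES))
    if bad:
        raise FormatError(f"labels not in the utterance set: {bad}")
    return events


def write_session(recording: Recording, events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=recording.signal.astype(np.float32))
        f.create_dataset("mic", data=recording.mic.astype(np.float32))
        f.attrs["rate"] = float(recording.rate)
        f.attrs["session_id"] = recording.session_id
        g = f.create_group("channels")
        g.create_dataset("label", data=[s.encode() for s in recording.channel_labels])
        g.create_dataset("roi", data=[str(s).encode() for s in recording.roi])
        g.create_dataset("excluded", data=recording.excluded.astype(np.uint8))
        e = f.create_group("events")
        e.create_dataset("trial", data=events["trial"].to_numpy(dtype=np.int64))
        e.create_dataset("stimulus_onset", data=events["stimulus_onset"].to_numpy(dtype=float))
        e.create_dataset("label", data=[s.encode() for s in events["label"]])
        e.create_dataset("block", data=events["block"].to_numpy(dtype=np.int64))
        e.create_dataset("voice_onset", data=events["voice_onset"].to_numpy(dtype=float))


def read_session(path: str | Path) -> tuple[Recording, pd.DataFrame]:
    with h5py.File(path, "r") as f:
        for name in ("signal", "mic", "channels", "events"):
            if name not in f:
                raise FormatError(f"session container missing: {name!r}")
        if "rate" not in f.attrs:
            raise FormatError("session container missing: 'rate'")
        ch = f["channels"]
        for name in ("label", "roi", "excluded"):
            if name not in ch:
                raise FormatError(f"session container missing channel field: {name!r}")
        ev = f["events"]
        for name in EVENT_COLUMNS:
            if name not in ev:
                raise FormatError(f"session container missing event field: {name!r}")
        rec = Recording(
            signal=f["signal"][()].astype(np.float64),
            rate=float(f.attrs["rate"]),
            channel_labels=[s.decode() for s in ch["label"][()]],
            roi=np.array([s.decode() for s in ch["roi"][()]], dtype=object),
            excluded=ch["excluded"][()].astype(bool),
            mic=f["mic"][()].astype(np.float64),
            session_id=str(f.attrs.get("session_id", "")),
        )
        events = pd.DataFrame(
            {
                "trial": ev["trial"][()],
                "stimulus_onset": ev["stimulus_onset"][()],
                "label": [s.decode() for s in ev["label"][()]],
                "block": ev["block"][()],
                "voice_onset": ev["voice_onset"][()],
            }
        )
    validate_events(events)
    return rec, events


def events_to_csv(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)
    events.to_csv(path, index=False)


def events_from_csv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path)
    return validate_events(events)


def common_average_reference(recording: Recording) -> Recording:
    """Subtract the per-sample mean over non-excluded channels from each of them.

    Excluded channels pass through unchanged and stay flagged. The common
    average is computed over the *included* channels only, so exclusion must
    happen before referencing.
    """
    out = recording.copy()
    included = ~out.excluded
    if not included.any():
        raise ValueError("cannot re-reference: all channels excluded")
    mean = out.signal[included].mean(axis=0)
    out.signal[included] -= mean
    return out


def select_channels(
    recording: Recording,
    rois: Iterable[str] = ("vSMC", "STG"),
    manual_exclude: Sequence[str] = (),
) -> Recording:
    """Keep channels whose roi is in ``rois``, dropping excluded / manually named ones.

    Channel ordering is preserved. Raises if the retained set is empty.
    """
    rois = set(rois)
    unknown = rois - {"vSMC", "STG"}
    if unknown:
        raise ValueError(f"rois must be a subset of {{'vSMC', 'STG'}}, got {sorted(unknown)}")
    manual = set(manual_exclude)
    keep = [
        i
        for i in range(recording.n_channels)
        if recording.roi[i] in rois
        and not recording.excluded[i]
        and recording.channel_labels[i] not in manual
    ]
    if not keep:
        raise ValueError("channel selection retained no channels")
    return Recording(
        signal=recording.signal[keep].copy(),
        rate=recording.rate,
        channel_labels=[recording.channel_labels[i] for i in keep],
        roi=recording.roi[keep].copy(),
        excluded=recording.excluded[keep].copy(),
        mic=recording.mic.copy(),
        session_id=recording.session_id,
    )
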