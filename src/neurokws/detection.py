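"""Causal peak-picking on the VAD series, VAD metrics, threshold selection.

The VAD series is z-scored against its pooled-baseline frames so thresholds
are in SD units. After the z-scored series crosses a threshold upward, the
next downward turn of its first difference marks a detection; the detector
re-arms only once the series falls back below threshold (one detection per
super-threshold excursion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .templates import FilterOutputs

MATCH_TOLERANCE_S = 0.1
THRESHOLD_GRID = np.arange(0.0, 20.0 + 1e-9, 0.25)


@dataclass
class DetectionList:
    """Utterance detections in event-time (window-center) convention."""

    times: np.ndarray    # seconds, strictly increasing
    scores: np.ndarray   # z-scored VAD value at the detected peak
    threshold: float     # SD units

    def __len__(self) -> int:
        return len(self.times)


def zscore_vad(v: np.ndarray, baseline_frames: np.ndarray) -> np.ndarray:
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    if baseline_frames.size == 0:
        raise ValueError("baseline_frames must be non-empty")
    mu = v[baseline_frames].mean()
    sd = v[baseline_frames].std()
    if sd <= 0:
        raise ValueError("zero VAD baseline SD")
    return (v - mu) / sd


def quiet_baseline_frames(
    outputs: FilterOutputs,
    stimulus_onsets: np.ndarray,
    activity_span_s: float = 1.5,
) -> np.ndarray:
    """Pooled-baseline frames whose full causal support is utterance-free.

    The smoothed VAD value at frame t integrates roughly the trailing
    2 x v_delay seconds, so a pre-stimulus frame can still carry the tail of
    the previous utterance. Frames whose support overlaps
    [onset, onset + activity_span_s] of any trial are dropped; falls back to
    the full pooled baseline if nothing survives.
    """
    support = 2.0 * outputs.v_delay_s
    t = outputs.frame_times[outputs.baseline_frames]
    ok = np.ones(len(t), dtype=bool)
    for onset in np.asarray(stimulus_onsets, dtype=float):
        ok &= (t - support > onset + activity_span_s) | (t <= onset)
    kept = outputs.baseline_frames[ok]
    return kept if kept.size else outputs.baseline_frames


def causal_peak_pick(
    outputs: FilterOutputs,
    threshold_sd: float,
    baseline_frames: np.ndarray | None = None,
    refine: bool = True,
) -> DetectionList:
    """Pick utterance detections from the VAD series of ``outputs``.

    Detection times are reported in event time: the peak's frame time minus
    the filter's VAD delay (window-center offset plus smoother delay).
    When ``refine`` is set and the unsmoothed squared-correlation series is
    available, each detection time is sharpened to the raw series' argmax
    over the trailing smoother-length window (still causal: only frames at
    or before the picked peak are consulted).
    """
    if threshold_sd < 0:
        raise ValueError("threshold_sd must be >= 0")
    bl = outputs.baseline_frames if baseline_frames is None else np.asarray(baseline_frames)
    zv = zscore_vad(outputs.v, bl)
    peaks = _pick_peaks(zv, threshold_sd)
    smoother_len = max(1, int(round((outputs.v_delay_s - outputs.v_raw_delay_s)
                                    * 2 * outputs.frame_rate)))
    times = []
    for p in peaks:
        if refine and outputs.v_raw is not None:
            lo = max(0, p - smoother_len)
            k = lo + int(np.argmax(outputs.v_raw[lo : p + 1]))
            times.append(outputs.frame_times[k] - outputs.v_raw_delay_s)
        else:
            times.append(outputs.event_time_of_vad_frame(p))
    times = np.asarray(times, dtype=float)
    order = np.argsort(times, kind="stable")
    scores = np.asarray(zv[peaks], dtype=float)
    return DetectionList(times=times[order], scores=scores[order],
                         threshold=float(threshold_sd))


def _pick_peaks(zv: np.ndarray, threshold: float) -> list[int]:
    """One peak per super-threshold excursion: the first non-increasing step
    of the series after the upward crossing."""
    above = zv > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = (np.flatnonzero(edges == 1) + 1).tolist()
    if above[0]:
        starts.insert(0, 0)
    ends = np.flatnonzero(edges == -1).tolist()  # last above-threshold index of a run
    if above[-1]:
        ends.append(len(zv) - 1)
    peaks = []
    for s, e in zip(starts, ends):
        run = zv[s : e + 2]  # include one frame past the run for the final downturn
        d = np.diff(run)
        turn = np.flatnonzero(d <= 0)
        if turn.size:  # no downturn by end of data -> detection never confirmed
            peaks.append(s + int(turn[0]))
    return peaks


def match_detections(
    det_times: np.ndarray, true_onsets: np.ndarray, tol_s: float = MATCH_TOLERANCE_S
) -> tuple[int, int]:
    """Greedy injective matching of detections to true onsets.

    Each onset claims at most the earliest unclaimed detection within
    ±tol_s; every unclaimed detection counts as a false positive (including
    extra detections near an already-matched onset).
    """
    det_times = np.sort(np.asarray(det_times, dtype=float))
    claimed = np.zeros(len(det_times), dtype=bool)
    tp = 0
    for onset in np.sort(np.asarray(true_onsets, dtype=float)):
        cand = np.flatnonzero(~claimed & (np.abs(det_times - onset) <= tol_s))
        if cand.size:
            claimed[cand[0]] = True
            tp += 1
    fp = int((~claimed).sum())
    return tp, fp


def vad_performance(
    detections_by_threshold: dict[float, DetectionList] | dict[float, np.ndarray],
    true_onsets: np.ndarray,
    tol_s: float = MATCH_TOLERANCE_S,
) -> pd.DataFrame:
    """Sensitivity and false positives per utterance at each swept threshold."""
    true_onsets = np.asarray(true_onsets, dtype=float)
    true_onsets = true_onsets[np.isfinite(true_onsets)]
    if true_onsets.size == 0:
        raise ValueError("true_onsets must be non-empty")
    rows = []
    for thr in sorted(detections_by_threshold):
        det = detections_by_threshold[thr]
        times = det.times if isinstance(det, DetectionList) else np.asarray(det, dtype=float)
        tp, fp = match_detections(times, true_onsets, tol_s)
        rows.append(
            {
                "threshold": float(thr),
                "sensitivity": tp / len(true_onsets),
                "fp_per_utterance": fp / len(true_onsets),
            }
        )
    return pd.DataFrame(rows)


def sweep_vad(
    outputs: FilterOutputs,
    true_onsets: np.ndarray,
    thresholds: np.ndarray = THRESHOLD_GRID,
    tol_s: float = MATCH_TOLERANCE_S,
    baseline_frames: np.ndarray | None = None,
) -> pd.DataFrame:
    """Convenience: peak-pick at every threshold and tabulate performance."""
    dets = {
        float(t): causal_peak_pick(outputs, float(t), baseline_frames)
        for t in thresholds
    }
    return vad_performance(dets, true_onsets, tol_s)


def select_threshold_eer(curve: pd.DataFrame) -> float:
    """Threshold minimizing |miss rate - FP per utterance|; ties -> higher threshold."""
    if len(curve) == 0:
        raise ValueError("empty threshold curve")
    gap = np.abs((1.0 - curve["sensitivity"].to_numpy()) - curve["fp_per_utterance"].to_numpy())
    thr = curve["threshold"].to_numpy(dtype=float)
    best = gap.min()
    return float(thr[np.isclose(gap, best)].max())


def detections_to_csv(det: DetectionList, path) -> None:
    pd.DataFrame(
        {"time": det.times, "score": det.scores, "threshold": det.threshold}
    ).to_csv(path, index=False)
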