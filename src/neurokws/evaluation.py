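"""ROC/AUC with permutation-null significance and simulated keyword spotting."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import discrimination as disc
from .detection import MATCH_TOLERANCE_S, causal_peak_pick
from .discrimination import KeywordModel, PCAModel, TrainingPair
from .templates import FilterOutputs

THETA_GRID = np.arange(-10.0, 10.0 + 1e-9, 0.25)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    null_aucs: np.ndarray | None = None
    cutoff95: float | None = None


@dataclass
class KwsEvalState:
    """Everything needed to (re)train and score one keyword spotter.

    ``train_pc``/``test_pc`` are standardized PC series (frames, k);
    ``*_events`` carry block, label, stimulus_onset, align_time;
    ``*_frame_for_event_time`` map event times to PC-series rows.
    """

    train_pc: np.ndarray
    train_events: pd.DataFrame
    train_frame_for_event_time: object
    test_pc: np.ndarray
    test_events: pd.DataFrame
    test_frame_for_event_time: object
    C: float = 1.0
    n_epochs: int = 10
    seed: int = 0


def roc_auc(
    scores_positive: np.ndarray,
    scores_negative: np.ndarray,
    thresholds: np.ndarray = THETA_GRID,
) -> ROCResult:
    """ROC curve over the threshold sweep and rank-based AUC (ties count 1/2)."""
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)
    tpr = np.array([(pos > t).mean() for t in thresholds])
    fpr = np.array([(neg > t).mean() for t in thresholds])
    return ROCResult(thresholds=np.asarray(thresholds, dtype=float), tpr=tpr, fpr=fpr,
                     auc=float(auc))


def _scores_at(events: pd.DataFrame, pc: np.ndarray, frame_for, model: KeywordModel):
    times = events["align_time"].to_numpy(dtype=float)
    ok = np.isfinite(times)
    idx = [frame_for(t) for t in times[ok]]
    s = pc[idx] @ model.w
    labels = events["label"].to_numpy()[ok]
    return s, labels


def train_and_auc(
    state: KwsEvalState,
    keyword: str,
    train_labels: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
) -> tuple[KeywordModel, float]:
    """Train one keyword model on the training task, AUC on mic-aligned test onsets.

    ``train_labels``/``test_labels`` override the event-table labels
    (permutation-null machinery).
    """
    events = state.train_events
    if train_labels is not None:
        events = events.copy()
        events["label"] = np.asarray(train_labels, dtype=object)
    pairs = disc.build_training_pairs(
        state.train_pc, events, keyword, state.train_frame_for_event_time
    )
    model = disc.train_keyword_classifier(
        pairs, keyword=keyword, C=state.C, n_epochs=state.n_epochs, seed=state.seed
    )
    s, labels = _scores_at(
        state.test_events, state.test_pc, state.test_frame_for_event_time, model
    )
    if test_labels is not None:
        ok = np.isfinite(state.test_events["align_time"].to_numpy(dtype=float))
        labels = np.asarray(test_labels, dtype=object)[ok]
    result = roc_auc(s[labels == keyword], s[labels != keyword])
    return model, result.auc


def permute_labels_within_blocks(
    events: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle trial labels independently within each block (balance preserved)."""
    labels = events["label"].to_numpy(dtype=object).copy()
    blocks = events["block"].to_numpy()
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        labels[idx] = labels[idx[rng.permutation(len(idx))]]
    return labels


def bootstrap_null_auc(
    state: KwsEvalState,
    keyword: str,
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Null AUC distribution from scrambled-label retraining.

    Per rep: permute labels within blocks (independently in the training and
    test tasks, destroying every feature-label association), retrain the
    keyword classifier (templates and PCA fixed), and compute the test AUC
    under the permuted test labels. Returns (null AUCs, 95th percentile
    cutoff).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        perm_train = permute_labels_within_blocks(state.train_events, rng)
        perm_test = permute_labels_within_blocks(state.test_events, rng)
        _, null[r] = train_and_auc(
            state, keyword, train_labels=perm_train, test_labels=perm_test
        )
    return null, float(np.percentile(null, 95))


def keyword_roc(state: KwsEvalState, keyword: str, n_null: int = 0,
                null_seed: int = 0) -> tuple[KeywordModel, ROCResult]:
    """Convenience: model + ROC (and optional permutation null) for one keyword."""
    model, _ = train_and_auc(state, keyword)
    s, labels = _scores_at(
        state.test_events, state.test_pc, state.test_frame_for_event_time, model
    )
    result = roc_auc(s[labels == keyword], s[labels != keyword])
    if n_null > 0:
        result.null_aucs, result.cutoff95 = bootstrap_null_auc(
            state, keyword, n_reps=n_null, seed=null_seed
        )
    return model, result


@dataclass
class KWSReport:
    """Per-keyword simulated keyword-spotting outcome."""

    table: pd.DataFrame           # keyword, detection_fraction, false_per_utterance
    vad_threshold: float

    def to_json(self, path) -> None:
        payload = {
            "vad_threshold": self.vad_threshold,
            "keywords": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=2)


def simulate_kws(
    test_outputs: FilterOutputs,
    test_pc: np.ndarray,
    test_events: pd.DataFrame,
    models: dict[str, KeywordModel],
    vad_threshold: float,
    train_session_id: str,
    test_session_id: str,
    tol_s: float = MATCH_TOLERANCE_S,
    allow_leakage: bool = False,
    vad_baseline_frames: np.ndarray | None = None,
) -> KWSReport:
    """End-to-end simulated spotting: VAD detections classified per keyword.

    ``test_events`` needs columns label and align_time (true utterance
    onsets). Refuses to run when train and test session ids coincide unless
    ``allow_leakage`` (in-sample diagnostics) is set.
    """
    if train_session_id == test_session_id and not allow_leakage:
        raise ValueError(
            "train and test sessions are identical; refusing to simulate "
            "(pass allow_leakage=True for in-sample diagnostics)"
        )
    detections = causal_peak_pick(test_outputs, vad_threshold, vad_baseline_frames)
    if len(detections.times):
        det_vectors = np.array(
            [test_pc[test_outputs.frame_for_event_time(t)] for t in detections.times]
        )
    else:
        det_vectors = np.zeros((0, test_pc.shape[1]))

    times = test_events["align_time"].to_numpy(dtype=float)
    ok = np.isfinite(times)
    onsets, labels = times[ok], test_events["label"].to_numpy()[ok]
    n_utt = int(ok.sum())

    rows = []
    for kw, model in models.items():
        if det_vectors.size:
            flagged = det_vectors @ model.w > model.theta
        else:
            flagged = np.zeros(0, dtype=bool)
        kw_times = detections.times[flagged]
        kw_onsets = onsets[labels == kw]
        matched = np.zeros(len(kw_times), dtype=bool)
        hits = 0
        for onset in kw_onsets:
            cand = np.flatnonzero(~matched & (np.abs(kw_times - onset) <= tol_s))
            if cand.size:
                matched[cand[0]] = True
                hits += 1
        false_det = int((~matched).sum())
        rows.append(
            {
                "keyword": kw,
                "detection_fraction": hits / max(1, len(kw_onsets)),
                "false_per_utterance": false_det / max(1, n_utt),
            }
        )
    return KWSReport(table=pd.DataFrame(rows), vad_threshold=float(vad_threshold))


def plot_roc(result: ROCResult, path, title: str = "") -> None:
    """Write an ROC curve as SVG (headless backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    order = np.argsort(result.fpr)
    ax.plot(result.fpr[order], result.tpr[order], marker=".", lw=1)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title or f"AUC = {result.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
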