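"""PCA reduction of filter outputs and the online max-margin keyword classifier.

The classifier is trained from (keyword, competitor) pairs formed within
stimulus blocks: each keyword trial is paired with every non-keyword trial
of its block plus one silent-period vector (1 s before the keyword trial's
stimulus). Learning is an online passive-aggressive (PA-I) loop: for each
pair, the competitor is represented by the most keyword-like vector within
±6 frames of its alignment time under the current weights, and the weights
move just far enough to restore a unit margin, capped by aggressiveness C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

CONTEXT_FRAMES = 6           # +-100 ms at 62.5 frames/s
SILENT_OFFSET_S = 1.0
THETA_GRID = np.arange(-10.0, 10.0 + 1e-9, 0.25)


@dataclass
class PCAModel:
    mean: np.ndarray                      # (n_features,)
    components: np.ndarray                # (k, n_features)
    explained_variance_ratio: np.ndarray  # full spectrum
    k: int
    scale: np.ndarray                     # per-retained-component training SD


@dataclass
class KeywordModel:
    keyword: str
    w: np.ndarray
    theta: float = 0.0
    aggressiveness: float = 1.0


@dataclass
class TrainingPair:
    x_pos: np.ndarray        # (k,) keyword vector at its alignment frame
    x_neg_context: np.ndarray  # (2*CONTEXT_FRAMES+1, k) competitor context
    kind: str = "utterance"  # or "silence"


def fit_pca(y: np.ndarray, variance: float = 0.90) -> PCAModel:
    """Fit PCA over all frames of the training filter outputs.

    ``y`` is (n_features, n_frames); frames are samples. Retains the minimal
    k whose cumulative explained variance is >= ``variance``; retained
    scores are standardized by their training SD.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a (features, frames) array with at least 2 frames")
    X = y.T
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("filter outputs are constant; PCA undefined")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance - 1e-12) + 1)
    k = min(k, scores.shape[1])
    scale = scores[:, :k].std(axis=0)
    scale[scale <= 0] = 1.0
    return PCAModel(
        mean=pca.mean_,
        components=pca.components_[:k],
        explained_variance_ratio=pca.explained_variance_ratio_,
        k=k,
        scale=scale,
    )


def transform(y: np.ndarray, model: PCAModel) -> np.ndarray:
    """Project (features, frames) filter outputs to standardized PC series (frames, k)."""
    X = np.asarray(y, dtype=float).T
    return (X - model.mean) @ model.components.T / model.scale


def build_training_pairs(
    pc_series: np.ndarray,
    events: pd.DataFrame,
    keyword: str,
    frame_for_event_time,
    context_frames: int = CONTEXT_FRAMES,
) -> list[TrainingPair]:
    """Form within-block (keyword, competitor) training pairs.

    ``events`` needs columns block, label, stimulus_onset, align_time (NaN
    drops the trial).  ``frame_for_event_time`` maps an event time to a row
    of ``pc_series`` (frames, k).  Per block: every keyword trial is paired
    with every non-keyword trial of that block, plus one silent-period
    competitor centered 1 s before the keyword trial's stimulus onset.
    Competitors carry their ±``context_frames`` frame context.
    """
    n_frames = pc_series.shape[0]

    def context_at(t: float) -> np.ndarray | None:
        c = frame_for_event_time(t)
        lo, hi = c - context_frames, c + context_frames + 1
        if lo < 0 or hi > n_frames:
            return None
        return pc_series[lo:hi]

    pairs: list[TrainingPair] = []
    usable = events[np.isfinite(events["align_time"].to_numpy(dtype=float))]
    for block, ev in usable.groupby("block"):
        kw = ev[ev["label"] == keyword]
        non = ev[ev["label"] != keyword]
        if len(kw) == 0:
            warnings.warn(f"keyword {keyword!r} absent from block {block}; no pairs",
                          stacklevel=2)
            continue
        for _, kw_row in kw.iterrows():
            x_pos = pc_series[frame_for_event_time(kw_row["align_time"])]
            for _, non_row in non.iterrows():
                ctx = context_at(non_row["align_time"])
                if ctx is not None:
                    pairs.append(TrainingPair(x_pos, ctx, "utterance"))
            silent_t = kw_row["stimulus_onset"] - SILENT_OFFSET_S
            ctx = context_at(silent_t)
            if ctx is not None:
                pairs.append(TrainingPair(x_pos, ctx, "silence"))
    return pairs


def train_keyword_classifier(
    pairs: list[TrainingPair],
    keyword: str = "",
    C: float = 1.0,
    n_epochs: int = 10,
    seed: int = 0,
    loss_tol: float = 1e-9,
) -> KeywordModel:
    """Online PA-I training over shuffled pairs.

    Per pair: competitor x- is the context row maximizing w·x; hinge loss
    l = max(0, 1 - w·x+ + w·x-); update w += tau (x+ - x-) with
    tau = min(C, l / ||x+ - x-||^2). Runs ``n_epochs`` epochs (re-shuffled
    each epoch from ``seed``) with early stop when epoch loss plateaus.
    """
    if not pairs:
        raise ValueError("no training pairs")
    rng = np.random.default_rng(seed)
    dim = pairs[0].x_pos.shape[0]
    w = np.zeros(dim)
    prev_loss = np.inf
    for _ in range(n_epochs):
        order = rng.permutation(len(pairs))
        total = 0.0
        for idx in order:
            p = pairs[idx]
            x_neg = p.x_neg_context[int(np.argmax(p.x_neg_context @ w))]
            loss = max(0.0, 1.0 - float(w @ p.x_pos) + float(w @ x_neg))
            total += loss
            if loss <= 0.0:
                continue
            d = p.x_pos - x_neg
            n2 = float(d @ d)
            if n2 == 0.0:
                warnings.warn("degenerate pair (x+ == x-) skipped", stacklevel=2)
                continue
            w = w + min(C, loss / n2) * d
        if total <= loss_tol or abs(prev_loss - total) <= loss_tol * max(1.0, prev_loss):
            break
        prev_loss = total
    return KeywordModel(keyword=keyword, w=w, theta=0.0, aggressiveness=C)


def score(model: KeywordModel, x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.shape != model.w.shape:
        raise ValueError(f"feature dimension {x.shape} != model dimension {model.w.shape}")
    return float(model.w @ x)


def classify(model: KeywordModel, x: np.ndarray, theta: float | None = None) -> bool:
    thr = model.theta if theta is None else theta
    return score(model, x) > thr


def hinge_loss(w: np.ndarray, pair: TrainingPair) -> float:
    x_neg = pair.x_neg_context[int(np.argmax(pair.x_neg_context @ w))]
    return max(0.0, 1.0 - float(w @ pair.x_pos) + float(w @ x_neg))
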