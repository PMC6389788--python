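"""Shared fixtures: synthetic sessions and a fully trained pipeline state.

The heavy train/test pair (2 blocks x 60 trials each) is built once per
session and shared by the acceptance tests and several module tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from neurokws import (
    detection as det,
    discrimination as disc,
    evaluation as ev,
    features as ft,
    recording_io as rio,
    templates as tpl,
)
from neurokws.synthetic_ecog import GroundTruth, SimConfig, generate_session

TRAIN_SEED = 101
TEST_SEED = 202


@dataclass
class TaskData:
    recording: rio.Recording
    events: pd.DataFrame          # includes align_time (mic onsets)
    stream: ft.FeatureStream
    truth: GroundTruth
    outputs: tpl.FilterOutputs = None
    vad_baseline: np.ndarray = None
    pc: np.ndarray = None


@dataclass
class Pipeline:
    train: TaskData
    test: TaskData
    templates: tpl.TemplateSet
    pca: disc.PCAModel
    state: ev.KwsEvalState
    train_path: str
    test_path: str


def _prepare(seed: int) -> TaskData:
    rec, events, truth = generate_session(SimConfig(seed=seed))
    rec = rio.common_average_reference(rec)
    rec = rio.select_channels(rec)
    stream, _ = ft.extract_high_gamma(rec, events)
    events = events.copy()
    events["voice_onset"] = ft.mic_voice_onsets(rec, events)
    events["align_time"] = events["voice_onset"]
    return TaskData(recording=rec, events=events, stream=stream, truth=truth)


@pytest.fixture(scope="session")
def pipeline(tmp_path_factory) -> Pipeline:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train = _prepare(TRAIN_SEED)
        test = _prepare(TEST_SEED)

        d = tmp_path_factory.mktemp("sessions")
        train_path, test_path = str(d / "train.h5"), str(d / "test.h5")
        raw_train, ev_train, _ = generate_session(SimConfig(seed=TRAIN_SEED))
        raw_test, ev_test, _ = generate_session(SimConfig(seed=TEST_SEED))
        rio.write_session(raw_train, ev_train, train_path)
        rio.write_session(raw_test, ev_test, test_path)

        epochs, kept = ft.epoch(train.stream, train.events["align_time"].to_numpy())
        tset = tpl.build_templates(
            epochs,
            train.events["label"].to_numpy()[kept],
            train.stream.roi,
            channel_labels=train.stream.channel_labels,
        )
        for task in (train, test):
            task.outputs = tpl.matched_filter(task.stream, tset)
            task.vad_baseline = det.quiet_baseline_frames(
                task.outputs, task.events["stimulus_onset"].to_numpy()
            )
        pca = disc.fit_pca(train.outputs.y)
        train.pc = disc.transform(train.outputs.y, pca)
        test.pc = disc.transform(test.outputs.y, pca)
        state = ev.KwsEvalState(
            train_pc=train.pc,
            train_events=train.events,
            train_frame_for_event_time=train.outputs.frame_for_event_time,
            test_pc=test.pc,
            test_events=test.events,
            test_frame_for_event_time=test.outputs.frame_for_event_time,
        )
    return Pipeline(train=train, test=test, templates=tset, pca=pca, state=state,
                    train_path=train_path, test_path=test_path)


@pytest.fixture(scope="session")
def tiny_session():
    """One 24-trial block, small channel count: fast material for unit tests."""
    cfg = SimConfig(n_channels_vsmc=8, n_channels_stg=2, n_blocks=1,
                    trials_per_block=24, seed=7)
    rec, events, truth = generate_session(cfg)
    return cfg, rec, events, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
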