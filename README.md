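# neurokws

Neural keyword spotting from multichannel electrophysiology, as a tested
library and CLI. The pipeline is a causal two-stage detector:

1. **Neural voice-activity detection (VAD)** — normalized high-gamma
   (70–110 Hz) features are cross-correlated with a spatiotemporal
   "response" template (sensorimotor channels only); a causal peak-picker
   on the smoothed squared correlation marks utterance times.
2. **Keyword discrimination** — 19 significance-masked discrimination
   templates (12 keywords + place / voicing / vowel contrasts) are
   correlated with the feature stream, reduced by PCA (90 % variance), and
   an online max-margin (passive-aggressive) classifier decides keyword vs
   non-keyword at each detected utterance.

Everything is trained on one session and applied frozen to a second
session; the only per-task quantity is the pooled-baseline feature
normalization. A fully ground-truthed synthetic session generator
(`neurokws.synthetic_ecog`) provides block-randomized consonant-vowel
sessions with planted high-gamma bursts and a microphone track, so the
whole pipeline can be exercised and validated end to end without any
recordings.

## Layout

| module | contents |
| --- | --- |
| `neurokws.synthetic_ecog` | `SimConfig`, selectivity maps, `generate_session` |
| `neurokws.recording_io` | HDF5 session container, event tables, common-average referencing, channel selection |
| `neurokws.features` | causal 128 ms/16 ms high-gamma z-features, microphone voice onsets, epoching |
| `neurokws.templates` | response / discrimination / VAD template building, causal matched filtering (plus the rectangular-window ablation) |
| `neurokws.detection` | causal peak-picking, VAD sensitivity/false-positive curves, equal-error-rate threshold selection |
| `neurokws.discrimination` | PCA reduction, within-block training pairs, PA-I online classifier |
| `neurokws.evaluation` | ROC/AUC, scrambled-label permutation null, simulated keyword spotting |
| `neurokws.pipeline_cli` | `PipelineConfig`, `run_pipeline`, and the `neurokws` CLI |

## CLI

```sh
neurokws simulate --config sim.yaml --out train.h5 --seed 101
neurokws simulate --config sim.yaml --out test.h5  --seed 202
cat > pipeline.yaml <<EOF
train_session: train.h5
test_session: test.h5
EOF
neurokws run-all --config pipeline.yaml --out runs/demo
```

`run-all` writes templates, models, detections, VAD curves, ROC/KWS
reports, a manifest, and a run log under `--out`. `simulate | features |
train-templates | filter | vad | train-kws | evaluate | simulate-kws`
expose the individual stages.

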