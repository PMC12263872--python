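# swarmspeech

A speech-based depression-screening toolkit: MFCC feature extraction
implemented from first principles, swarm-intelligence wrapper feature
selection (dragonfly, firefly and moth-flame optimizers), a 1D CNN + LSTM
binary classifier written in pure NumPy, and macro-averaged
precision/recall/F1 evaluation.  Because the clinical corpora this kind of
screening is studied on are access-restricted, the package ships a
synthetic-data module that generates two-class audio (classes differing in
pitch level, pitch variability, energy-modulation rate and pause fraction)
and labeled feature tables with a known informative subset, so every stage
is testable offline end to end.

## Layout

| module | purpose |
|---|---|
| `swarmspeech.audio_features` | WAV loading, pre-emphasis, framing, power spectrum, Mel filterbank, log energies, DCT cepstra, recording-level functionals |
| `swarmspeech.optimizers` | dragonfly / firefly / moth-flame continuous minimizers behind one `optimize()` interface |
| `swarmspeech.feature_selection` | threshold mask decoding, cross-validated wrapper fitness, swarm-driven subset search |
| `swarmspeech.classifier` | CNN-LSTM model spec, NumPy layers with hand-written backprop, Adam training with early stopping |
| `swarmspeech.metrics` | confusion counts, per-class and macro precision/recall/F1 |
| `swarmspeech.synthetic_data` | deterministic two-class audio and feature-table generators |
| `swarmspeech.pipeline` / `swarmspeech.cli` | YAML config, stratified splitting, full-run orchestration, `swarmspeech` CLI |

## CLI

```bash
# synthetic data
swarmspeech simulate audio --seed 1 --out data/audio --n-per-class 60
swarmspeech simulate table --seed 1 --out data/tbl --d 30 --k 5 --delta 2

# stage by stage
swarmspeech extract --manifest data/audio/manifest.csv --out features.csv
swarmspeech select --table data/tbl/table.csv --out mask.txt --seed 1
swarmspeech train --features data/audio/manifest.csv --mask mask.txt --seed 1
swarmspeech evaluate --y-true true.txt --y-pred pred.txt

# full pipeline (simulate -> extract -> select -> train -> evaluate)
swarmspeech run --config config.yaml --seed 1 --out run_dir
```

`swarmspeech run` with no config uses the package defaults (firefly
selection, 13 MFCCs, 60 simulated recordings per class) and writes
`report.json`, `selected_features.txt` and `fitness_history.csv` into the
output directory.  A config file is a YAML document with sections `mfcc`,
`optimizer`, `selection`, `model`, `training`, `simulate`, `io` and a
global `seed`; unknown keys are rejected.  Example:

```yaml
seed: 1
optimizer: {kind: firefly, pop_size: 15, n_iter: 30}
model: {conv_filters: [8, 16, 32], lstm_units: [16, 8], t_fixed: 256}
training: {epochs: 15}
simulate: {n_per_class: 60}
```

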