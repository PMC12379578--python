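# megspeech

Decoding *yes* vs. *no* from magnetoencephalography (MEG) during
spontaneous, self-paced speech — as a fully synthetic, fully tested
pipeline. The package is aimed at neural-decoding researchers and BCI
method developers who need a reproducible desk-scale testbed for the
complete analysis chain: continuous-data cleaning, acoustic event
detection, three-phase trial epoching, and binary word decoding under a
temporally ordered evaluation protocol.

## What it implements

A participant utters *yes*/*no* about once every 4–5 s (≥80 repetitions
per word) while MEG (gradiometers + EOG/ECG references) and audio are
recorded. Each utterance of acoustic span `[onset, offset)` (length L)
yields three equal-length windows on the MEG axis:

* **intended** speech: `[onset − L, onset)`
* **overt** speech: `[onset, onset + L)`
* **postspeech**: `[offset, offset + L)`

The pipeline:

1. **Synthesis** (`megspeech.synth`) — seeded sessions with 1/f sensor
   noise, 60 Hz line harmonics, blink/cardiac artifacts, class-dependent
   focal spatiotemporal patterns per phase, and a synchronized audio
   track; ground-truth event tables included.
2. **Preprocessing** (`megspeech.preprocess`) — zero-phase 4th-order
   Butterworth low-pass at 250 Hz, notch bank at 60 Hz and harmonics,
   robust bad-channel exclusion, and FastICA artifact removal validated
   against the EOG/ECG channels.
3. **Events** (`megspeech.speech_events`) — Wiener denoising, energy VAD
   with hangover yielding sample-accurate onsets/offsets, ground-truth
   overlap labeling, and a TOST equivalence test of yes/no durations.
4. **Decoders** — `RmsLdaDecoder`: per-channel RMS features + LDA with
   diagonal shrinkage `Σ = (1−γ)Σ̂ + γ diag(Σ̂)` and optional coefficient
   thresholding, tuned by Gaussian-process Bayesian optimization;
   `SpeechCNN`: conv(32, k5)–ReLU–norm → conv(64, k5)–ReLU–norm → global
   average pooling → FC(2) → softmax, Adam, grid-searched learning rate —
   implemented in pure numpy with a hand-verified backward pass. Both are
   scikit-learn-style estimators accepting ragged trial lists and
   per-example weights.
5. **Evaluation** (`megspeech.evaluate`) — temporal 70/30 split, fourfold
   CV on contiguous blocks repeated via Bayesian-bootstrap (flat-Dirichlet)
   example weights, accuracy, t-tests vs. chance, paired decoder
   comparison, one-way ANOVA + Tukey HSD across phases.

## Worked example

```bash
$ cat > study.json <<'JSON'
{"session": {"n_channels_grad": 32, "n_reps_per_word": 12,
             "inter_word_interval": [2.0, 2.5]},
 "settings": {"cnn_params": {"learning_rate": 0.003, "max_epochs": 8,
                             "batch_size": 8}, "ica_n_components": 10}}
JSON
$ megspeech synth --config study.json --seed 3 --out session.h5
wrote 34 channels x 57886 samples, 24 events -> session.h5
$ megspeech events --session session.h5 --out events.csv
detected 24 segments, labeled 24 -> events.csv
$ megspeech decode --session session.h5 --events events.csv \
    --seed 3 --no-cv --out report.json
intended  lda  test acc 0.500
intended  cnn  test acc 0.250
overt     lda  test acc 1.000
overt     cnn  test acc 0.750
post      lda  test acc 0.750
post      cnn  test acc 0.750
```

The session here is deliberately tiny (24 trials, 8 test trials per
phase, 8 CNN epochs), so single accuracies are noisy; the overt phase —
carrying the strongest injected pattern (effect size 1.5 vs. 0.9 post and
0.6 intended) — is nonetheless decoded best, and `report.json` holds the
full machine-readable report (per-phase accuracies, binomial p-values vs.
chance, duration-equivalence test, analysis settings). At study scale
(`megspeech.studies`, 64 channels, 80 repetitions per word) the same
pipeline yields the expected signature: CNN test accuracy ordered
overt > post > intended with overt ≥ 0.85, and a significant phase ANOVA,
while zero-effect sessions stay at chance.

`megspeech simulate-study --config study.json --n-sessions 5 --seed 0
--out study_report.json` runs generation + full analysis across sessions
("participants") and reports across-session statistics (t vs. chance,
CNN−LDA paired t, phase ANOVA).

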