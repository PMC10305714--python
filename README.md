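# driveact

Classification of primary and secondary car-driver activities from
smart-glasses sensor data (4 EOG channels + 3-axis accelerometer), built as a
fully reproducible pipeline on synthetic recordings:

1. **`driveact.synthetic`** — generates labeled EOG/IMU recordings for 16
   activity classes (crossroad/parking/roundabout maneuvers plus 4
   distracting activities) from a fixed per-class event grammar: saccades,
   blinks, head/trunk motion templates, with configurable powerline hum,
   baseline drift, spikes and sensor noise.
2. **`driveact.jins_io`** — reads/writes the JINS MEME ES_R CSV dialect
   (parameter rows, `dd.mm.rrrr:hh:mm:ss` dates, 200 Hz EOG / 100 Hz ACC
   interleaving) and houses the 16-class label vocabulary.
3. **`driveact.preprocess`** — zero-phase Butterworth low-pass + differencing
   for EOG, median + Hamming-FIR smoothing for acceleration, decimation to a
   common 50 Hz rate, per-channel z-scoring, then either whole-recording
   resampling to a fixed length or 280/140 sliding windows.
4. **`driveact.cnn`** — a 1D CNN (3 conv blocks of 128×5 filters with batch
   norm, one max-pool, global average pooling, dropout 0.4, softmax dense),
   trained with Adam (batch 32, lr 2e-4) on categorical cross-entropy.
   Implemented directly on NumPy (im2col convolutions, hand-written backprop),
   so training is exactly reproducible from a seed with no framework
   dependency.
5. **`driveact.evaluation`** — confusion matrix, per-class and type-level
   (Crossroad/Parking/Roundabout/Secondary) precision/recall/F1, weighted
   averages, binary primary-vs-secondary accuracy, PCA embedding.
6. **`driveact.pipeline`** — one-config orchestration with seeded provenance
   and content-hash caching.

## CLI

```bash
driveact generate   --config cfg.yaml --out data/          # synthetic dataset as JINS CSVs
driveact preprocess --config cfg.yaml --in data/manifest.tsv --out prep/
driveact train      --config cfg.yaml --data prep/ --out run/
driveact evaluate   --model run/model --data prep/ --split run/split.json
driveact run-all    --config cfg.yaml --out run/           # end to end
driveact convert    rec.csv plain.csv [--to-jins]          # dialect conversion
```

The YAML config mirrors `driveact.pipeline.RunConfig` with sections
`synthetic`, `preproc`, `model`, `split` (all fields optional; defaults match
the study setup: 1200 primary + 700 secondary recordings, 50 Hz sync, 3000-
sample inputs, 16 classes, 100 epochs).

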