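# wristhr

Heart-rate reconstruction from motion-corrupted wrist PPG.

Wrist-worn PPG is easily corrupted by arm, wrist and finger movement.
`wristhr` implements a two-stage pipeline that keeps producing a usable HR
estimate anyway: every 6-s window of wristband data (PPG @ 20 Hz, 3-axis
accelerometer + gyroscope @ 10 Hz, skin temperature @ 0.1 Hz) is first
classified into one of three activity groups, and the window is then routed
to the HR estimator that works best for that group:

| predicted group | estimator |
| --- | --- |
| 1 — rest | dominant spectral peak of the band-passed PPG (0.6–3 Hz) |
| 2 — finger movement (read / write) | B1: Gaussian-process regressor |
| 3 — displacement (walking) | B2: bagged-trees regressor |

The regressors are trained on z-normalized statistical features
(63 columns: 18 from PPG, 15 each from accelerometer norm, gyroscope norm
and temperature), with NCA feature weighting for the classifier (top 9) and
regression ReliefF for the regressors (top 15). Ground-truth HR labels come
from a chest-strap reference ECG (Pan–Tompkins QRS detection → tachogram →
60/IBI), aligned to the wristband via accelerometer cross-correlation.

Because no public dataset accompanies the method, the package ships a
first-class synthetic session simulator (`wristhr.simulate`): a Beer–Lambert
optical model whose exponent combines the cardiac pulse train, baseline
drift, a mechanical artifact driven by wrist acceleration and a vascular
artifact driven by finger-movement bursts that are invisible to the wrist
IMU, plus a lag-coupled skin-temperature channel and a synthesized reference
ECG. Everything is deterministic given the seeds.

## CLI

Five verbs cover the full workflow:

```sh
wristhr simulate   --users 10 --seed 0 --out sessions/ [--protocol proto.yaml]
wristhr featurize  --sessions sessions/ --config cfg.yaml --out table.csv
wristhr train      --table table.csv --config cfg.yaml --out bundle/
wristhr reconstruct --session sessions/user09 --bundle bundle/ --out recon.csv
wristhr evaluate   --result recon.csv --out report.json
```

`cfg.yaml` overrides any `PipelineConfig` field (window length/hop, band
edges, feature counts, ensemble sizes, seed, …). Sessions are plain CSV
directories plus `meta.json`; window tables are CSV files with 63 feature
columns and the `label_hr` / `label_task` columns.

## Layout

```
src/wristhr/
  simulate.py          synthetic session generator (protocol, physiology,
                       Beer–Lambert artifact model)
  session_io.py        PipelineConfig, session/table CSV persistence
  preprocess.py        baseline removal, IMU vector norms, PPG band-pass +
                       FIR smoothing, 6-s windowing with labels
  ground_truth.py      Pan–Tompkins QRS detection, tachogram HR,
                       cross-device synchronization
  features.py          63-column per-window feature battery, z-normalization
  select.py            NCA and RReliefF feature ranking
  models.py            70/30 split, AdaBoost classifier, GP + bagged-tree
                       regressors, bundle (de)serialization
  reconstruct_eval.py  class-routed reconstruction, metrics, FFT-only baseline
  pipeline.py, cli.py  orchestration and the command-line interface
```
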