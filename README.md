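# semgimg

Gesture recognition from **instantaneous high-density sEMG images**.

At every sampling instant, the voltages of an HD-sEMG electrode grid are
arranged by electrode position and linearly mapped from [−2.5 mV, 2.5 mV]
to a grayscale intensity image. Single frames are classified with a small
convolutional network (or with classical baselines on the raw instantaneous
channel vectors), and per-frame decisions are pooled by majority voting
over a trailing window, trading observational latency for accuracy.
A fully seeded synthetic HD-sEMG generator makes the entire pipeline
testable without any external data.

## Package layout

| module | contents |
| --- | --- |
| `semgimg.grid` | `ElectrodeGrid`, `IntensityMap`, `Recording`, `SemgImage`; image/difference-image/vector construction, jet and RGB colouring, PNG/HDF5 export |
| `semgimg.preprocess` | 45–55 Hz band-stop (power-line), full-wave rectification, 75 Hz envelope low-pass, MVC normalization, 3×3 spatial median, decimation, ±1-row circular shift augmentation, RMS maps, declarative pipelines |
| `semgimg.convnet` | seeded NumPy ConvNet: 2×(64 3×3 conv) + 2×(64 unshared 1×1 locally connected) + dense 512/512/128 + G-way softmax; batch norm everywhere, dropout 0.5 on hidden layers 4–6; SGD (batch 1000, 28 epochs, lr 0.1 ÷10 after epochs 16/24, weight decay 1e-4); batch-norm recalibration on unlabeled data |
| `semgimg.baselines` | MLP (1024 ReLU units, same SGD recipe), KNN/SVM/RF/LDA with pinned hyper-parameters, every-k-th-frame training decimation |
| `semgimg.voting` | trailing-window majority voting, whole-segment voting, stream fusion, frame/voted/segment accuracy with per-subject mean ± sd, odd/even / leave-one-trial-out / two-thirds splits |
| `semgimg.synthetic` | amplitude-modulated band-limited Gaussian model and a motor-unit action-potential train mode; per-(subject, gesture) Gaussian-blob amplitude maps; optional 50 Hz interference |
| `semgimg.io` | MAT-file import/export, canonical HDF5 store, experiment runner with presets, results bundles (CSV + JSON + config echo) |
| `semgimg.cli` | `semgimg` command-line interface |

## CLI

```bash
# generate a synthetic dataset and run the self-contained demo experiment
semgimg simulate --grid 8x16 --gestures 4 --trials 10 --seed 1 --out data.h5
semgimg run synthetic-demo --seed 1 --out results/demo

# train / predict / evaluate individually
semgimg train data.h5 --out model.h5
semgimg predict data.h5 --model model.h5 --out preds.json
semgimg vote-curve preds.json --windows 1,10,40,150,segment --out curve.json

# real-data protocols expect a canonical HDF5 store built via `semgimg import`
semgimg import session*.mat --config mapping.yaml --grid 8x16 --out dba.h5
semgimg run exp1-dba --dataset dba.h5 --out results/exp1
```

Presets `exp1-dba` (odd/even trials, windows 1/40/150), `exp2-baselines`
(classical classifiers, training frames decimated ×9), `exp3-csl`
(session-wise leave-one-trial-out, 3×3 spatial median, test-time batch-norm
recalibration) and `exp4-ninapro` (1×10 grid, 100 Hz, two-thirds split)
encode the evaluation protocols; `synthetic-demo` runs offline end to end.

## Notes

- The ConvNet is implemented directly in NumPy (no GPU framework): the
  images are tiny, one CPU suffices, and runs are bit-reproducible for a
  fixed seed.
- Voting ties break to the smallest class index; windows are trailing
  (causal) and truncated at segment starts.
- Out-of-range voltages clip to [0, 1] by default; pass
  `IntensityMap(clip=False)` to raise instead.
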