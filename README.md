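# emdpcnn

Motor-imagery EEG classification by **empirical mode decomposition (EMD)**
feature extraction and a **parallel 1-D convolutional neural network
(PCNN)** with per-subject transfer-learning fine-tuning.

## Who this is for

Brain-computer-interface (BCI) researchers working with cue-aligned
motor-imagery EEG — e.g. the BCI Competition IV 2a (22 channels, 4
classes) and 2b (3 bipolar channels C3/Cz/C4, 2 classes) recordings, both
250 Hz — who want a transparent, fully testable implementation of the
EMD + parallel-CNN pipeline: preprocessing, sifting, per-IMF features,
network training and the complete evaluation-metric suite. A synthetic
generator emulating event-related desynchronization (ERD) makes every
stage runnable and verifiable without downloading any dataset.

## The method

**EMD.** A 1-D signal `v(t)` is sifted into intrinsic mode functions
(IMFs): repeatedly subtract the mean of the cubic-spline envelopes
through the local maxima and minima, `m(t) = (e_l(t) + e_u(t))/2`, until
the candidate's extrema and zero-crossing counts differ by at most one
and its envelope mean is near zero. Each accepted IMF is removed from
the running residue, so

```
v(t) = Σ_{i=1..M} c_i(t) + r(t)
```

holds exactly (float precision) by construction.

**Features.** On each (channel, IMF) pair: energy `Σ|g(n)|²`, order-7
autoregressive coefficients (Burg), fuzzy approximate entropy
`Φ^m − Φ^{m+1}` with an exponential similarity kernel
`exp(−d²/r·var)` over baseline-removed templates, peak-to-peak
amplitude, skewness and excess kurtosis — concatenated channel-major
into one vector per epoch.

**PCNN.** Per trial the network consumes a channels × time raster
(optionally EMD-denoised). A shared stem — conv1d(32 filters, kernel 20,
stride 1, same padding) → batch-norm → ReLU — feeds two parallel
branches that differ only in max vs average pooling; their outputs are
concatenated into a dropout-regularised dense head ending in a K-way
softmax. Training is Adam on categorical cross-entropy + L2, with
validation early stopping; transfer learning fine-tunes a copy of the
pretrained network (convolutional stem optionally frozen) on one
subject's 70 % training split.

**Metrics.** From the confusion matrix (rows = predicted, columns =
actual), one-vs-rest per class: specificity TN/(TN+FP), sensitivity =
recall TP/(TP+FN), precision TP/(TP+FP), accuracy
(TP+TN)/total, and F1 = 2PR/(P+R), plus unweighted macro averages.

## Worked example

`python examples/03_train_classifier.py` generates 300 synthetic trials
(left vs right hand; mu/beta gains attenuated to 0.3 on the
contralateral channel), trains a reduced 16-filter PCNN and prints:

```
trained for 12 epochs (final val acc 1.000)
confusion matrix (rows = predicted, cols = actual):
[[45  0]
 [ 0 45]]
macro metrics (%): {'specificity': 100.0, 'sensitivity': 100.0, 'precision': 100.0,
 'accuracy': 100.0, 'recall': 100.0, 'f1': 100.0}
```

All 90 held-out trials are classified correctly: under strong ERD
contrast the lateralised band-power gap is fully learnable from the raw
standardized rasters. `examples/01_decompose_signal.py` shows the EMD
separating a 2 Hz + 20 Hz mixture (IMF–tone correlations 0.9997,
reconstruction error 2×10⁻¹⁶), and `examples/04_transfer_learning.py`
shows fine-tuning lifting a gain-shifted subject from 0.600 to 0.833
test accuracy.

A thin CLI wires the same stages together on files:

```
emdpcnn synth --classes 2 --trials-per-class 100 --seed 0 --out runs/
emdpcnn train --input runs/<run>/epochs.npz --out runs/
emdpcnn evaluate --input runs/<run>/epochs.npz --model runs/<run>/model --out runs/
```

## Layout

- `src/emdpcnn/io.py` — GDF/EDF reading, Butterworth band-pass (4–38 Hz,
  order 3, causal), exponential moving standardization (decay 0.999),
  epoch extraction (0.5–2.5 s window → 500 samples at 250 Hz)
- `src/emdpcnn/emd.py` — extrema, spline envelopes, sifting, decomposition
- `src/emdpcnn/features.py` — the six per-IMF features and feature tables
- `src/emdpcnn/pcnn.py` — layers, parallel architecture, forward/backward
- `src/emdpcnn/training.py` — Adam, early stopping, splits, transfer
- `src/emdpcnn/evaluation.py` — confusion matrix and metrics
- `src/emdpcnn/synthetic.py` — ERD-style synthetic MI-EEG, EDF+ writer
- `src/emdpcnn/cli.py` — the `emdpcnn` command
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
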