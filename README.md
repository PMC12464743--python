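# physiodecode

Joint reconstruction of slow **respiration-variation (RV)** and **heart-rate
(HR)** time series directly from parcellated fMRI data, with the surrounding
analysis pipeline: physiological waveform feature extraction and quality
control, multi-atlas ROI reduction, response-function variance-explained
analysis, functional-connectivity impact analysis, and a ground-truth forward
simulator that makes the whole pipeline testable at desk scale.

## The problem

BOLD fMRI measures blood oxygenation, so it responds not only to neural
activity but to anything that moves blood gases — in particular to slow
(< 0.15 Hz) fluctuations in breathing depth and heart rate. These two signals
account for a large share of low-frequency fMRI variance and distort
functional-connectivity estimates, yet many datasets have no physiological
recordings at all. Because the physiological imprint is distributed across
the whole brain, the lost signals can be decoded back out of the fMRI data
itself.

`physiodecode` does this with a single bidirectional LSTM over ROI
time-series channels:

* input: an R×T matrix of parcel-mean BOLD signals (R ROIs from a composed
  cortical + white-matter + subcortical + brainstem-arousal atlas; 497
  regions in the full composition), detrended, band-passed to 0.01–0.15 Hz,
  downsampled and z-scored;
* a bidirectional LSTM (hidden state *h* per direction) reads the sequence
  forwards and backwards, so the hemodynamic delay between physiology and
  BOLD needs no explicit lag modelling;
* dropout and two independent linear heads map the per-frame hidden state to
  one RV and one HR value per frame — the outputs have the same length as
  the input and both signals are learned jointly (multi-task), exploiting
  their natural coupling (r ≈ 0.275 at rest).

Targets are the classic definitions: RV(t) is the standard deviation of the
respiration-belt waveform in a 6-s window centred on each frame; HR(t) is
60 / mean inter-beat interval of the pulse-oximetry beats in the same window
(bpm), both band-passed and z-scored. Training minimises the equal-weighted
sum of per-signal MSE with Adam and a plateau learning-rate schedule
(decay 0.5, patience 2), keeping the weights of the best validation epoch.
Evaluation is subject-wise: five-fold cross-validation with a 68/12/20
train/validation/test partition in which all scans of a subject travel
together, scored by the Pearson correlation between reconstructed and
measured signals.

Downstream, reconstructed (or measured) RV/HR are turned into BOLD
regressors by convolution with the respiration and cardiac response
functions (RRF/CRF) plus temporal and dispersion derivatives; percent
variance explained is the OLS variance reduction ×100, and the connectivity
module quantifies how ROI-to-ROI and seed-based correlation maps change when
this physiological subspace (optionally with motion parameters and their
derivatives) is projected out.

The network and its training loop are implemented in NumPy (exact
backpropagation through time, verified against finite differences), exposed
as a scikit-learn-style estimator.

## Worked example

Simulate a small cohort with known ground truth, train a reduced model on a
subject-wise fold, and evaluate held-out scans:

```python
import numpy as np
from physiodecode import (PhysioReconstructor, SimConfig, simulate_dataset,
                          make_cv_splits, evaluate_scan, variance_explained_map)

cfg = SimConfig(n_scans=60, n_rois=30, n_frames=300, varexp_target=0.25, seed=42)
scans, manifest = simulate_dataset(cfg)
subjects = [s.subject for s in scans]
train_s, val_s, test_s = make_cv_splits(sorted(set(subjects)), k=5, seed=42).folds[0]
pick = lambda g: [i for i, s in enumerate(subjects) if s in g]
X = [s.roi_data.T for s in scans]
y = [np.column_stack([s.rv_true, s.hr_true]) for s in scans]

model = PhysioReconstructor(hidden_size=64, batch_size=16, dropout=0.3,
                            max_epochs=30, seed=42)
model.fit([X[i] for i in pick(train_s)], [y[i] for i in pick(train_s)],
          X_val=[X[i] for i in pick(val_s)], y_val=[y[i] for i in pick(val_s)])

te = pick(test_s)
preds = model.predict([X[i] for i in te])
r_rv = [evaluate_scan(p[:, 0], y[i][:, 0]) for p, i in zip(preds, te)]
r_hr = [evaluate_scan(p[:, 1], y[i][:, 1]) for p, i in zip(preds, te)]
print(f"held-out scans: {len(te)}")
print(f"median r (RV): {np.median(r_rv):.3f}")
print(f"median r (HR): {np.median(r_hr):.3f}")

scan = scans[te[0]]
ve = variance_explained_map(scan.roi_data, preds[0][:, 0], preds[0][:, 1], scan.dt)
print(f"variance explained by reconstructed RV/HR, scan {scan.scan_id}: "
      f"mean {ve.mean():.1f}%, max {ve.max():.1f}%")
```

Output:

```
held-out scans: 12
median r (RV): 0.647
median r (HR): 0.671
variance explained by reconstructed RV/HR, scan sub-0005_scan-1: mean 22.6%, max 31.8%
```

The median correlations say the network recovers both latent signals from
held-out subjects' ROI data well above the mismatched-pair baseline (≈ 0);
the variance-explained figures match the simulated regime, where the true
regressors carry ~25% of each region's variance.

The same pipeline is scriptable from a shell:

```bash
physiodecode simulate --out work --set simulate.n_scans=60 --set seed=42
physiodecode train --out work work/manifest.yaml --set model.hidden_size=64
physiodecode evaluate --out work work/model.npz work/manifest.yaml
```

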