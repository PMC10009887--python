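# fecgsqa

Signal-quality-driven channel selection for non-invasive fetal
electrocardiography (fECG).

## The problem

Multi-channel trans-abdominal recordings mix a large maternal ECG with a
fetal ECG that is one to two orders of magnitude smaller and whose
strength varies electrode by electrode with fetal position. In a
wearable fetal heart-rate (fHR) monitor, running a full fECG-extraction
chain on every channel wastes power on channels that carry no usable
fetal signal. `fecgsqa` implements a supervised signal-quality-assessment
(SQA) pipeline that recognises the informative channels *directly from
the raw abdominal signals*, before any extraction:

1. **Features** — each channel is high-pass filtered (1 Hz, 4th-order
   Butterworth, causal) and cut into 5-s segments; 16 signal-quality
   indexes (SQIs) are computed per segment: Welch band powers in
   [0.5–10], [10–20], [20–48], [48–52], [52–100] Hz, spectral entropy,
   baseline std, steepest slope, amplitude extremes, std, kurtosis,
   skewness, the band-power ratios pSQI = P₅₋₁₅/P₅₋₄₅ and
   basSQI = P₀₋₃/P₀₋₁₀₀, and Hjorth complexity.
2. **Labels** — a channel is *informative* iff its fetal SNR is strictly
   above 5 dB; classes are balanced by seeded random downsampling.
3. **Ranking** — greedy mRMR (mutual-information difference criterion)
   scores the features on every cross-validation training split;
   normalized scores are summed and the smallest prefix holding 80% of
   the total relevance is the selected subset.
4. **Classifier** — bagging of 100 CART trees (≤ 10 splits each),
   evaluated by 10-time 10-fold stratified cross-validation (Acc, TPR,
   TNR, PPV, F1); a channel is selected when a strict majority of its
   segments is predicted informative.
5. **Downstream proof** — the fECG is extracted per channel with a
   multi-reference QRD-RLS adaptive filter (3 thoracic mECG reference
   leads, 20 taps each, forgetting factor 0.999), fetal R-peaks are
   detected by an expected-rate max-search, and detection is scored
   against reference annotations with a 50-ms tolerance window
   (ACC_det = TP/(TP+FP+FN), TPR_det, PPV_det, F1_det), comparing
   *all channels* vs *selected channels* per recording
   (Wilcoxon signed-rank, Bonferroni-corrected).

A deterministic synthetic-data generator (24 abdominal channels + 3
thoracic references, Gaussian-bump P-QRS-T beats, per-channel fetal
amplitude and maternal gain, baseline wander, 50 Hz powerline, noise,
full ground truth) stands in for clinical data; see `docs/methods.md`
for the model, its parameters and its limits.

## Worked example

```python
import fecgsqa as fq

# synthetic training set: 6 recordings x 24 channels x 30 s,
# labelled from ground-truth fetal SNR, balanced
table = fq.build_training_table(6, seed=11, duration=30.0)
model = fq.train(table, fq.EnsembleParams(seed=1))

# screen an unseen recording
rec, gt = fq.generate_recording(fq.study_config(99, duration=30.0))
sel = fq.select_channels(model, rec)
print("selected channels:", sel.selected)
print("true SNR of selected (dB):",
      [float(round(gt.true_fetal_snr_per_channel[c], 1)) for c in sel.selected])
```

prints

```
selected channels: [3, 10, 16]
true SNR of selected (dB): [12.8, 11.7, 11.7]
```

— the screener kept 3 of 24 channels, and every one of them is a channel
whose true fetal SNR clears the 5 dB informativeness threshold.

The same workflow is available from the shell:

```sh
fecgsqa simulate --seed 5 --duration 30 --out rec
fecgsqa features rec --out features.csv
fecgsqa train --labelled labelled.csv --out model.joblib
fecgsqa select-channels --model model.joblib --rec rec --out channels.json
```

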