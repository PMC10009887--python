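# Methods

## Problem and approach

In non-invasive fetal electrocardiography, 20–30 electrodes on the
maternal abdomen record a mixture of a large maternal ECG (mECG), a fetal
ECG (fECG) one to two orders of magnitude smaller, baseline wander,
powerline interference and broadband noise. The fetal content varies
strongly across electrodes with fetal position, so most channels are
useless for fetal heart-rate (fHR) measurement at any given time. For a
wearable monitor, extracting the fECG from every channel wastes power;
the question this package addresses is whether the informative channels
can be recognised *before* extraction, directly from the raw signals.

The method: cut each abdominal channel into 5-s segments, compute 16
signal-quality indexes (SQIs) per segment, classify each segment
informative / non-informative with a bagged decision-tree ensemble, and
keep a channel when a strict majority of its segments is predicted
informative. Downstream, fECG extraction (multi-reference QRD-RLS
adaptive cancellation of the mECG using three thoracic reference leads)
and fetal QRS detection (expected-rate max-search) quantify the benefit:
fetal-QRS detection scores restricted to the selected channels are
compared against using all channels.

## Preprocessing

Channels are resampled (polyphase, rational-factor approximation better
than 1e-9) and high-pass filtered with a causal single-pass Butterworth
filter realized in second-order sections. Two presets exist: the feature
/ training chain uses 500 Hz with a 1 Hz 4th-order high-pass (the lowest
reasonable cut-off: powerline and high-frequency noise are deliberately
left in band so the classifier learns to recognise them — no notch
filter anywhere); recordings with strong baseline wander use 512 Hz with
a 3 Hz 5th-order high-pass. Filtering is causal, not zero-phase, because
the intended setting is real-time wearable processing. Filters are
applied to the whole channel before segmentation; segments are
consecutive non-overlapping 5-s windows from sample 0 (overlap would
only duplicate correlated rows), with any trailing remainder discarded.

## Quality features

Spectral features come from a Welch PSD with 1-s Hann windows and 50%
overlap (one-sided density, 1 Hz grid — fine enough to isolate the
48–52 Hz powerline band; the estimator, window and overlap are package
choices and are configurable). `pband1..pband5` are mean densities over
the closed bands [0.5–10], [10–20], [20–48], [48–52], [52–100] Hz. The
two ratios use integrated (summed) band power so unequal band widths
cancel: `pSQI` = P[5–15]/P[5–45] (fetal-QRS band fraction) and `basSQI`
= P[0–3]/P[0–100] (baseline fraction, denominator truncated at Nyquist
below 100 Hz). `seSQI` is the PSD's Shannon entropy normalized to [0, 1].

Time-domain features: `bas_pow` (std of a centred 1-s moving-average
baseline, window forced odd, symmetric edge padding), `ss` (largest
absolute sample-to-sample slope x fs), `HA`/`LA` (signed extremes),
`stdSQI`, `kSQI`/`sSQI` (population, non-excess kurtosis and skewness —
Gaussian noise scores kurtosis 3, a sparse ECG-like spike train well
above 5), and Hjorth `complexity` (mobility of the first difference over
mobility of the signal; 1 for a pure tone, ~1.22 for white noise).

Zero-variance segments never raise: all features are recorded as 0 with
a degenerate marker, and the classifier maps degenerate rows to
non-informative by construction.

## Labelling and balancing

A channel is informative when its fetal SNR is strictly above 5 dB. For
synthetic data the generator's ground-truth SNR — fetal power over
everything-else power in the channel, after the same 1 Hz high-pass the
features see — is the default labeller; every segment inherits its
channel's label. For real data a template estimator is provided: 100-ms
windows centred on annotated fetal R-peaks are averaged into a template,
SNR = 10 log10(template power / residual power). Note the two scales
differ systematically: the template concentrates power in the QRS window
and is computed after maternal cancellation, so it reads several dB
above the whole-signal raw-channel SNR; the tests therefore validate the
estimator against the oracle SNR of the extracted trace, not against the
raw-channel ground truth. Items within 1 dB of the threshold can be
flagged for manual review. The majority class is randomly downsampled
(seeded, without replacement) to balance the training set.

## Feature ranking (mRMR)

Greedy minimum-redundancy maximum-relevance, MID (difference) variant:
first pick argmax MI(f, y); then repeatedly pick argmax of MI(f, y) minus
the mean MI between f and the already-selected features. MID is used
rather than MIQ to avoid division instabilities; mutual information is
the plug-in estimate on equal-frequency 10-bin discretizations (robust
to the heavy-tailed SQI distributions). A feature's raw score is its
criterion value at selection time, floored at 0 (a fully redundant
duplicate scores 0). Every cross-validation training split contributes
one score vector, min-max normalized to [0, 1] (an all-equal vector
degenerates to zeros); vectors are summed across the 100 splits, features
are ranked by the aggregate, and the selected subset is the smallest
prefix reaching 80% of the total relevance. Ties break by the canonical
feature order.

## Classifier and evaluation

Bagging of 100 CART trees (Gini impurity, best-first growth capped at 10
internal splits, i.e. 11 leaves), bootstrap resamples of full size;
features considered per split default to sqrt(16) = 4, with an "all"
option exposed. No hyperparameter tuning. Prediction is the tree-vote
fraction; an exact 0.5 tie is non-informative (false positives cost
downstream compute). Evaluation is 10-repeat 10-fold stratified CV —
each repeat a fresh seeded partition, each partition its own seeded
ensemble, so results are bit-reproducible — reporting Acc, TPR, TNR,
PPV, F1 per partition with median/quartile summaries; metrics with zero
denominators are recorded as NaN and excluded from medians rather than
forced to 0. Partitions stratify on the label only.

## Extraction and detection

The maternal canceller is exponentially weighted recursive least squares
in QR-decomposition (square-root) form: the upper-triangular factor of
the regressor covariance is propagated with Givens rotations — the
square-root form is a numerical-stability choice, equivalent to
covariance-form RLS to rounding error. The regressor concatenates
per-reference delay lines: 3 thoracic leads x 20 taps = 60 weights,
forgetting factor 0.999 (memory ~1000 samples), triangular factor
initialized to sqrt(0.01) x identity. The a-priori error is the fECG
estimate. The first 10 x taps samples are an adaptation transient,
flagged and excluded from SNR estimation and detection scoring.

The detector resolves polarity automatically (the sign whose candidate
extrema have the larger median magnitude), then keeps samples that are
the maximum of the polarity-corrected raw trace (not squared) within
+/- w, where w = 0.5 x fs / expected_rate and the expected fetal rate
defaults to 2.2 Hz (~132 bpm); overlapping candidates resolve in favour
of the larger peak. Detection runs per channel; no cross-channel fusion.

Detected and reference peaks are matched one-to-one, greedily by
ascending |dt|, within a 50-ms tolerance (interpreted as |dt| <= 50 ms,
the common fetal-QRS challenge convention; the tolerance is a flag).
Greedy nearest-first matching can in principle differ from optimal
bipartite matching, but not when successive peaks are more than twice
the tolerance apart, which fetal RR intervals (> 370 ms) always satisfy.
Counts are pooled over a recording's channels (micro-average) to give
one metric value per recording per condition; conditions are compared
with Kruskal-Wallis plus pairwise Wilcoxon signed-rank tests,
Bonferroni-corrected over the pairwise family at alpha = 0.05.

## Synthetic data

The generator stands in for clinical multi-channel recordings: 24
abdominal channels + 3 thoracic references at 500 Hz. Beats are sums of
five Gaussian bumps (P, Q, R, S, T) — parameter-light and deterministic,
deliberately simpler than a dynamical ECG model but sufficient to
exercise every quality feature; maternal QRS is ~90 ms wide, fetal
~30–40 ms. RR intervals jitter multiplicatively (Gaussian, truncated at
3 sigma, 2% default). The maternal source is three lead morphologies
sharing one beat train; each abdominal channel sees a random unit
3-vector mixture of them, which is exactly what a 3-reference adaptive
canceller can remove; references carry the maternal leads plus small
instrumentation noise. Per-channel defaults for the study draw: fetal
amplitude log-uniform on [3, 80] uV, maternal gain log-uniform on
[0.02, 1.0] x 60 uV, 0.3 Hz baseline (15 uV), 50 Hz powerline (2 uV,
European mains), white noise (2 uV). The draw was calibrated once so
that roughly a quarter of channels exceed the 5 dB label threshold, and
frozen. Ground truth (fetal/maternal peak trains, per-channel SNR, the
unit fetal waveform) is returned with every recording; identical config
and seed give bit-identical output.

What the simulator does not model: fetal movement and time-varying
presentation, electrode-contact artifacts, uterine EMG, non-stationary
noise, twins. Consequently the synthetic classification task is easier
than the clinical one — cross-validated accuracies here approach 100%,
whereas mid-80s% is what heterogeneous clinical segments support — and
the 80%-relevance prefix can collapse to a very few features (often a
single dominant one, skewness), because relevance concentrates when the
classes separate cleanly. Passing tests demonstrate the correctness and
internal consistency of the pipeline, plus the qualitative
channel-selection benefit, not clinical-grade performance.

## Problem sizes and numerics

The shipped study uses 10 training recordings and 20 test recordings of
30 s each (24 channels; ~500–600 balanced training segments), a size
chosen so the whole study re-runs from scratch in a few minutes on one
CPU while leaving every statistical conclusion (Wilcoxon at n = 20)
well-powered. Degenerate inputs (zero variance, zero denominators,
empty channel selections, fewer than 3 beats) are defined outcomes, not
errors, as described above; an empty channel selection scores all
reference peaks as missed. The QRD-RLS inner loop is JIT-compiled with
numba; the covariance-form RLS and the exhaustive matching/ranking
oracles used by the tests are independent plain-NumPy implementations.

## Known limitations

* The template SNR estimator and the raw-channel ground-truth SNR are
  different scales (see Labelling); threshold decisions transfer between
  them only up to a systematic offset.
* The max-search detector assumes a roughly known fetal rate band; far
  outside 110–160 bpm the window size degrades detection.
* Greedy matching, MID-mRMR and the MATLAB-style bagging defaults are
  one concrete choice each where several exist in the literature; all
  are exposed as parameters.
* File I/O covers delimited matrices with JSON sidecars and plain-text
  annotation indices; EDF/BDF and streaming input are out of scope.
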