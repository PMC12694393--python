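# Methods

## Problem and model

Atrial fibrillation (AF) manifests in the inter-beat (RR) interval stream as
high, weakly autocorrelated beat-to-beat variability, whereas sinus rhythm
(SR) produces regular intervals slowly modulated by respiration. The package
classifies fixed-length windows of N consecutive RR intervals (N = 25, 50 or
100, raw seconds, no normalization) with a compact one-dimensional
convolutional network sized for microcontroller deployment:

```
Input (N x 1)
  -> Conv1D(16, k=3, valid) -> BatchNorm -> ReLU -> AvgPool(2) -> Dropout(0.25)
  -> Conv1D(32, k=3, valid) -> BatchNorm -> ReLU -> AvgPool(2)
  -> Flatten -> Dense(64) -> ReLU -> Dropout(0.1) -> Dense(2) -> Softmax
```

With valid padding the sequence lengths are 25→23→11→9→4 (flatten 128,
10,210 parameters), 50→48→24→22→11 (flatten 352) and 100→98→49→47→23
(flatten 736). Padding is configurable (`ModelConfig.padding`); valid is the
default and the mode all shape oracles in the test suite pin down.

Training: Adam (learning rate 9e-4, β₁ = 0.9, β₂ = 0.999, ε = 1e-7),
categorical cross-entropy on one-hot labels, batch size 32, at most 100
epochs, early stopping on validation loss with patience 5 and restoration of
the best weights, and a seeded stratified 80/20 train/validation split of
each fold's training table. The forward/backward passes, Adam and the early
stopping loop are implemented directly on NumPy arrays; backpropagation
through every layer type is verified against central-difference gradients in
the test suite.

### Numerical choices

- **BatchNorm momentum 0.9** (ε = 1e-3). At these dataset sizes an epoch is
  only a few dozen optimizer steps; a 0.99 decay leaves the inference-time
  moving statistics stale for ~15 epochs, during which validation loss is
  uninformative and patience-5 early stopping aborts training at chance
  accuracy. A 0.9 decay converges within roughly two epochs.
- **Early stopping min_delta = 0**; the monitored quantity is validation
  loss; ties do not reset patience.
- Weight init is Glorot-uniform with a seeded generator; dropout and batch
  shuffling draw from one seeded per-run generator, so a fixed seed
  reproduces training exactly. Weights are serialized as float32 in a
  deterministic container (JSON header + raw array bytes) so identical runs
  produce byte-identical artifacts.
- Softmax is computed with max-subtraction; cross-entropy clips
  probabilities at 1e-7.

## INT8 quantization

Post-training, per-tensor affine quantization: conv/dense weights are
symmetric int8 (scale = max|w|/127, zero point 0); activations are
asymmetric int8 calibrated from min/max ranges observed while pushing a
seeded representative set (200 training windows by default) through the
float model. Quantized inference snaps every intermediate activation to its
calibrated 256-level grid and uses the dequantized int8 weights, emulating
integer-kernel arithmetic up to accumulator rounding. BatchNorm is kept as a
separate float32 per-channel affine rather than folded into the preceding
convolution; its few dozen parameters do not change the footprint story
(the serialized INT8 container is ~3.9x smaller than float32 for N = 100).
Class probabilities for the INT8 model come from a float softmax over the
dequantized logits, so ranking metrics (AUC) stay well defined.

## Dataset construction

- RR intervals are differenced from beat annotations after restricting to
  segments of the requested rhythm; differencing runs across same-rhythm
  segment boundaries by default, and the [0.25, 2] s plausibility filter
  (inclusive endpoints; 30–240 bpm) removes the implausible cross-segment
  intervals this creates. A strict within-segment mode is available.
- Windows are non-overlapping by default (stride = N, configurable),
  labelled 0 = SR / 1 = AF.
- Cross-validation is subject-wise: 5 folds, 3 exclusive test subjects per
  fold drawn without replacement (seeded), the other 20 subjects train. The
  partition is drawn once and reused across window lengths.
- Class balance is enforced per exported table (train and test separately,
  pooled across that fold's subjects) by seeded random down-sampling of the
  majority class, preserving the survivors' order.

## Evaluation

Confusion matrices count AF as positive with an argmax (0.5) decision rule.
Precision, recall and F1 are macro-averaged — on balanced tables this makes
them coincide with accuracy for any near-symmetric classifier, which is the
regime these experiments operate in. AUC-ROC is the rank statistic with
midrank tie handling. Cross-fold summaries are mean ± sample standard
deviation (ddof = 1). Fold confusion matrices may be summed element-wise
into one aggregate because test subjects are mutually exclusive across
folds; the row-normalized aggregate equals the pooled per-class rates, which
the tests assert.

## Synthetic cohort

The generator emulates only the property the classifier exploits —
irregularity contrast — and is explicitly non-physiological:

| parameter | default | meaning |
|---|---|---|
| SR mean RR | per subject ~ U(0.7, 1.0) s | resting sinus rate 60–86 bpm |
| RSA amplitude / period | 0.04 s / 4.5 s | respiratory modulation |
| SR beat noise sd | 0.02 s | residual sinus variability |
| AF mean RR | per subject ~ U(0.55, 0.85) s | faster ventricular response |
| AF coefficient of variation | 0.22 | i.i.d. Gamma intervals, lag-1 autocorr ≈ 0 |
| clip range | [0.3, 1.8] s | strictly inside the plausibility filter |
| cohort | 23 subjects × 5000 beats | ~5 000 beats ≈ 1.1 h per subject |
| AF time share | ≈ 0.45 (per subject ± 0.2) | mixed-rhythm recordings |

Each synthetic subject carries both rhythms. The synthetic ECG is a train of
1 mV Gaussian QRS-like deflections (~40 ms wide) on a 0.05 mV baseline
wander, sampled at 125 Hz; beat k is placed half an interval into the trace
so every peak is interior and a threshold detector recovers the beat count
exactly. A 12-bit/3.3 V DAC model (LSB 1000·vref/2^bits ≈ 0.805 mV, floor
quantization, reconstruction error ≤ 1 LSB) mirrors the signal-playback
bench used for hardware-in-the-loop validation.

**What passing on synthetic data shows.** The SR/AF variance contrast at
these defaults is large: window variance alone separates the classes with
probability > 0.99, and the cross-validated network reaches accuracy 1.0 at
every window length, with INT8/float32 label agreement 1.0. This validates
the pipeline mechanics (no subject leakage, balanced tables, training,
quantization parity, aggregation) — it does not estimate clinical
performance. Real AF recordings contain ectopy, detector noise, rhythm
transitions and inter-subject overlap that the generator deliberately omits,
which is why published subject-wise accuracies on real Holter data sit near
0.96–0.98 rather than 1.0, improving with window length. The monotone
trend acc(N=100) ≥ acc(N=25) is asserted on the synthetic cohort but is
saturated there (both at 1.0).

## Streaming simulator

The desk-scale engine mirrors the embedded firmware loop: RR intervals and
the ECG samples spanning them accumulate in independent buffers; when the RR
buffer reaches N the model runs one inference and both buffers are cleared
(after every inference, not only on SR — this yields non-overlapping
analysis windows consistent with one inference per N beats). An AF
classification publishes a JSON payload — stream id, event time, the N RR
values, the exactly-spanning ECG samples at 125 Hz, and the AF probability —
to a pluggable sink; the default sink is a directory of JSON files standing
in for the device's MQTT uplink, and a sink failure falls back to a local
file. Replaying a stream with the same model is byte-reproducible.

## Problem sizes

The shipped study conditions are 23 subjects × 5000 beats, 5 folds, window
lengths 25/50/100; a full cross-validated run of all three lengths,
including INT8 conversion and evaluation, completes in a couple of minutes
on one CPU core.

## Known limitations

- The synthetic generators model marginal RR statistics only (no ectopic
  beats, no f-waves or P-wave morphology, no artifacts, no rhythm
  transitions inside a window).
- BatchNorm is not folded before quantization, so the INT8 graph is a
  faithful simulation of per-tensor integer inference rather than a
  deployable flat buffer.
- Reading real WFDB records requires the optional `wfdb` package; without it
  the ingest operations work on parsed annotation structures and CSVs.
- Mixed-rhythm windows are never generated (windows are cut within one
  rhythm's series), matching the study design rather than free-living data.
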