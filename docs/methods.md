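# Methods

This note records the model, the synthetic data-generating process, the
numerical choices, and the limits of what the shipped experiments show.

## Model

**Patching.** A series of T minutes is reshaped into N = T/S non-overlapping
patches; S must divide T exactly (no padding or truncation — silent
truncation would corrupt day alignment, and the canonical worked numbers
10,080/18 = 560 assume exact division). Each patch is embedded to D
dimensions by one shared affine map, or, in "conv" mode, by two shared
same-padded 1D convolutions (kernel 3, 8 channels each, ReLU) followed by a
linear map from the flattened activations to D. Fixed sinusoidal positional
embeddings are added.

**Encoder block.** Post-norm ordering, as is conventional for this model
family: multi-head self-attention, add & LayerNorm, feed-forward
(ReLU, width `ff_dim`), add & LayerNorm. ReLU was chosen for the
feed-forward nonlinearity (simple exact gradient); no dropout is applied at
the desk scales shipped here (the config knob exists). There is no
classification token: sequence representations are produced by pooling.

**Presets.** Exact layer/head/width values of the published PAT-S/M/L
models are not public; the shipped presets were chosen to land near the
published parameter scales and make no claim of weight-level equivalence:

| preset | S | D | blocks | heads | ff | params (embed+encoder) |
|---|---|---|---|---|---|---|
| tiny | 180 | 16 | 1 | 4 | 32 | 5,120 |
| PAT-S | 18 | 64 | 4 | 4 | 416 | 283,712 (~285 K) |
| PAT-M | 18 | 128 | 5 | 8 | 512 | 993,792 (~1.00 M) |
| PAT-L | 18 | 128 | 10 | 8 | 512 | 1,985,152 (~1.99 M) |

**Masked autoencoder.** Mask count = floor(ratio·N): ratio 0 masks nothing
and nothing can mask everything. Masks are uniform subsets drawn without
replacement, fresh per example per epoch. Visible tokens keep their
original relative order into the encoder (positional information is already
attached). One shared learned mask token is used (per-position tokens
rejected as parameter bloat). Because encoder and decoder widths may
differ, a learned linear projection maps encoder outputs to the decoder
width and positional embeddings are regenerated at that width before the
decoder — the conventional resolution when the decoder is narrower. The
decoder head is a per-token linear map D_dec → S whose outputs concatenate
to the full T minutes. Defaults: mask ratio 0.90 and minute-level MSE over
*all* minutes (both knobs exposed; the masked-only loss mode is
implemented and tested but is the reportedly weaker choice). The shipped
default decoder (1 block, D_dec = 64 for the S/M/L presets) is under a
quarter of the encoder's parameter count; configs violating strict
encoder > decoder asymmetry are rejected.

**Optimisation.** The reference training procedure for this model family
does not pin an optimiser; Adam with a fixed learning rate (default 1e-3)
is used throughout, with optional early stopping — on held-out
reconstruction loss for pretraining (off by default), on validation AUC
with patience 5 and best-weight restoration for classifiers. All
randomness (init, shuffling, masks, splits) flows from explicit seeds
through `numpy` generators; no global RNG state is touched, and identical
seeds give bit-identical runs.

**Autodiff.** No deep-learning framework is declared; `patlite.nn` is a
small tape-based reverse-mode engine over float64 numpy arrays implementing
exactly the operations the model needs (broadcast arithmetic, batched
matmul, softmax, LayerNorm composition, token gather/scatter, im2col
convolution). Its gradients are validated against central finite
differences through the complete MAE and classifier graphs in the test
suite.

## Preprocessing

Per-minute standardization z-scores each minute position across the
participants of a dataset using the population (divide-by-n) standard
deviation — the convention of the usual column scaler. Zero-variance
minutes map to 0 and are flagged by sd = 0 in the recorded stats. The
default workflow standardizes train/validation/test splits separately,
matching the protocol this package follows; `apply_stats` supports the
conventional train-stats-only alternative. A whole-dataset z-score
(`standardize_global`) is available for heterogeneous pretraining corpora.
Savitzky–Golay smoothing defaults to window 51 / order 3 with polynomial
("interp") edge handling, avoiding wrap-around across the week boundary.
Minute indices are 0-based; no clock alignment is attempted.

## Synthetic cohorts

Each simulated day is `floor + A·sin²(π(m − wake)/L)` inside the wake
window (flat floor of 1 count outside), with per-participant chronotype
(wake ≈ 07:00 ± 30 min, wake window ≈ 16 h ± 30 min, amplitude ≈ 50 counts,
log-normal across participants) and mean-one multiplicative log-normal
observation noise; `noise_sd` is the log-scale standard deviation
(default 0.5) — chosen over additive noise to keep raw intensities
non-negative by construction. Label-1 participants (base rate default 0.2)
have wake onset delayed by `wake_shift_minutes` and daytime amplitude
scaled by `amplitude_ratio`; at a 120-minute shift and default noise, a
trivial morning-activity feature already separates the classes at
AUC ≥ 0.8, guaranteeing downstream models have signal to find. The
pretraining corpus draws wake time from U(300, 540) minutes, wake duration
from U(870, 1020) and amplitude from U(20, 80). An optional weekend
amplitude factor exists but defaults to off so the null case stays simple.

What the generator does **not** emulate: device-specific count
distributions, non-wear gaps, weekday structure, age/activity covariates,
or any biomechanical realism. Passing tests therefore demonstrate that the
pipeline recovers a planted circadian effect at desk scale — not clinical
performance on real accelerometer cohorts.

## Evaluation protocol

A stratified test set (2,000 participants at full scale) is held out;
training subsets of the requested sizes (default 500/1,000/2,500/pool) are
drawn *with replacement* from the remainder — implemented literally, with a
without-replacement flag; duplicates never cross into the test set. 20% of
each subset, stratified, becomes validation. Stratification is enforced in
tests to ±2 percentage points of the pool rate (a testable proxy for
"stratified"). Model selection uses validation AUC. AUC is the
probability a random positive outscores a random negative with ties
counted one-half. Models are ranked by the arithmetic mean of per-size
AUCs; display rounding is half-up (3 decimals for AUC, 1 for
percentage-point improvements), with unrounded values kept internally.

## Explainability

The literal aggregation "sum attention across key positions for each
query" equals 1 for every query — softmax rows are normalised — so it
yields a uniform, information-free profile; it is implemented behind
`mode="query_sum"` and unit-tested to return exactly that. The default
aggregates attention *received* per key (summed over queries, averaged
over heads, normalised to 1), which produces the non-uniform heatmaps this
model family reports. Only the last block's attention is used; multi-block
rollout and gradient-based attribution are out of scope.

## Desk-scale experiment sizes

The shipped experiments are sized for a single CPU: pretraining corpora of
200–2,000 synthetic weeks with the tiny preset, labelled cohorts of
100–500, five replicate seeds where variability matters. The
pretrained-vs-random comparison is paired — same cohorts and fine-tune
seeds in both arms, only the encoder initialisation differs — to measure
the initialisation effect rather than cohort noise. One encoder is
pretrained per experiment and shared across the replicate fine-tune seeds.
The null-cohort calibration scores on an independently generated cohort
rather than the early-stopping validation split, since selecting the best
epoch by validation AUC biases that same AUC upward under the null.

## Known limitations

- Encoder representations at the shipped scales are not foundation models
  in any practical sense; they demonstrate mechanics, not transfer at
  n = 21,538.
- The numpy engine is single-threaded-ish and float64-only; it is not
  suitable for the full PAT-L pretraining workload.
- `MaskSpec` supports per-example masks in batches, but all examples in a
  batch must share the same mask ratio.
- Label/feature realism of the synthetic cohorts is deliberately minimal
  (see above); AUC values on synthetic cohorts are not comparable to
  published NHANES numbers, which are shipped separately as reference data
  in `patlite.reference`.
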