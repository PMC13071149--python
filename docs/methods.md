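# Methods

This note records the models, procedures and design choices behind
`ecgfewshot`, including the places where the design was genuinely open and
what the synthetic experiments can and cannot show.

## Problem and study design

The package studies *trainability*, not peak accuracy, in extreme few-shot
ECG rhythm classification: with only N = 70 labeled 12-lead records (14 per
class over SR, AFIB, STACH, SARRH, SBRAD), supervised training from scratch
can fail catastrophically — the validation metric peaks at the very first
epoch and the network degenerates into a near-constant predictor. The audit
makes this failure measurable with three quantities per training run r:

* test Macro-F1 (unweighted mean of per-class F1) and accuracy,
* the best validation epoch e\*_r (1-based, earliest epoch attaining the
  maximum of the monitored validation metric),
* the group-level collapse rate over R repeated seeds,
  CollapseRate = (1/R) Σ_r 1(e\*_r ≤ 1).

Seven controlled configurations isolate the effect of self-supervised
initialization from data augmentation and label budget: 300-sample
references (A imbalanced, A′ balanced, B balanced with strong
augmentation), the 70-sample scratch baseline C, augmentation-only E, and
the SSL-initialized pair D-Aug / D-NoAug, with D-NoAug (no downstream
augmentation) as the core mechanism-isolating setting.

## Synthetic data generator

Tests and desk-scale experiments run on synthetic 12-lead records (10 s,
100 Hz, shape 12×1000) whose class structure carries exactly the features a
rhythm classifier must rely on:

* **RR process.** A record's mean heart rate is drawn uniformly from its
  class range (SR 60–100, AFIB 60–150, STACH 101–160, SARRH 60–100,
  SBRAD 35–59 bpm). Sinus classes jitter intervals with Gaussian noise at a
  coefficient of variation of 0.03; SARRH adds a sinusoidal modulation
  (depth 0.15) at a respiratory frequency drawn from 0.15–0.4 Hz; AFIB draws
  gamma-distributed intervals with CV 0.24 ("irregularly irregular"). The
  series is rescaled so the realized mean rate equals the drawn target,
  which preserves CV and modulation structure.
* **Morphology.** Each beat is a sum of Gaussian bumps for P, Q, R, S, T at
  fixed offsets from the R peak (R amplitude 1, P 0.15, T 0.3 on an
  arbitrary mV-like scale). AFIB sets the P amplitude to zero and adds a
  fibrillatory sinusoid (amplitude 0.08) at a random 5–9 Hz frequency —
  chosen to sit above P-wave spectral content but below the 50 Hz Nyquist
  limit. This is an ECGSYN-like simplification, not a dynamical ODE model.
* **Leads.** The 12 leads are fixed random per-lead gains (|gain| in
  0.4–1.2, four leads sign-flipped) applied to one base waveform plus
  independent Gaussian noise (SD 0.03). True vectorcardiographic projection
  is out of scope.

Ground-truth beat times are kept in record metadata, which gives the QRS
region masks used by the saliency audit and lets tests verify parameter
recovery (naive peak detection recovers the configured rate within
±5 bpm on noise-free records; AFIB's realized RR CV exceeds SR's in ≥95% of
paired same-seed draws).

What the generator does **not** emulate: inter-patient morphology variance,
electrode artifacts and baseline wander, multi-label pathology,
patient-wise record correlation. Passing the directional end-to-end tests
therefore shows the pipeline's mechanics are sound — not that the specific
PTB-XL numbers would be reproduced on real data. A real-data adapter
(`ecgfewshot.ptbxl`, optional `wfdb` dependency) maps PTB-XL-layout WFDB
files onto the same record type.

## Preprocessing

Records are resampled to 100 Hz (polyphase filtering) and then each lead is
Z-scored within its own 10 s segment, x̃ = (x − μ_l)/(σ_l + ε) with
ε = 1e−8 (the stabilizer value was an open choice). Two numerical details:

* Polyphase filtering is applied to mean-centered leads and the mean is
  restored afterwards; this makes constant (DC) leads exact and reduces
  edge ringing.
* Upsampling is refused rather than silently interpolated; the pipeline
  order (resample, then normalize) is fixed by construction.

Splits are generated from independent random streams spawned from one seed
and own disjoint record-id namespaces, so the few-shot, validation, test,
reference and unlabeled collections can never share a record. The
validation set size is not fixed by the study design; we use a class-
balanced 7-per-class set (35 records), generated disjointly from all other
splits, because balanced monitoring avoids majority-class early-stopping
artifacts at N = 70. The unlabeled pool is likewise generated disjoint from
the test set as a leakage guard.

## Augmentation family

Three operators in fixed order crop → scale → noise, all config-exposed:

| operator | SSL views | downstream "strong" | emulates |
|---|---|---|---|
| random crop/resample (fraction of window) | 0.7–1.0 | 0.5–1.0 | heart-rate variability |
| amplitude scale (one gain per record) | 0.8–1.2 | 0.5–1.5 | gain drift |
| additive Gaussian noise (SD, post-normalization units) | 0.05 | 0.15 | acquisition noise |

Magnitudes were an open choice; the SSL block is deliberately mild and the
downstream block deliberately aggressive, and the two blocks are configured
separately rather than assumed equal. Lead dropout, time masking and
permutation are intentionally excluded from the family.

## Encoder, contrastive objective, training stack

The encoder is a lightweight 1-D CNN front-end (strided convolutions with
ReLU) followed by self-attention blocks over the downsampled time axis and
mean pooling to a 64-dimensional representation h. Two presets:

* `default`: conv 16/32/64 channels (kernels 7/5/3, stride 2 each), two
  4-head attention blocks, ≈77k parameters;
* `tiny`: conv 8/16/64 (strides 4/2/2), one 2-head attention block, ≈30k
  parameters — used for desk-scale runs.

Both sit far under the 1e6 "lightweight" budget; layer counts are defaults,
not fidelity claims. The projection head is the standard two-layer ReLU MLP
64 → 128 → 64, used only during pretraining and discarded afterwards.

Pretraining minimizes NT-Xent at temperature τ = 0.1 over cosine
similarities of the 2N in-batch view embeddings, excluding self-similarity
from each denominator; embeddings are not pre-normalized (cosine similarity
handles scale). The implementation is max-shifted log-sum-exp, stable for
|sim/τ| well past 100, and is tested against an independent double-loop
oracle to 1e−9. Pretraining refuses labeled records outright.

The whole training stack runs on a small in-repo reverse-mode autodiff
engine over numpy (`ecgfewshot.nn`): broadcasted arithmetic, batched
matmul, strided 1-D convolution via sliding windows, attention, reductions
and indexing, with gradients retained on interior graph nodes (which is
what 1-D Grad-CAM reads). Models train in float32; oracle-facing public
functions compute in float64. Optimization is Adam (lr 1e−3 for
pretraining, 1e−4 for fine-tuning).

One measured property worth recording: the first-batch contrastive loss at
a random untrained encoder sits *below* the chance level log(2N−1), because
two augmented views of the same record are already correlated through any
encoder. The chance-level value is recovered exactly when unrelated records
are paired arbitrarily; the tests check both facts separately.

## Fine-tuning protocol

A linear 64→5 head (with bias, kept as the standard head even though the
softmax(Wᵀh) formulation omits it) is attached to the encoder and the whole
network is trained end-to-end (full unfreezing) with multiclass
cross-entropy at lr 1e−4, batch size 32, for at most `max_epochs` epochs
(default 100; 30 in the desk-scale config). After every epoch the
validation Macro-F1 is computed; training stops exactly `patience` (10)
epochs after the last strict improvement, the weights of the best epoch e\*
are restored, and the test set is evaluated once. Ties are broken toward
the earliest epoch — conservative for collapse detection, since a flat
degenerate trajectory then yields e\* = 1. The monitored quantity was an
open choice; validation Macro-F1 aligns the early-stopping signal with the
primary endpoint and makes the collapse signature well-defined. Validation
and test records are never augmented; when downstream augmentation is
enabled, every training record is re-perturbed each epoch.

## Aggregation and reporting conventions

* F1 zero-division convention: if a class has no true and no predicted
  instances (or precision+recall = 0), its F1 is 0 — this strictly
  penalizes collapsed predictors and keeps Macro-F1 well-defined.
* Group SDs are sample standard deviations (denominator R−1) over seeds;
  a single run reports SD 0.
* The majority-class baseline Macro-F1 for majority fraction p is
  2p/(5(1+p)) (the constant predictor scores F1 = 2p/(1+p) on the majority
  class and 0 elsewhere).
* Epochs and record indices are 1-based; time is sample-indexed from 0.
* One global seed expands deterministically (via seed-sequence spawning,
  all derived seeds < 2³¹) into the data seed, the pretraining seed and the
  per-run fine-tuning seeds, so all groups share data and differ only in
  initialization and training stochasticity.

## Saliency audit

1-D Grad-CAM on the encoder's last convolutional feature map: channel
weights are time-averaged gradients of the target-class logit, the map is
the rectified weighted channel sum, linearly upsampled to the 1000-sample
input axis and normalized to max 1 when positive. Saliency is computed on
the shared time axis (leads are pooled by the conv front-end); per-lead
maps are out of scope. The region-attention weight of a mask is the
fraction of total saliency mass inside it; QRS masks are ±60 ms windows
around the generator's ground-truth beat times. A constant-output
classifier mechanically yields an all-zero map — the interpretability-side
signature of collapse. Which feature map and region normalization a
saliency audit should use is a declared choice, not an inference.

## Problem sizes

The desk-scale configuration (`configs/tiny.yaml`) keeps the study
structure — N = 70 few-shot set, 300-sample references, all seven groups,
five seeds — while using a 64-record unlabeled pool, a 200-record test set,
the `tiny` encoder and a 30-epoch budget, so the full matrix runs in a few
minutes on one CPU core. `configs/default.yaml` states the full-scale
conditions (16,304-record pool, 2035-record test set, 100-epoch budget,
`default` encoder, three seeds) for long offline runs.

## Known limitations

* Synthetic classes are more cleanly separable in their defining features
  than clinical ECG; absolute metric values are not comparable to
  real-data results, only the audit's mechanics and directions are tested.
* The collapse regime at desk scale is milder than on real data (the
  synthetic task at N=70 tends to learn slowly rather than collapse
  outright), so collapse-rate comparisons are asserted as inequalities.
* No learning-rate schedules, layer freezing, label smoothing or
  class-weighted losses; no significance testing across groups.
* Reproducibility is bit-exact for fixed seed, thread count and BLAS
  implementation; across different BLAS builds results may differ in the
  last float digits.
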