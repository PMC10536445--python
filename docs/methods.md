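# Methods

## Problem and model

Obstructive sleep apnea (OSA) produces a characteristic oximetric
signature: recurrent desaturations of 3–4% below the local baseline,
lasting tens of seconds. `spo2former` labels every second of a 1 Hz SpO2
trace as apnea or normal with a transformer encoder, then aggregates the
per-second decisions into events and an apnea–hypopnea index (AHI), calling
a patient OSA-positive at AHI ≥ 5 events/hour.

The network is:

1. **Input embedding** — a pointwise linear lift of the single normalized
   SpO2 feature to `d_model` (default 32).
2. **Positional stage** — one of:
   - `none`: the encoder sees the window as an unordered set;
   - `constant`: the normalized sample index `i/(n−1)`, broadcast across
     depth and added to the embedding;
   - `sinusoidal`: the fixed table `PE(pos, 2i) = sin(pos/10000^{2i/d})`,
     `PE(pos, 2i+1) = cos(·)`, added to the embedding (table built at
     `max(sequence_length, 64)` rows and truncated to the window);
   - `learnable`: a 1-D convolutional autoencoder (CAE) whose
     reconstruction *replaces* the raw input before the lift.
3. **Encoder stack** — 4 identical layers of multi-head scaled-dot-product
   self-attention (`Attention(Q,K,V) = softmax(QKᵀ/√d_k)V`, `d_k =
   d_model/n_heads`) and a position-wise feedforward (`d_model → d_ff →
   d_model`, ReLU), each sublayer with residual connection, layer
   normalization (post-norm; pre-norm available) and dropout.
4. **Head** — per-timestep linear `d_model → 1` with sigmoid: one apnea
   probability per second. A window-level head (mean-pool → sigmoid) is
   available behind `head="segment"` for comparison; per-second labeling
   is the default because it is the point of the design.

The CAE encoder applies `n_down_layers` (default 2) same-padded
convolutions with kernel 7, stride 2 and ReLU, with dropout in between;
the decoder mirrors them with transposed convolutions targeting the exact
intermediate lengths (so odd window lengths round-trip exactly), and a
final kernel-7 stride-1 convolution returns to one channel. Decoder
channel counts are `reversed(filters)[1:] + (filters[0],)` — for the
default filters (32, 16): 16 → 32 → 32 → 1. Depth and filter counts are
free choices (only kernel 7, down-stride 2 and the final stride-1 layer
are fixed by design); two down/up layers are the smallest stack meeting
the design. The CAE is trained end-to-end through the classification loss
only — the model is a single unit, with no reconstruction pretraining. An
auxiliary mean-squared reconstruction term is available
(`TrainConfig.recon_loss_weight`, default 0), and the reconstruction can
be *added* to the raw input instead of replacing it
(`ModelConfig.cae_additive`); both default to the replacement-only wiring.

Because the CAE compresses the window (bottleneck length
`ceil(n / 2^n_down)`), it carries smooth, event-scale structure, not
per-second white noise. This is the right bias for desaturation events
(tens of seconds) and is why toy tasks with i.i.d. per-second labels are
served by the additive encodings instead.

## Numerical core

No deep-learning framework is a dependency: the package ships a compact
tape-based reverse-mode autodiff engine over float64 numpy arrays
(`spo2former.nn`), with dense, layer-norm, softmax, dropout and 1-D
(transposed) convolution primitives, Adam, and a plateau learning-rate
scheduler. Every primitive's gradient is validated against central finite
differences in the test suite, and the transposed convolution is tested to
be the exact adjoint of the forward convolution. Initialization is Glorot
uniform from a seeded generator; batch order and dropout masks come from
the same seed chain, so runs are bit-reproducible.

## Preprocessing

Records are 1 Hz series with aligned 0/1 labels. Missing samples (NaN)
are dropped together with their labels (no interpolation); windows of
`sequence_length` seconds (default 120, the length at which this architecture performs best —
roughly the two-minute span a scorer inspects; 10–360 supported) are cut with stride = length by
default, each min–max normalized to [0, 1] **independently**. A constant
window maps to all zeros rather than erroring. Trailing remainders are
discarded, not padded. Splits are either segment-random or
patient-grouped; patient-grouped is what the per-patient evaluation uses,
since segment-level splitting would leak a patient's physiology across
sides.

## Training protocol

Per-timestep binary cross-entropy (computed stably from logits),
minimized by Adam in batches of 32. The reference protocol uses an
initial learning rate of 1e-5 with a ×0.2 cut when the validation loss
plateaus; `TrainConfig` defaults to exactly that. The sklearn-style
estimator (`SpO2TransformerClassifier`) defaults to 1e-3 instead: the
desk-scale experiments in this package take a few hundred Adam steps, and
1e-5 moves the parameters by ~1e-3 in that budget — far too little to
leave initialization. 1e-5 remains the right setting for the
million-sample overnight workload the protocol was designed for. Plateau
detection uses an improvement threshold (`min_delta`, default 1e-4)
as in the standard framework implementations; without it, monotone
microscopic improvements would postpone the decay indefinitely.
Class weighting is off by default (matching the protocol), with
inverse-frequency weighting behind `class_weighting="balanced"`.

## Synthetic cohort

The simulator's defaults describe a plausible adult overnight recording:
baseline 97 ± 0.5% (slow Gaussian-filtered drift, clipped at 3σ),
desaturations 3–4% deep and 10–60 s long at a Poisson rate of
`target_ahi` events/hour placed without overlap (10 s refractory gap),
piecewise-linear descent over the first third of each event and linear
(optionally exponential) recovery, 0.5% i.i.d. Gaussian sensor noise,
0.1% missing samples and 0.05% artifact spikes (40–75%, far outside any
clean trace). Labels are 1 exactly on event seconds, so the event list
and label vector are interchangeable ground truth; corruption never
touches labels.

What passing tests on this cohort show: the pipeline can learn the
desaturation signature from noisy, imbalanced, gap-ridden 1 Hz data and
recover patient-level AHI categories. What they do not show: performance
on real polysomnography-annotated data, where hypopneas without clear
desaturation, arousal-related events, baseline pathology and
oximeter-specific filtering make the task substantially harder.

## Desk-scale experiments

`spo2former.experiments` fixes two reference experiments sized for a
single CPU core:

- **End-to-end benchmark** — 20 patients × 1 h, target AHIs evenly spaced
  0–40, desaturation depth 4%, noise 0.3%; the AHI-0 and AHI-40 patients
  held out; default model trained ≤ 10 epochs (early stop once validation
  AUC reaches 0.95). Reports pooled per-second metrics on the held-out
  pair and their OSA calls.
- **Positional-encoding ablation** — 400 windows of 64 s where dips
  (8–16 s) occur anywhere but only dips starting in the second half are
  positive. Without positional information the attainable AUC is capped
  (first-half dips are indistinguishable false positives); the learnable
  encoding recovers the position gate. Compared after 20 epochs on a
  fixed 25% validation split.

## Numerical choices and edge cases

- Constant encoding at n=1 is `[0.0]`; min–max of a constant window is 0.
- Zero-denominator metric conventions: recall/precision/specificity are 0
  when undefined, F1 is 0 when precision+recall is 0; such reports carry a
  `degenerate` flag. ROC AUC raises on single-class inputs.
- Event reconstruction: maximal runs of predicted-apnea seconds ≥ 10 s
  (the standard minimum duration for respiratory events) become events;
  an optional merge gap joins nearby runs first. AHI divides the event
  count by the *scored* hours (seconds actually covered by windows).
- Overlapping windows average their per-second scores; uncovered trailing
  seconds are NaN and excluded from metrics, never imputed.
- Attention softmax is computed shift-invariantly (row max subtracted).

## Known limitations

- Training is CPU-bound numpy; overnight-scale cohorts (10⁶ seconds, 40
  epochs) are out of reach here — the architecture, not the throughput,
  is the point of this package.
- SpO2-only input by design; no multichannel fusion.
- The simulator does not model apnea/hypopnea subtypes, gas-exchange
  dynamics, sleep staging or oximeter averaging filters.
- Head count, feedforward width and dropout are free hyperparameters of
  the architecture; the defaults (4 heads, d_ff 64, dropout 0.1) are
  small, explicit and configurable.
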