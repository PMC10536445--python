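# spo2former

Per-second obstructive sleep apnea (OSA) detection from raw pulse-oximetry
(SpO2) time series with a transformer encoder and a learnable
convolutional-autoencoder positional encoding.

OSA produces recurrent oxygen desaturations — drops of 3–4% from the
preceding baseline lasting tens of seconds. `spo2former` labels **every
second** of a 1 Hz SpO2 trace as apnea or normal, which lets a physician
inspect the model's reasoning at the same granularity as the raw signal,
then aggregates the decisions into respiratory events and an
apnea–hypopnea index (AHI = events per hour; AHI ≥ 5 ⇒ OSA).

The model maps a normalized window `X = [x₀, …, xₙ]` to per-second apnea
probabilities through:

- a pointwise linear embedding of the SpO2 feature to depth `d_model = 32`;
- one of four positional stages: none, constant (`PE(i) = i/(n−1)`),
  sinusoidal (`PE(pos,2i) = sin(pos/10000^{2i/d_model})`,
  `PE(pos,2i+1) = cos(·)`), or **learnable** — a 1-D convolutional
  autoencoder (kernel 7, stride 2, ReLU, dropout; transposed-convolution
  decoder; final kernel-7 stride-1 layer) whose same-length reconstruction
  replaces the raw input, trained end-to-end with the classifier;
- four encoder layers of multi-head self-attention,
  `Attention(Q,K,V) = softmax(QKᵀ/√d_k)V`, with residual connections and
  layer normalization;
- a per-timestep sigmoid head.

It is written for researchers in biomedical signal analysis who want a
fully inspectable, framework-free reference implementation: the neural
network runs on a compact numpy autodiff core shipped with the package
(every gradient finite-difference-tested), and an annotated synthetic
overnight-oximetry simulator makes the whole pipeline testable without
any clinical data.

## Worked example

```python
import numpy as np
from spo2former import (
    SimParams, simulate_cohort, drop_missing, window_record,
    SpO2TransformerClassifier, per_patient_report, roc_auc,
)

# 8 synthetic patients, 1 h each, from event-free to severe OSA
records = simulate_cohort(
    8, ahi_values=[0, 5, 10, 15, 20, 25, 30, 40],
    base_params=SimParams(duration_s=3600, noise_sd=0.3,
                          desat_depth_range=(4.0, 4.0)),
    seed=7,
)
records = [drop_missing(r)[0] for r in records]

# train on six patients, hold out the mildest and the most severe
train, test = records[1:-1], [records[0], records[-1]]
segs = [s for r in train for s in window_record(r, 120)]
X = np.stack([s.values for s in segs])   # (n_windows, 120) in [0, 1]
y = np.stack([s.labels for s in segs])   # per-second 0/1 labels

clf = SpO2TransformerClassifier(pe="learnable", sequence_length=120,
                                max_epochs=25, early_stop_auc=0.97,
                                random_state=0).fit(X, y)

for res in per_patient_report(clf.model_, test):
    print(f"{res.patient_id}: AUC={res.metrics.auc}  "
          f"estimated AHI={res.estimated_ahi:.1f}  OSA={res.osa_predicted}")
```

Output from this exact script (~45 s on one CPU core):

```
p00: AUC=None  estimated AHI=0.0  OSA=False
p07: AUC=0.9278313683458378  estimated AHI=25.9  OSA=True
```

The event-free patient (target AHI 0) has no apnea seconds, so per-second
AUC is undefined (`None`, flagged degenerate) and the estimated AHI of 0
yields the correct negative OSA call. The severe patient (target AHI 40,
29 realized events in its single hour) is scored well per second and
called OSA-positive with an estimated AHI of 25.9 events/hour.

A command-line interface mirrors the library:

```bash
spo2former simulate --n-patients 10 --duration-h 8 --out cohort/
spo2former train --records cohort/ --pe learnable --seq-len 120 --out run/
spo2former evaluate --model run/model.npz --records cohort/ --out metrics.json
spo2former predict --model run/model.npz --record cohort/p00.csv --out scores.csv
spo2former ablate-pe --records cohort/ --out ablation.json
spo2former sweep-length --records cohort/ --lengths 10,60,120 --out sweep.json
```

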