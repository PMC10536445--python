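"""Reproducible desk-scale experiments.

These drive the full pipeline — simulate a cohort, window, train, score
held-out patients — at problem sizes a single CPU core handles in minutes:
20 one-hour patients for the end-to-end benchmark and a 64-s
position-sensitive task for the positional-encoding ablation. They are the
package's own reference experiments; overnight-cohort scale is reached
by raising ``n_patients``/``duration_s`` and
``max_epochs`` and lowering the learning rate to 1e-5.
"""

from __future__ import annotations

import numpy as np

from .estimator import SpO2TransformerClassifier
from .metrics import roc_auc
from .records import drop_missing, window_record
from .simulate import SimParams, simulate_cohort, simulate_positional_task
from .train import per_patient_report


def desk_scale_benchmark(
    seed: int = 0,
    n_patients: int = 20,
    duration_s: int = 3600,
    sequence_length: int = 120,
    max_epochs: int = 10,
    pe: str = "learnable",
) -> dict:
    """Train the default detector on a synthetic cohort and score two
    held-out patients: the event-free one (target AHI 0) and the severe
    one (target AHI 40).

    The cohort spans target AHIs 0..40 evenly; desaturations are 4% deep
    with 0.3% sensor noise. Returns pooled per-second metrics on the two
    held-out patients and their OSA calls (AHI >= 5 rule).
    """
    ahis = np.linspace(0.0, 40.0, n_patients)
    params = SimParams(duration_s=duration_s, desat_depth_range=(4.0, 4.0), noise_sd=0.3)
    records = [drop_missing(r)[0] for r in simulate_cohort(n_patients, ahis, params, seed=seed)]

    # hold out the two extremes; train on everything in between
    test_records = [records[0], records[-1]]
    train_records = records[1:-1]
    segments = [s for r in train_records for s in window_record(r, sequence_length)]
    x = np.stack([s.values for s in segments])
    y = np.stack([s.labels for s in segments])

    est = SpO2TransformerClassifier(
        sequence_length=sequence_length,
        pe=pe,
        max_epochs=max_epochs,
        early_stop_auc=0.95,
        random_state=seed,
    )
    est.fit(x, y)

    labels, scores = [], []
    for rec in test_records:
        s = est.model_.predict_proba(
            np.stack([seg.values for seg in window_record(rec, sequence_length)])
        ).ravel()
        labels.append(np.concatenate([seg.labels for seg in window_record(rec, sequence_length)]))
        scores.append(s)
    labels = np.concatenate(labels)
    scores = np.concatenate(scores)

    from .metrics import report_from_scores

    report = report_from_scores(labels, scores, est.threshold)
    per_patient = per_patient_report(est.model_, test_records, threshold=est.threshold)
    low, high = per_patient[0], per_patient[1]
    return {
        "heldout_auc": report.auc,
        "heldout_accuracy": report.accuracy,
        "heldout_f1": report.f1,
        "heldout_sensitivity": report.recall,
        "heldout_specificity": report.specificity,
        "n_heldout_seconds": int(labels.size),
        "epochs_used": len(est.history_["epoch"]),
        "osa_call_ahi0_negative": not low.osa_predicted,
        "osa_call_ahi40_positive": high.osa_predicted,
        "estimated_ahi_low": low.estimated_ahi,
        "estimated_ahi_high": high.estimated_ahi,
        "true_ahi_high": high.true_ahi,
    }


def pe_ablation(
    seed: int = 0,
    variants: tuple[str, ...] = ("none", "learnable"),
    n_sequences: int = 400,
    length: int = 64,
    max_epochs: int = 20,
) -> dict[str, float]:
    """Validation AUC per positional-encoding variant on a task where the
    label depends on where within the window an event falls."""
    x, y = simulate_positional_task(n_sequences, length=length, seed=seed)
    n_val = n_sequences // 4
    x_tr, y_tr = x[:-n_val], y[:-n_val]
    x_va, y_va = x[-n_val:], y[-n_val:]
    aucs = {}
    for pe in variants:
        est = SpO2TransformerClassifier(
            sequence_length=length,
            pe=pe,
            n_encoder_layers=2,
            d_model=16,
            n_heads=2,
            d_ff=32,
            max_epochs=max_epochs,
            validation_fraction=0.0,
            random_state=seed,
        )
        est.fit(x_tr, y_tr)
        scores = est.predict_proba(x_va)
        aucs[pe] = roc_auc(y_va.ravel(), scores.ravel())
    return aucs
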