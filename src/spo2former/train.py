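"""Training protocol and patient-level evaluation.

Training minimizes per-timestep binary cross-entropy with Adam, monitors
validation loss, and multiplies the learning rate by ``lr_plateau_factor``
(default 0.2, from an initial 1e-5) whenever the validation loss fails to
improve for ``plateau_patience_epochs`` consecutive epochs. Everything is
seeded: parameter initialization, batch order and dropout masks, so two
runs with the same seed and data coincide.

Patient-level evaluation scores each whole record per second with
:func:`predict_per_second`, reconstructs events from the thresholded
predictions, estimates the apnea–hypopnea index, and calls a patient
OSA-positive at AHI >= 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .events import OSA_AHI_THRESHOLD, estimate_ahi, extract_events
from .metrics import MetricsReport, report_from_scores
from .nn import Adam, ReduceLROnPlateau, Tensor, bce_with_logits
from .records import PatientRecord, Segment
from .transformer import SpO2Transformer


class TrainingError(RuntimeError):
    pass


class PredictionError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Batch size 32, initial learning rate 1e-5 and the plateau decay factor
    0.2 form the reference protocol for overnight-scale cohorts; patience
    and the epoch cap are free choices. ``early_stop_auc`` optionally halts training once the
    validation AUC reaches a level, for cheap CPU-scale experiments.
    """

    batch_size: int = 32
    initial_lr: float = 1e-5
    lr_plateau_factor: float = 0.2
    plateau_patience_epochs: int = 5
    plateau_min_delta: float = 1e-4
    max_epochs: int = 40
    k_folds: int = 5
    holdout_fraction: float = 0.2
    class_weighting: str = "off"
    threshold: float = 0.5
    early_stop_auc: float | None = None
    recon_loss_weight: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.lr_plateau_factor < 1.0:
            raise ValueError("lr_plateau_factor must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.class_weighting not in ("off", "balanced"):
            raise ValueError("class_weighting must be 'off' or 'balanced'")


def kfold_partition(items, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold split of indices; each fold validates once."""
    n = len(items)
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train, val) for train, val in kf.split(np.arange(n))]


def _as_arrays(segments) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(segments, tuple) and len(segments) == 2:
        x, y = segments
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y)
        if x.ndim == 3:
            x = x[..., 0]
        return x, y
    if len(segments) == 0:
        return np.empty((0, 0)), np.empty((0, 0), dtype=np.int64)
    x = np.stack([s.values for s in segments])
    y = np.stack([s.labels for s in segments])
    return x, y


def _mean_loss_and_acc(model: SpO2Transformer, x: np.ndarray, y: np.ndarray, weights, batch_size: int):
    model.eval()
    total_loss, total_correct = 0.0, 0
    wsum = 0.0
    for i in range(0, x.shape[0], batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward_logits(Tensor(xb[..., None])).data
        wb = weights(yb) if weights is not None else None
        elem = np.maximum(logits, 0) - logits * yb + np.log1p(np.exp(-np.abs(logits)))
        if wb is None:
            total_loss += elem.sum()
            wsum += elem.size
        else:
            total_loss += (wb * elem).sum()
            wsum += wb.sum()
        total_correct += ((logits >= 0).astype(int) == yb).sum()
    return total_loss / wsum, total_correct / y.size


def train_model(
    model: SpO2Transformer,
    train_segments,
    validation_segments,
    config: TrainConfig = TrainConfig(),
) -> tuple[SpO2Transformer, dict]:
    """Fit the detector; returns the model and a per-epoch history.

    ``train_segments``/``validation_segments`` are lists of
    :class:`~spo2former.records.Segment` or ``(values, labels)`` array
    pairs. History keys: ``epoch, train_loss, val_loss, train_acc,
    val_acc, lr`` (the learning rate in force during each epoch).
    """
    x_tr, y_tr = _as_arrays(train_segments)
    x_va, y_va = _as_arrays(validation_segments)
    if x_tr.shape[0] == 0:
        raise TrainingError("empty training set")

    weights = None
    if config.class_weighting == "balanced":
        pos = max(int((y_tr == 1).sum()), 1)
        neg = max(int((y_tr == 0).sum()), 1)
        total = y_tr.size
        w_pos, w_neg = total / (2.0 * pos), total / (2.0 * neg)

        def weights(yb):
            return np.where(yb == 1, w_pos, w_neg)

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.initial_lr)
    scheduler = ReduceLROnPlateau(
        optimizer,
        factor=config.lr_plateau_factor,
        patience=config.plateau_patience_epochs,
        min_delta=config.plateau_min_delta,
    )
    history: dict[str, list] = {k: [] for k in ("epoch", "train_loss", "val_loss", "train_acc", "val_acc", "lr")}

    n = x_tr.shape[0]
    for epoch in range(config.max_epochs):
        lr_in_force = optimizer.lr
        model.train(True)
        order = rng.permutation(n)
        run_loss, run_correct, run_count = 0.0, 0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = Tensor(x_tr[idx][..., None])
            yb = y_tr[idx]
            logits, recon = model.forward_parts(xb)
            loss = bce_with_logits(logits, yb, weights(yb) if weights is not None else None)
            if config.recon_loss_weight > 0 and recon is not None:
                # optional auxiliary self-supervision: mean squared
                # reconstruction error of the autoencoder stage
                diff = recon - Tensor(xb.data)
                loss = loss + config.recon_loss_weight * (diff * diff).mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            run_loss += float(loss.data) * yb.size
            run_correct += int(((logits.data >= 0).astype(int) == yb).sum())
            run_count += yb.size

        # running means over the epoch's minibatches (training mode)
        train_loss, train_acc = run_loss / run_count, run_correct / run_count
        if x_va.shape[0] > 0:
            val_loss, val_acc = _mean_loss_and_acc(model, x_va, y_va, weights, config.batch_size)
        else:
            val_loss, val_acc = train_loss, train_acc

        history["epoch"].append(epoch)
        history["train_loss"].append(float(train_loss))
        history["val_loss"].append(float(val_loss))
        history["train_acc"].append(float(train_acc))
        history["val_acc"].append(float(val_acc))
        history["lr"].append(float(lr_in_force))

        if config.early_stop_auc is not None and x_va.shape[0] > 0:
            from .metrics import UndefinedAUCError, roc_auc

            scores = model.predict_proba(x_va)
            try:
                if roc_auc(y_va.ravel(), scores.ravel()) >= config.early_stop_auc:
                    break
            except UndefinedAUCError:
                pass

        scheduler.step(float(val_loss))

    model.eval()
    return model, history


def predict_per_second(
    model: SpO2Transformer,
    record: PatientRecord,
    window_length_s: int | None = None,
    stride_s: int | None = None,
) -> np.ndarray:
    """Score every second of a cleaned record.

    The record is windowed (min–max normalization per window), each window
    scored, and per-second scores reassembled in record order; seconds
    covered by several overlapping windows get the mean score; uncovered
    trailing seconds are NaN (excluded from metrics).
    """
    from .records import window_record

    window_length_s = window_length_s or model.config.sequence_length
    stride_s = stride_s or window_length_s
    if np.isnan(record.spo2).any():
        raise PredictionError(f"{record.patient_id}: record contains missing values; clean it first")
    if len(record) < window_length_s:
        raise PredictionError(
            f"{record.patient_id}: record of {len(record)} s is shorter than one {window_length_s} s window"
        )
    segments = window_record(record, window_length_s, stride_s)
    values = np.stack([s.values for s in segments])
    scores = model.predict_proba(values)
    acc = np.zeros(len(record))
    cnt = np.zeros(len(record))
    for seg, sc in zip(segments, scores):
        acc[seg.start_s : seg.start_s + window_length_s] += sc
        cnt[seg.start_s : seg.start_s + window_length_s] += 1
    out = np.full(len(record), np.nan)
    covered = cnt > 0
    out[covered] = acc[covered] / cnt[covered]
    return out


@dataclass
class PatientResult:
    """Per-patient evaluation: per-second metrics plus the OSA call."""

    patient_id: str
    metrics: MetricsReport | None
    estimated_ahi: float
    true_ahi: float | None
    osa_predicted: bool
    osa_true: bool | None
    skipped: bool = False

    def to_dict(self) -> dict:
        d = {
            "patient_id": self.patient_id,
            "estimated_ahi": float(self.estimated_ahi),
            "true_ahi": None if self.true_ahi is None else float(self.true_ahi),
            "osa_predicted": bool(self.osa_predicted),
            "osa_true": None if self.osa_true is None else bool(self.osa_true),
        }
        if self.metrics is not None:
            d.update(self.metrics.to_dict())
        if self.skipped:
            d["skipped"] = True
        return d


def lopo_report(
    records: list[PatientRecord],
    estimator_params: dict | None = None,
    threshold: float = 0.5,
    min_event_duration_s: int = 10,
) -> list[PatientResult]:
    """Leave-one-patient-out evaluation: retrain with each patient held out.

    K times more expensive than :func:`per_patient_report` with a single
    shared model; intended for small cohorts.
    """
    from .estimator import SpO2TransformerClassifier
    from .records import window_record

    results: list[PatientResult] = []
    for held_out in records:
        others = [r for r in records if r is not held_out]
        est = SpO2TransformerClassifier(**(estimator_params or {}))
        segments = [s for r in others for s in window_record(r, est.sequence_length)]
        if not segments:
            raise TrainingError("no training segments for leave-one-patient-out fold")
        x = np.stack([s.values for s in segments])
        y = np.stack([s.labels for s in segments])
        est.fit(x, y)
        results.extend(
            per_patient_report(
                est.model_, [held_out], threshold=threshold,
                min_event_duration_s=min_event_duration_s,
            )
        )
    return results


def true_ahi_of(record: PatientRecord) -> float | None:
    if record.events is not None:
        return len(record.events) / record.duration_hours
    return record.meta.get("true_ahi")


def per_patient_report(
    model: SpO2Transformer,
    records: list[PatientRecord],
    window_length_s: int | None = None,
    stride_s: int | None = None,
    threshold: float = 0.5,
    min_event_duration_s: int = 10,
) -> list[PatientResult]:
    """Evaluate a trained model on each patient separately."""
    results = []
    for record in records:
        true_ahi = true_ahi_of(record)
        try:
            scores = predict_per_second(model, record, window_length_s, stride_s)
        except PredictionError as exc:
            warnings.warn(str(exc), stacklevel=2)
            results.append(
                PatientResult(
                    patient_id=record.patient_id,
                    metrics=None,
                    estimated_ahi=float("nan"),
                    true_ahi=true_ahi,
                    osa_predicted=False,
                    osa_true=None if true_ahi is None else true_ahi >= OSA_AHI_THRESHOLD,
                    skipped=True,
                )
            )
            continue
        covered = ~np.isnan(scores)
        metrics = report_from_scores(record.labels[covered], scores[covered], threshold)
        preds = (scores[covered] >= threshold).astype(np.int64)
        events = extract_events(preds, min_duration_s=min_event_duration_s)
        hours = covered.sum() / 3600.0
        ahi = estimate_ahi(events, hours)
        results.append(
            PatientResult(
                patient_id=record.patient_id,
                metrics=metrics,
                estimated_ahi=ahi,
                true_ahi=true_ahi,
                osa_predicted=ahi >= OSA_AHI_THRESHOLD,
                osa_true=None if true_ahi is None else true_ahi >= OSA_AHI_THRESHOLD,
            )
        )
    return results
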