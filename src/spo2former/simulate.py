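"""Synthetic overnight oximetry with annotated apnea events.

The simulator produces 1 Hz SpO2 recordings that carry the oximetric
signature of obstructive sleep apnea: a near-constant baseline around
95–98% with slow drift, interrupted by desaturation events in which
saturation falls 3–4% below the local baseline over roughly the first
third of the event and recovers over the remainder. Event count follows a
Poisson draw whose mean is ``target_ahi`` events per hour; events are
placed uniformly at random without overlap, separated by a refractory gap.
Per-second labels are 1 exactly on event seconds, so the label vector and
the event list are two views of the same ground truth. Measurement
imperfections — i.i.d. Gaussian noise, missing samples (NaN) and
implausible artifact spikes — are layered on after labeling and never
change the labels.

What this emulates, and what it does not: the statistics a per-second
detector must cope with (class imbalance, noise, gaps, artifacts, drifting
baseline), not gas-exchange physiology, hypopnea/apnea subtypes or
oximeter-specific filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .records import EventAnnotation, PatientRecord


class SimulationError(ValueError):
    """The requested event load cannot be placed in the recording."""


REFRACTORY_GAP_S = 10  # minimum normal seconds between consecutive events


@dataclass(frozen=True)
class SimParams:
    """Generation settings for one synthetic overnight recording.

    Defaults describe a plausible adult overnight oximetry trace: baseline
    97% with ±0.5% slow drift, desaturations of 3–4% lasting 10–60 s,
     0.5% Gaussian sensor noise, and sparse dropouts/artifacts.
    """

    duration_s: int = 8 * 3600
    baseline_mean: float = 97.0
    baseline_sd: float = 0.5
    target_ahi: float = 15.0
    desat_depth_range: tuple[float, float] = (3.0, 4.0)
    event_duration_range_s: tuple[int, int] = (10, 60)
    desat_shape: str = "linear-recovery"
    noise_sd: float = 0.5
    missing_rate: float = 0.001
    artifact_rate: float = 0.0005
    quantize: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.duration_s < 60:
            raise ValueError("duration_s must be at least 60")
        if self.target_ahi < 0:
            raise ValueError("target_ahi must be >= 0")
        lo, hi = self.desat_depth_range
        if not (0 < lo <= hi < 100):
            raise ValueError("desat_depth_range must lie within (0, 100)")
        dlo, dhi = self.event_duration_range_s
        if dlo < 1 or dhi < dlo:
            raise ValueError("event_duration_range_s must satisfy 1 <= min <= max")
        if self.desat_shape not in ("linear-recovery", "exponential-recovery"):
            raise ValueError(f"unknown desat_shape {self.desat_shape!r}")


def _place_events(
    rng: np.random.Generator, duration_s: int, target_ahi: float, dur_range: tuple[int, int]
) -> list[EventAnnotation]:
    hours = duration_s / 3600.0
    n_events = int(rng.poisson(target_ahi * hours))
    mean_dur = 0.5 * (dur_range[0] + dur_range[1])
    expected_occupied = n_events * (mean_dur + REFRACTORY_GAP_S)
    if expected_occupied > 0.8 * duration_s:
        raise SimulationError(
            f"target_ahi={target_ahi} implies ~{expected_occupied:.0f} occupied seconds "
            f"in a {duration_s} s recording; event load infeasible"
        )
    events: list[EventAnnotation] = []
    occupied: list[tuple[int, int]] = []  # (start - gap, end + gap) exclusion zones
    attempts = 0
    while len(events) < n_events:
        attempts += 1
        if attempts > 200 * max(n_events, 1):
            raise SimulationError("could not place all events without overlap")
        dur = int(rng.integers(dur_range[0], dur_range[1] + 1))
        if dur >= duration_s:
            continue
        start = int(rng.integers(0, duration_s - dur + 1))
        lo, hi = start - REFRACTORY_GAP_S, start + dur + REFRACTORY_GAP_S
        if any(lo < e and s < hi for s, e in occupied):
            continue
        occupied.append((start, start + dur))
        events.append(EventAnnotation(start_s=start, duration_s=dur))
    events.sort(key=lambda ev: ev.start_s)
    return events


def _desat_profile(duration: int, depth: float, shape: str) -> np.ndarray:
    """Per-second SpO2 deficit during one event (positive = below baseline)."""
    descent = max(1, int(np.ceil(duration / 3)))
    profile = np.empty(duration)
    profile[:descent] = depth * (np.arange(1, descent + 1) / descent)
    rec = duration - descent
    if rec > 0:
        x = np.arange(1, rec + 1) / rec
        if shape == "linear-recovery":
            profile[descent:] = depth * (1.0 - x)
        else:  # exponential-recovery
            tau = 0.35
            profile[descent:] = depth * (np.exp(-x / tau) - np.exp(-1 / tau)) / (1 - np.exp(-1 / tau))
    return profile


def simulate_record(params: SimParams, patient_id: str = "sim") -> PatientRecord:
    """Generate one annotated 1 Hz recording, reproducible from its seed."""
    rng = np.random.default_rng(params.seed)
    t = params.duration_s

    # slow baseline drift: smoothed white noise rescaled to baseline_sd,
    # clipped at 3 sigma so the physiological envelope is guaranteed
    drift = gaussian_filter1d(rng.standard_normal(t), sigma=60.0, mode="reflect")
    sd = drift.std()
    if sd > 0:
        drift *= params.baseline_sd / sd
    drift = np.clip(drift, -3 * params.baseline_sd, 3 * params.baseline_sd)
    clean = params.baseline_mean + drift

    events = _place_events(rng, t, params.target_ahi, params.event_duration_range_s)
    labels = np.zeros(t, dtype=np.int64)
    for ev in events:
        depth = rng.uniform(*params.desat_depth_range)
        sl = slice(ev.start_s, ev.start_s + ev.duration_s)
        clean[sl] -= _desat_profile(ev.duration_s, depth, params.desat_shape)
        labels[sl] = 1
    clean = np.clip(clean, 0.0, 100.0)

    spo2 = clean + rng.normal(0.0, params.noise_sd, size=t)
    if params.quantize:
        spo2 = np.round(spo2)
    spo2 = np.clip(spo2, 0.0, 100.0)

    record = PatientRecord(
        patient_id=patient_id,
        spo2=spo2,
        labels=labels,
        events=events,
        meta={
            "target_ahi": params.target_ahi,
            "true_ahi": len(events) / (t / 3600.0),
            "n_events": len(events),
        },
    )
    if params.missing_rate > 0 or params.artifact_rate > 0:
        record = inject_artifacts(
            record,
            missing_rate=params.missing_rate,
            artifact_rate=params.artifact_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return record


def inject_artifacts(
    record: PatientRecord, missing_rate: float, artifact_rate: float, seed: int = 0
) -> PatientRecord:
    """Corrupt a record with missing samples and implausible spikes.

    Each sample independently becomes missing (NaN) with ``missing_rate`` or
    an artifact spike with ``artifact_rate``; labels are untouched. Spikes
    are drawn in 40–75%, far below any clean overnight trace, emulating
    probe-displacement readings.
    """
    for name, rate in (("missing_rate", missing_rate), ("artifact_rate", artifact_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    if missing_rate == 0.0 and artifact_rate == 0.0:
        return record
    rng = np.random.default_rng(seed)
    spo2 = record.spo2.copy()
    u = rng.random(len(spo2))
    missing = u < missing_rate
    artifact = (u >= missing_rate) & (u < missing_rate + artifact_rate)
    spo2[missing] = np.nan
    spo2[artifact] = rng.uniform(40.0, 75.0, size=int(artifact.sum()))
    return replace(record, spo2=spo2, meta={**record.meta, "n_missing": int(missing.sum()), "n_artifacts": int(artifact.sum())})


def simulate_cohort(
    n_patients: int,
    ahi_values,
    base_params: SimParams = SimParams(),
    seed: int = 0,
) -> list[PatientRecord]:
    """Generate a cohort, one record per target AHI, with derived seeds."""
    ahi_values = list(ahi_values)
    if len(ahi_values) != n_patients:
        raise ValueError("ahi_values must have one entry per patient")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_patients) % (2**31 - 1)
    records = []
    width = max(2, len(str(n_patients - 1)))
    for i, (ahi, s) in enumerate(zip(ahi_values, child_seeds)):
        params = replace(base_params, target_ahi=float(ahi), seed=int(s))
        records.append(simulate_record(params, patient_id=f"p{i:0{width}d}"))
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids generated")
    return records


def simulate_positional_task(
    n_sequences: int,
    length: int = 64,
    dip_rate: float = 0.04,
    dip_duration_range: tuple[int, int] = (8, 16),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A sequence-labeling task where position within the window matters.

    Dips appear anywhere in an otherwise flat noisy trace, but only dips
    starting in the second half of the window are labeled positive. A
    model without positional information can detect dips but cannot tell
    halves apart, so its attainable AUC is capped; position-aware models
    can separate the classes fully. Returns ``X`` of shape
    (n, length, 1) in [0, 1] and ``y`` of shape (n, length).
    """
    rng = np.random.default_rng(seed)
    x = np.full((n_sequences, length), 0.8) + rng.normal(0.0, noise_sd, (n_sequences, length))
    y = np.zeros((n_sequences, length), dtype=np.int64)
    half = length // 2
    for i in range(n_sequences):
        n_dips = rng.poisson(dip_rate * length)
        for _ in range(n_dips):
            dur = int(rng.integers(dip_duration_range[0], dip_duration_range[1] + 1))
            start = int(rng.integers(0, length - dur + 1))
            x[i, start : start + dur] -= 0.6
            if start >= half:
                y[i, start : start + dur] = 1
    x = np.clip(x, 0.0, 1.0)
    return x[..., None], y
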