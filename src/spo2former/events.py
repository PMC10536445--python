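"""From per-second predictions to respiratory events and AHI.

A per-second detector emits a 0/1 sequence; clinically one needs events
and an apnea–hypopnea index (events per hour of recording). Maximal runs
of predicted-apnea seconds become events if they last at least
``min_duration_s`` (default 10 s, the standard scoring minimum for
respiratory events); nearby runs can optionally be merged first. A patient
is called OSA-positive when the estimated AHI reaches 5 events/hour.
"""

from __future__ import annotations

import numpy as np

from .records import EventAnnotation

OSA_AHI_THRESHOLD = 5.0


def binary_runs(predictions: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as (start, length) pairs."""
    p = np.asarray(predictions).astype(np.int64)
    if not np.isin(p, (0, 1)).all():
        raise ValueError("predictions must be binary")
    padded = np.concatenate([[0], p, [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def extract_events(
    predictions,
    min_duration_s: int = 10,
    merge_gap_s: int = 0,
) -> list[EventAnnotation]:
    """Turn a per-second 0/1 sequence into scored events.

    Runs separated by at most ``merge_gap_s`` zeros are merged first; then
    runs shorter than ``min_duration_s`` are discarded.
    """
    runs = binary_runs(predictions)
    if merge_gap_s > 0 and len(runs) > 1:
        merged = [runs[0]]
        for start, length in runs[1:]:
            prev_start, prev_len = merged[-1]
            if start - (prev_start + prev_len) <= merge_gap_s:
                merged[-1] = (prev_start, start + length - prev_start)
            else:
                merged.append((start, length))
        runs = merged
    return [
        EventAnnotation(start_s=s, duration_s=n)
        for s, n in runs
        if n >= min_duration_s
    ]


def estimate_ahi(events: list[EventAnnotation], recording_hours: float) -> float:
    """Events per hour of recording."""
    if recording_hours <= 0:
        raise ValueError("recording_hours must be positive")
    return len(events) / recording_hours
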