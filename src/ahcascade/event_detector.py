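"""Run-length correction of predicted label sequences, event intervals, AHI.

Two rules clean the raw 10-s segment predictions before events are read off:

1. Only runs of at least 10 consecutive AH-labeled start seconds count as a
   valid event — an apnea/hypopnea lasts ≥10 s, and with a 10-s window on a
   1-s step a real event produces at least that many consecutive positives.
   Shorter runs are reset to N.
2. Gaps of at most 5 N-labeled seconds between two valid runs are reset to
   AH — the segmentation geometry cannot produce such short gaps between two
   genuine events, so they are classifier noise inside one event.

A corrected run over start seconds ``[a, b]`` becomes the event
``[a, b + 10)`` (the last segment covers ``[b, b+10)``).  AHI is the event
count per analyzed hour; severity uses the standard 5/15/30 events/h cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cascade import LabelSequence
from .preprocess import AH, N

MIN_RUN_SEGMENTS = 10
MAX_GAP_SEGMENTS = 5
SEVERITY_ORDER = ["NON", "MILD", "MODERATE", "SEVERE"]
SEVERITY_CUTOFFS = (5.0, 15.0, 30.0)

__all__ = [
    "MIN_RUN_SEGMENTS",
    "MAX_GAP_SEGMENTS",
    "SEVERITY_ORDER",
    "SEVERITY_CUTOFFS",
    "DetectedEvent",
    "SubjectResult",
    "correct_sequence",
    "events_from_sequence",
    "compute_ahi",
    "severity_of",
]


@dataclass(frozen=True)
class DetectedEvent:
    """One detected AH event, half-open ``[start_s, end_s)``, always ≥10 s."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s - self.start_s < 10:
            raise ValueError(
                f"detected events span >= 10 s, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SubjectResult:
    """Per-subject detection outcome next to its reference."""

    subject_id: str
    events: list[DetectedEvent] = field(default_factory=list)
    ahi_est: float = 0.0
    ahi_ref: float = 0.0
    severity_est: str = "NON"
    severity_ref: str = "NON"
    event_minutes: float = 0.0


def _ah_runs(ah: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as inclusive (first, last) pairs."""
    if not ah.any():
        return []
    padded = np.diff(np.concatenate([[0], ah.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def correct_sequence(
    seq: LabelSequence,
    min_run: int = MIN_RUN_SEGMENTS,
    max_gap: int = MAX_GAP_SEGMENTS,
) -> LabelSequence:
    """Apply the two run-length rules; idempotent.

    Rule 1 first (short AH runs → N), then rule 2 (short N gaps between
    surviving valid runs → AH); merged runs are not re-tested against rule 1.
    UNKNOWN entries count as N for run accounting and are preserved unless
    rule 2 overwrites them.
    """
    labels = np.asarray(seq.labels, dtype=object).copy()
    ah = labels == AH
    runs = [(a, b) for a, b in _ah_runs(ah) if b - a + 1 >= min_run]
    valid = np.zeros(len(labels), dtype=bool)
    for a, b in runs:
        valid[a : b + 1] = True
    labels[ah & ~valid] = N
    for (_, prev_end), (next_start, _) in zip(runs, runs[1:]):
        gap = next_start - prev_end - 1
        if gap <= max_gap:
            labels[prev_end + 1 : next_start] = AH
    return LabelSequence(labels=labels, start_offset_s=seq.start_offset_s)


def events_from_sequence(seq: LabelSequence, window_s: int = 10) -> list[DetectedEvent]:
    """Read sorted, non-overlapping events off a corrected sequence."""
    labels = np.asarray(seq.labels, dtype=object)
    return [
        DetectedEvent(
            start_s=seq.start_offset_s + a,
            end_s=seq.start_offset_s + b + window_s,
        )
        for a, b in _ah_runs(labels == AH)
    ]


def compute_ahi(events: list[DetectedEvent], analyzed_duration_s: float) -> float:
    """Events per hour of analyzed recording time."""
    if analyzed_duration_s <= 0:
        raise ValueError(f"analyzed duration must be > 0, got {analyzed_duration_s}")
    return len(events) / (analyzed_duration_s / 3600.0)


def severity_of(ahi: float) -> str:
    """Severity grade at the standard cutoffs: <5 NON, <15 MILD, <30 MODERATE."""
    if ahi < 0:
        raise ValueError(f"AHI must be >= 0, got {ahi}")
    for grade, cutoff in zip(["NON", "MILD", "MODERATE"], SEVERITY_CUTOFFS):
        if ahi < cutoff:
            return grade
    return "SEVERE"
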