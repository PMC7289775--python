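"""Signal conditioning: artifact masking, NF filtering, segmentation, SpO2 alignment.

Four steps run before feature extraction:

1. SpO2 values below an artifact floor (default 50%) are masked invalid —
   finger-oximeter dropouts produce physiologically impossible readings.
2. NF is smoothed with a 4-point sliding average and high-passed with a
   third-order Butterworth filter (0.05 Hz cutoff) to strip baseline drift.
3. Both windows (60 s and 10 s) slide with a 1-s step; a segment is labeled
   AH when it overlaps the union of annotated events by more than 5 s.
4. SpO2 is advanced by ``tau_s`` seconds (default 23) so that the delayed
   desaturation response co-occurs with the flow signature of the event.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signal_io import Recording, RespiratoryEvent

logger = logging.getLogger(__name__)

AH = "AH"
N = "N"
UNKNOWN = "UNKNOWN"

#: Minimum input length for filter_nf (forward-backward filter padding).
MIN_FILTER_SAMPLES = 32

__all__ = [
    "AH",
    "N",
    "UNKNOWN",
    "PreprocessConfig",
    "Segment",
    "remove_artifacts",
    "filter_nf",
    "align_spo2",
    "segmentize",
    "label_segments",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters.

    ``tau_s`` is the SpO2 time advance in seconds and must satisfy
    0 < tau_s < 30; the default 23 is the value at which the detector
    performs best.  ``ah_overlap_s`` is the strict labeling threshold:
    a segment is AH only when event overlap exceeds it.
    """

    spo2_artifact_floor: float = 50.0
    ma_points: int = 4
    hp_order: int = 3
    hp_cutoff_hz: float = 0.05
    tau_s: int = 23
    step_s: int = 1
    ah_overlap_s: float = 5.0
    max_invalid_frac: float = 0.10
    ma_centered: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.tau_s < 30:
            raise ValueError(f"tau_s must lie in (0, 30), got {self.tau_s}")
        if self.ma_points < 1:
            raise ValueError("ma_points must be >= 1")
        if self.step_s != 1:
            raise ValueError("only the 1-s step is supported")

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PreprocessConfig":
        """Load from YAML or JSON; field names mirror the dataclass exactly."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Segment:
    """A windowed view of one recording: ``[start_s, start_s + window_s)``."""

    start_s: int
    window_s: int
    recording_ref: str
    label: str = UNKNOWN
    usable: bool = True


def remove_artifacts(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Mask SpO2 dropout artifacts (values below the artifact floor) as invalid.

    Sample values are untouched; only ``valid_mask`` changes.  The masked
    fraction is logged.
    """
    cfg = cfg or PreprocessConfig()
    out = rec.copy()
    bad = out.spo2 < cfg.spo2_artifact_floor
    out.valid_mask &= ~bad
    frac = float(np.mean(~out.valid_mask)) if out.n_samples else 0.0
    logger.info("recording %s: %.2f%% of samples invalid", rec.subject_id, 100 * frac)
    return out


def filter_nf(nf: np.ndarray, cfg: PreprocessConfig | None = None, sample_rate_hz: float = 8.0) -> np.ndarray:
    """Sliding-average then Butterworth high-pass filter the NF channel.

    The moving average (default 4 points, causal) suppresses high-frequency
    artifact noise; the high-pass (default third order, 0.05 Hz) removes
    baseline drift.  The high-pass stage is applied forward-backward so event
    timing is not delayed.
    """
    cfg = cfg or PreprocessConfig()
    nf = np.asarray(nf, dtype=float)
    if len(nf) < MIN_FILTER_SAMPLES:
        raise ValueError(
            f"filter_nf needs at least {MIN_FILTER_SAMPLES} samples, got {len(nf)}"
        )
    kernel = np.ones(cfg.ma_points) / cfg.ma_points
    if cfg.ma_centered:
        smoothed = np.convolve(nf, kernel, mode="same")
    else:
        smoothed = sps.lfilter(kernel, [1.0], nf)
    sos = sps.butter(
        cfg.hp_order, cfg.hp_cutoff_hz, btype="highpass", fs=sample_rate_hz, output="sos"
    )
    return sps.sosfiltfilt(sos, smoothed)


def align_spo2(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Advance SpO2 (and its validity) by ``tau_s`` seconds.

    Oximetry lags the airflow disturbance by roughly the lung-to-finger
    circulation time, so the desaturation caused by an event appears ~23 s
    after its flow signature; advancing SpO2 makes the two co-occur.  The
    trailing ``tau_s`` seconds, for which no future SpO2 exists, are marked
    invalid.
    """
    cfg = cfg or PreprocessConfig()
    shift = int(round(cfg.tau_s * rec.sample_rate_hz))
    if rec.n_samples <= shift:
        raise ValueError(
            f"recording of {rec.duration_s:.1f}s is shorter than tau_s={cfg.tau_s}s"
        )
    out = rec.copy()
    out.spo2 = np.concatenate([rec.spo2[shift:], np.full(shift, rec.spo2[-1])])
    shifted_valid = np.concatenate(
        [rec.valid_mask[shift:], np.zeros(shift, dtype=bool)]
    )
    # NF validity is unchanged; a sample is usable only if both channels are.
    out.valid_mask = rec.valid_mask & shifted_valid
    return out


def segmentize(
    rec: Recording, window_s: int, cfg: PreprocessConfig | None = None
) -> list[Segment]:
    """Slide a ``window_s`` window over the recording with a 1-s step.

    One segment per integer start second from 0 to ``duration - window_s``;
    segments whose invalid-sample fraction exceeds ``max_invalid_frac`` are
    flagged unusable.
    """
    cfg = cfg or PreprocessConfig()
    duration = int(np.floor(rec.duration_s))
    if duration < window_s:
        logger.warning(
            "recording %s (%.0fs) shorter than the %ds window; no segments",
            rec.subject_id,
            rec.duration_s,
            window_s,
        )
        return []
    fs = rec.sample_rate_hz
    win_n = int(round(window_s * fs))
    step_n = int(round(cfg.step_s * fs))
    n_starts = duration - window_s + 1
    # Vectorized invalid-fraction per window via a cumulative sum.
    c = np.concatenate([[0], np.cumsum(~rec.valid_mask)])
    starts_n = np.arange(n_starts) * step_n
    invalid = (c[starts_n + win_n] - c[starts_n]) / win_n
    return [
        Segment(
            start_s=int(t),
            window_s=window_s,
            recording_ref=rec.subject_id,
            usable=bool(invalid[t] <= cfg.max_invalid_frac),
        )
        for t in range(n_starts)
    ]


def _union_overlap(start: float, end: float, events: list[RespiratoryEvent]) -> float:
    """Length of the intersection of [start, end) with the union of events."""
    clipped = sorted(
        (max(start, e.onset_s), min(end, e.end_s))
        for e in events
        if e.end_s > start and e.onset_s < end
    )
    total = 0.0
    cur_end = start
    for a, b in clipped:
        a = max(a, cur_end)
        if b > a:
            total += b - a
            cur_end = b
    return total


def label_segments(
    segments: list[Segment],
    annotations: list[RespiratoryEvent],
    cfg: PreprocessConfig | None = None,
) -> list[Segment]:
    """Label each segment AH when event overlap strictly exceeds ``ah_overlap_s``.

    Overlap is measured against the *union* of annotated events, so the rule
    is invariant to splitting one event into abutting sub-events.  The same
    rule applies to 60-s and 10-s segments.  Unusable segments are labeled too
    (the flag, not the label, governs exclusion).
    """
    cfg = cfg or PreprocessConfig()
    out = []
    for seg in segments:
        overlap = _union_overlap(seg.start_s, seg.start_s + seg.window_s, annotations)
        label = AH if overlap > cfg.ah_overlap_s else N
        out.append(
            Segment(seg.start_s, seg.window_s, seg.recording_ref, label, seg.usable)
        )
    return out


def preprocess_recording(
    rec: Recording, cfg: PreprocessConfig | None = None
) -> tuple[Recording, list[Segment], list[Segment]]:
    """Run the full conditioning chain and return (recording, segs60, segs10).

    The returned recording has artifacts masked, NF filtered, and SpO2
    aligned; the two segment lists are labeled from the recording's own
    annotations.
    """
    cfg = cfg or PreprocessConfig()
    rec = remove_artifacts(rec, cfg)
    rec.nf = filter_nf(rec.nf, cfg, rec.sample_rate_hz)
    rec = align_spo2(rec, cfg)
    segs60 = label_segments(segmentize(rec, 60, cfg), rec.annotations, cfg)
    segs10 = label_segments(segmentize(rec, 10, cfg), rec.annotations, cfg)
    return rec, segs60, segs10
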