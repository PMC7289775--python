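"""Synthetic overnight NF/SpO2 recordings with ground-truth AH annotations.

The generator emulates the structure the detector assumes in thermistor +
pulse-oximeter data: an amplitude-modulated breathing sinusoid (~0.25 Hz,
jittered) over slow baseline drift and sensor noise; apneas and hypopneas
scheduled by a renewal process at a target AHI, each ≥10 s, scaling the
breathing envelope down to the event's residual fraction (≤10% for apneas,
10–70% for hypopneas, per the scoring definitions); an SpO2 channel at an
integer-quantized ~97% baseline whose desaturations (≥3% deep) start a fixed
circulation lag (default 23 s) after each event onset and recover
exponentially; and occasional oximeter dropout bursts below 50%.  Every event
is recorded exactly in the annotations, and everything is reproducible from
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .preprocess import PreprocessConfig, label_segments, segmentize
from .cascade import LabelSequence
from .signal_io import Recording, RespiratoryEvent

__all__ = [
    "SynthConfig",
    "generate_recording",
    "generate_cohort",
    "oracle_label_sequence",
    "SEVERITY_AHI_RANGES",
]

#: Per-severity target-AHI sampling ranges for cohort generation (events/h).
SEVERITY_AHI_RANGES = {
    "NON": (1.0, 4.5),
    "MILD": (6.0, 14.0),
    "MODERATE": (16.0, 29.0),
    "SEVERE": (31.0, 55.0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; the defaults are the study conditions.

    ``apnea_residual_frac`` and ``hypopnea_residual_range`` are the fractions
    of baseline breathing amplitude remaining during an event (apnea: >90%
    drop; hypopnea: 30–90% drop).  ``desat_lag_s`` is the circulation delay
    from event onset to desaturation onset.  ``artifact_rate`` is the
    fraction of SpO2 samples replaced by sub-50% dropout bursts.
    """

    duration_s: float = 3600.0
    target_ahi: float = 15.0
    apnea_fraction: float = 0.5
    resp_freq_hz: float = 0.25
    resp_freq_jitter: float = 0.08
    baseline_amp: float = 1.0
    apnea_residual_frac: float = 0.08
    hypopnea_residual_range: tuple[float, float] = (0.1, 0.7)
    event_duration_range_s: tuple[float, float] = (15.0, 45.0)
    desat_depth_range_pct: tuple[float, float] = (3.0, 10.0)
    desat_lag_s: float = 23.0
    spo2_baseline_pct: float = 97.0
    spo2_quantize: bool = True
    artifact_rate: float = 0.01
    noise_sd: float = 0.03
    drift_amp: float = 0.3
    drift_freq_hz: float = 0.005
    min_event_gap_s: float = 15.0
    sample_rate_hz: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_duration_range_s[0] < 10:
            raise ValueError("event durations must be >= 10 s")
        if not 0 < self.desat_lag_s < 30:
            raise ValueError("desat_lag_s must lie in (0, 30)")
        if self.desat_depth_range_pct[0] < 3:
            raise ValueError("desaturation depth must be >= 3%")
        if not self.apnea_residual_frac <= 0.1:
            raise ValueError("apnea residual must be <= 0.1 (>90% drop)")
        if not self.apnea_residual_frac < self.hypopnea_residual_range[0]:
            raise ValueError("apnea residual must lie below the hypopnea range")
        if self.target_ahi < 0:
            raise ValueError("target_ahi must be >= 0")


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, sigma_s: float) -> np.ndarray:
    """Unit-variance Gaussian-smoothed noise (smoothness scale ``sigma_s`` s)."""
    x = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma=sigma_s * fs)
    sd = x.std()
    return x / sd if sd > 0 else x


def _schedule_events(cfg: SynthConfig, rng: np.random.Generator) -> list[RespiratoryEvent]:
    """Renewal-process event schedule targeting ``target_ahi`` events/h."""
    if cfg.target_ahi == 0:
        return []
    mean_interval = 3600.0 / cfg.target_ahi
    mean_dur = float(np.mean(cfg.event_duration_range_s))
    mean_gap = mean_interval - mean_dur
    if mean_gap <= cfg.min_event_gap_s:
        raise ValueError(
            f"target_ahi={cfg.target_ahi} infeasible: mean inter-event gap "
            f"{mean_gap:.1f}s does not exceed the minimum separation "
            f"{cfg.min_event_gap_s}s"
        )
    end_margin = cfg.desat_lag_s + 17.0  # room for the desaturation to land
    events: list[RespiratoryEvent] = []
    t = 30.0  # settle-in margin so the first event has a clean pre-baseline
    while True:
        t += cfg.min_event_gap_s + rng.exponential(mean_gap - cfg.min_event_gap_s)
        dur = rng.uniform(*cfg.event_duration_range_s)
        if t + dur > cfg.duration_s - end_margin:
            break
        label = "APNEA" if rng.random() < cfg.apnea_fraction else "HYPOPNEA"
        events.append(RespiratoryEvent(round(t, 1), round(dur, 1), label))
        t += dur
    return events


def generate_recording(
    cfg: SynthConfig, subject_id: str | None = None, return_internals: bool = False
):
    """Generate one annotated recording (optionally with clean internals).

    With ``return_internals=True`` a ``(recording, internals)`` pair is
    returned; ``internals`` holds the noise-free NF, the event-scaled
    breathing envelope, and the pre-quantization SpO2, for tests that check
    the generated morphology directly.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate_hz
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs

    events = _schedule_events(cfg, rng)

    # --- NF channel -------------------------------------------------------
    freq = cfg.resp_freq_hz * (
        1.0 + cfg.resp_freq_jitter * np.clip(_smooth_noise(rng, n, fs, 4.0), -2.5, 2.5)
    )
    phase = 2.0 * np.pi * np.cumsum(freq) / fs
    env = cfg.baseline_amp * (1.0 + 0.1 * np.clip(_smooth_noise(rng, n, fs, 10.0), -2.5, 2.5))

    event_factor = np.ones(n)
    ramp_s = 2.0
    residuals: list[float] = []
    for ev in events:
        if ev.label == "APNEA":
            res = cfg.apnea_residual_frac * rng.uniform(0.5, 1.0)
        else:
            res = rng.uniform(*cfg.hypopnea_residual_range)
        residuals.append(res)
        i0, i1 = int(ev.onset_s * fs), int(ev.end_s * fs)
        nr = min(int(ramp_s * fs), (i1 - i0) // 2)
        seg = np.full(i1 - i0, res)
        if nr > 0:
            down = res + (1 - res) * 0.5 * (1 + np.cos(np.linspace(0, np.pi, nr)))
            seg[:nr] = down
            seg[-nr:] = down[::-1]
        event_factor[i0:i1] = seg

    clean_nf = env * event_factor * np.sin(phase)
    drift = cfg.drift_amp * np.sin(2 * np.pi * cfg.drift_freq_hz * t + rng.uniform(0, 2 * np.pi))
    nf = clean_nf + drift + rng.normal(0.0, cfg.noise_sd, n)

    # --- SpO2 channel -----------------------------------------------------
    wander = 0.4 * _smooth_noise(rng, n, fs, 30.0)
    dip = np.zeros(n)
    for ev in events:
        depth = rng.uniform(*cfg.desat_depth_range_pct)
        t0 = ev.onset_s + cfg.desat_lag_s
        fall_s = 8.0
        hold_s = max(2.0, ev.duration_s - fall_s)
        rec_tau_s = 15.0
        i0 = int(t0 * fs)
        i_fall = min(n, i0 + int(fall_s * fs))
        i_hold = min(n, i_fall + int(hold_s * fs))
        shape = np.zeros(n)
        shape[i0:i_fall] = 0.5 * (1 - np.cos(np.linspace(0, np.pi, i_fall - i0)))
        shape[i_fall:i_hold] = 1.0
        rec_len = min(n - i_hold, int(6 * rec_tau_s * fs))
        if rec_len > 0:
            shape[i_hold : i_hold + rec_len] = np.exp(
                -np.arange(rec_len) / (rec_tau_s * fs)
            )
        dip = np.maximum(dip, depth * shape)
    clean_spo2 = cfg.spo2_baseline_pct + wander - dip
    spo2 = clean_spo2 + rng.normal(0.0, 0.15, n)
    if cfg.spo2_quantize:
        spo2 = np.round(spo2)
    spo2 = np.clip(spo2, 50.0, 100.0)

    # --- oximeter dropout artifacts --------------------------------------
    if cfg.artifact_rate > 0:
        burst_len = int(2.0 * fs)
        n_bursts = max(1, int(round(cfg.artifact_rate * n / burst_len)))
        starts = rng.integers(0, max(1, n - burst_len), size=n_bursts)
        for s in starts:
            spo2[s : s + burst_len] = rng.uniform(20.0, 45.0)

    rec = Recording(
        subject_id=subject_id or f"synth-{cfg.seed}",
        sample_rate_hz=fs,
        nf=nf,
        spo2=spo2,
        annotations=list(events),
    )
    if return_internals:
        internals = {
            "clean_nf": clean_nf,
            "envelope": env * event_factor,
            "event_factor": event_factor,
            "clean_spo2": clean_spo2,
            "wander": wander,
            "dip": dip,
            "residuals": residuals,
        }
        return rec, internals
    return rec


def generate_cohort(
    n_subjects: int = 24,
    severity_mix: tuple[int, int, int, int] = (2, 12, 5, 5),
    seed: int = 0,
    base_cfg: SynthConfig | None = None,
) -> list[Recording]:
    """Generate a cohort with per-subject target AHIs drawn per severity group.

    ``severity_mix`` gives the number of NON/MILD/MODERATE/SEVERE subjects and
    must sum to ``n_subjects``.  Per-subject seeds and target AHIs derive
    deterministically from the master seed.
    """
    if sum(severity_mix) != n_subjects:
        raise ValueError(
            f"severity_mix {severity_mix} sums to {sum(severity_mix)}, "
            f"expected n_subjects={n_subjects}"
        )
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base_cfg = base_cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    cohort: list[Recording] = []
    idx = 0
    for grade, count in zip(SEVERITY_AHI_RANGES, severity_mix):
        lo, hi = SEVERITY_AHI_RANGES[grade]
        for _ in range(count):
            ahi = float(rng.uniform(lo, hi))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            cfg = replace(base_cfg, target_ahi=ahi, seed=sub_seed)
            cohort.append(
                generate_recording(cfg, subject_id=f"s{idx:02d}-{grade.lower()}")
            )
            idx += 1
    return cohort


def oracle_label_sequence(
    rec: Recording, window_s: int = 10, cfg: PreprocessConfig | None = None
) -> LabelSequence:
    """The label sequence the labeling rule yields from ground-truth annotations.

    Lets the event detector be tested independently of the classifier: these
    are the labels a perfect segment classifier would output.
    """
    cfg = cfg or PreprocessConfig()
    segments = label_segments(segmentize(rec, window_s, cfg), rec.annotations, cfg)
    labels = np.array([s.label for s in segments], dtype=object)
    return LabelSequence(labels=labels)
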