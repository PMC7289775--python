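"""Morphological feature extraction from NF and SpO2 segments.

Nineteen features per segment, in two families:

* NF family — built on per-breath tidal volume ``Ft`` (the difference between
  two adjacent signal extrema) and its 30-s rolling baseline ``Fb`` (the
  maximum ``Ft`` over the 30 s preceding the segment): mean/SD/range of
  ``Ft``; counts and fractions of breaths dropping >30% (``Fha``/``Fhap``),
  >70% (``Fap``/``Fapp``) below ``Fb`` or staying above 85% of it
  (``Fnor``/``Fnorp``); and ``Fkur``, the fourth standardized moment of the
  NF magnitude spectrum restricted to the 0.2–0.4 Hz breathing band (apneic
  breathing scatters spectral energy that normal breathing concentrates in a
  single peak, lowering the moment).

* SpO2 family — SD, range, and first-to-last tendency of SpO2; seconds spent
  below 92%/91% (``Sp92``/``Sp91``); seconds below 98% of the rolling
  baselines ``Spbm``/``Spba`` (max / mean SpO2 in the preceding 30 s,
  ``Spdum``/``Spdua``); and the desaturation levels
  ``Spldm = Spbm − mean(SpO2)``, ``Splda = Spba − mean(SpO2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .preprocess import Segment
from .signal_io import Recording

#: Table order of the feature columns.
FEATURE_NAMES = [
    "Fmean", "Fstd", "Fran",
    "Fha", "Fhap",
    "Fap", "Fapp",
    "Fnor", "Fnorp",
    "Fkur",
    "Spstd", "Spran",
    "Spten",
    "Spdum", "Spdua",
    "Spldm", "Splda",
    "Sp92", "Sp91",
]

#: Reduced set used by the 60-s screening detector: the >30%-drop breath
#: counts, the SpO2 dispersion pair, and the desaturation-duration pair.
REDUCED_FEATURES = ["Fha", "Fhap", "Spstd", "Spran", "Spdum", "Spdua"]

META_COLUMNS = ["recording", "start_s", "window_s"]

__all__ = [
    "FEATURE_NAMES",
    "REDUCED_FEATURES",
    "META_COLUMNS",
    "Breath",
    "Baselines",
    "detect_breaths",
    "rolling_baselines",
    "nf_features",
    "spo2_features",
    "extract_features",
]


@dataclass(frozen=True)
class Breath:
    """One breath: a pair of adjacent NF extrema and their amplitude difference."""

    t_max_s: float
    t_min_s: float
    tidal_volume: float

    def __post_init__(self) -> None:
        if self.tidal_volume < 0:
            raise ValueError("tidal_volume must be >= 0")

    @property
    def t_start_s(self) -> float:
        """Time of the breath's first extremum; used for window membership."""
        return min(self.t_max_s, self.t_min_s)


@dataclass(frozen=True)
class Baselines:
    """Rolling pre-segment baselines: max tidal volume, max and mean SpO2."""

    Fb: float
    Spbm: float
    Spba: float


def detect_breaths(
    nf: np.ndarray, sample_rate_hz: float = 8.0, prominence_frac: float = 0.05
) -> list[Breath]:
    """Detect breaths as disjoint pairs of consecutive NF extrema.

    Maxima and minima with prominence at least ``prominence_frac`` of the
    signal range are pooled and sorted in time; runs of same-sign extrema are
    collapsed to the most extreme one so the sequence alternates; consecutive
    extrema are then paired disjointly (1st–2nd, 3rd–4th, …), each pair
    yielding one breath with ``Ft = |v_a − v_b|``.  A flat signal yields an
    empty list.
    """
    nf = np.asarray(nf, dtype=float)
    rng = float(np.ptp(nf)) if len(nf) else 0.0
    if rng == 0.0:
        return []
    prom = prominence_frac * rng
    imax, _ = sps.find_peaks(nf, prominence=prom)
    imin, _ = sps.find_peaks(-nf, prominence=prom)
    idx = np.concatenate([imax, imin])
    kind = np.concatenate([np.ones(len(imax), bool), np.zeros(len(imin), bool)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]

    # Enforce alternation: within a same-kind run keep the most extreme point.
    keep_idx: list[int] = []
    keep_kind: list[bool] = []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            better = nf[i] > nf[keep_idx[-1]] if k else nf[i] < nf[keep_idx[-1]]
            if better:
                keep_idx[-1] = i
        else:
            keep_idx.append(int(i))
            keep_kind.append(bool(k))

    breaths: list[Breath] = []
    for a, b in zip(range(0, len(keep_idx) - 1, 2), range(1, len(keep_idx), 2)):
        ia, ib = keep_idx[a], keep_idx[b]
        t_a, t_b = ia / sample_rate_hz, ib / sample_rate_hz
        if keep_kind[a]:  # a is the max
            t_max, t_min = t_a, t_b
        else:
            t_max, t_min = t_b, t_a
        breaths.append(Breath(t_max, t_min, abs(float(nf[ia] - nf[ib]))))
    return breaths


def rolling_baselines(
    breaths: list[Breath],
    spo2: np.ndarray,
    segment_start_s: float,
    window_s: int = 10,
    lookback_s: float = 30.0,
    sample_rate_hz: float = 8.0,
) -> Baselines:
    """Compute the pre-segment baselines ``Fb``, ``Spbm``, ``Spba``.

    ``Fb`` is the maximum tidal volume among breaths starting in
    ``[segment_start − lookback, segment_start)``; ``Spbm``/``Spba`` are the
    max/mean of the valid SpO2 samples (``NaN`` marks invalid) in the same
    interval.  At recording start, where the interval is empty, the
    within-segment values are used instead.
    """
    spo2 = np.asarray(spo2, dtype=float)
    lo, hi = segment_start_s - lookback_s, segment_start_s
    ft_back = [b.tidal_volume for b in breaths if lo <= b.t_start_s < hi]
    if not ft_back:
        seg_end = segment_start_s + window_s
        ft_back = [b.tidal_volume for b in breaths if hi <= b.t_start_s < seg_end]
    fb = max(ft_back) if ft_back else 0.0

    i_lo = max(0, int(round(lo * sample_rate_hz)))
    i_hi = max(0, int(round(hi * sample_rate_hz)))
    window = spo2[i_lo:i_hi]
    window = window[~np.isnan(window)]
    if window.size == 0:
        i_end = int(round((segment_start_s + window_s) * sample_rate_hz))
        window = spo2[i_hi:i_end]
        window = window[~np.isnan(window)]
    if window.size == 0:
        return Baselines(Fb=fb, Spbm=0.0, Spba=0.0)
    return Baselines(Fb=fb, Spbm=float(np.max(window)), Spba=float(np.mean(window)))


def _band_kurtosis(x: np.ndarray, sample_rate_hz: float, mode: str = "magnitude") -> float:
    """Fourth standardized moment of the 0.2–0.4 Hz spectral values.

    ``mode`` selects the spectral quantity the moment is taken over:
    ``magnitude`` (default), ``power``, or ``time`` (kurtosis of the
    band-passed time-domain signal).
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if mode == "time":
        sos = sps.butter(3, [0.2, 0.4], btype="bandpass", fs=sample_rate_hz, output="sos")
        vals = sps.sosfiltfilt(sos, x)
    else:
        spec = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(len(x), d=1.0 / sample_rate_hz)
        vals = spec[(freqs >= 0.2) & (freqs <= 0.4)]
        if mode == "power":
            vals = vals**2
    if vals.size < 2 or np.allclose(vals, vals[0]):
        return 0.0
    return float(stats.kurtosis(vals, fisher=False, bias=True))


def nf_features(
    breaths: list[Breath],
    nf: np.ndarray,
    baselines: Baselines,
    sample_rate_hz: float = 8.0,
    fkur_mode: str = "magnitude",
) -> dict[str, float]:
    """NF feature sub-vector for one segment (breaths already restricted to it).

    A segment with no detected breaths yields the all-zero sub-vector, so
    downstream classifiers never see missing values.
    """
    ft = np.array([b.tidal_volume for b in breaths], dtype=float)
    out = dict.fromkeys(
        ["Fmean", "Fstd", "Fran", "Fha", "Fhap", "Fap", "Fapp", "Fnor", "Fnorp"], 0.0
    )
    if ft.size:
        fb = baselines.Fb
        out["Fmean"] = float(ft.mean())
        out["Fstd"] = float(ft.std())
        out["Fran"] = float(np.ptp(ft))
        fha = int(np.sum(ft < 0.7 * fb))
        fap = int(np.sum(ft < 0.3 * fb))
        fnor = int(np.sum(ft > 0.85 * fb))
        out.update(
            Fha=float(fha), Fap=float(fap), Fnor=float(fnor),
            Fhap=fha / ft.size, Fapp=fap / ft.size, Fnorp=fnor / ft.size,
        )
    out["Fkur"] = _band_kurtosis(nf, sample_rate_hz, fkur_mode)
    return out


def spo2_features(
    spo2: np.ndarray,
    baselines: Baselines,
    sample_rate_hz: float = 8.0,
) -> dict[str, float]:
    """SpO2 feature sub-vector for one segment (``NaN`` marks invalid samples).

    Duration features (``Sp92``, ``Sp91``, ``Spdum``, ``Spdua``) are reported
    in seconds (sample count ÷ rate).  An all-invalid segment yields the
    all-zero sub-vector.
    """
    spo2 = np.asarray(spo2, dtype=float)
    valid = spo2[~np.isnan(spo2)]
    names = ["Spstd", "Spran", "Spten", "Spdum", "Spdua", "Spldm", "Splda", "Sp92", "Sp91"]
    if valid.size == 0:
        return dict.fromkeys(names, 0.0)
    mean = float(valid.mean())
    return {
        "Spstd": float(valid.std()),
        "Spran": float(np.ptp(valid)),
        "Spten": float(valid[-1] - valid[0]),
        "Spdum": float(np.sum(valid < 0.98 * baselines.Spbm)) / sample_rate_hz,
        "Spdua": float(np.sum(valid < 0.98 * baselines.Spba)) / sample_rate_hz,
        "Spldm": baselines.Spbm - mean,
        "Splda": baselines.Spba - mean,
        "Sp92": float(np.sum(valid < 92.0)) / sample_rate_hz,
        "Sp91": float(np.sum(valid < 91.0)) / sample_rate_hz,
    }


def extract_features(
    rec: Recording,
    segments: list[Segment],
    prominence_frac: float = 0.05,
    fkur_mode: str = "magnitude",
) -> pd.DataFrame:
    """Extract the full feature table for every usable segment of a recording.

    Breaths are detected once on the whole (already filtered) NF channel so
    that overlapping windows agree on breath boundaries, then assigned to
    segments by their first-extremum time.  Returns one row per usable
    segment with ``recording, start_s, window_s, label`` metadata columns and
    the feature columns in table order; deterministic given its inputs.
    """
    breaths = detect_breaths(rec.nf, rec.sample_rate_hz, prominence_frac)
    b_times = np.array([b.t_start_s for b in breaths])
    ft_all = np.array([b.tidal_volume for b in breaths])
    fs = rec.sample_rate_hz
    spo2 = np.where(rec.valid_mask, rec.spo2, np.nan)

    def _baselines(start: float, win: int, a: int, b: int) -> Baselines:
        # searchsorted-based equivalent of rolling_baselines (O(log n)/segment)
        la = np.searchsorted(b_times, start - 30.0)
        ft_back = ft_all[la:a] if a > la else ft_all[a:b]
        fb = float(ft_back.max()) if ft_back.size else 0.0
        i_lo = max(0, int(round((start - 30.0) * fs)))
        i_hi = int(round(start * fs))
        w = spo2[i_lo:i_hi]
        w = w[~np.isnan(w)]
        if w.size == 0:
            w = spo2[i_hi : int(round((start + win) * fs))]
            w = w[~np.isnan(w)]
        if w.size == 0:
            return Baselines(fb, 0.0, 0.0)
        return Baselines(fb, float(w.max()), float(w.mean()))

    rows = []
    for seg in segments:
        if not seg.usable:
            continue
        start, win = seg.start_s, seg.window_s
        i0, i1 = int(round(start * fs)), int(round((start + win) * fs))
        a, b = np.searchsorted(b_times, [start, start + win])
        seg_breaths = breaths[a:b]
        base = _baselines(start, win, a, b)
        row = {
            "recording": seg.recording_ref,
            "start_s": start,
            "window_s": win,
            "label": seg.label,
        }
        row.update(nf_features(seg_breaths, rec.nf[i0:i1], base, fs, fkur_mode))
        row.update(spo2_features(spo2[i0:i1], base, fs))
        rows.append(row)
    columns = META_COLUMNS + ["label"] + FEATURE_NAMES
    return pd.DataFrame(rows, columns=columns)
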