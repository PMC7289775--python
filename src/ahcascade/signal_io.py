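"""Reading and writing polysomnography channels and respiratory-event annotations.

The canonical in-memory object is :class:`Recording`: paired nasal-flow (NF)
and SpO2 sample arrays on a common 8 Hz grid, a validity mask, and a list of
annotated respiratory events.  Channels whose native rate differs from the
canonical rate are converted on read: slower SpO2 by sample-and-hold, faster
NF by block-mean decimation.

Time convention: seconds from recording start, 0-based; event intervals are
half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CANONICAL_RATE_HZ = 8.0

__all__ = [
    "CANONICAL_RATE_HZ",
    "Recording",
    "RespiratoryEvent",
    "FormatError",
    "MissingChannelError",
    "read_edf",
    "write_edf",
    "read_csv_recording",
    "write_csv_recording",
    "read_annotations",
    "write_annotations",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


class MissingChannelError(KeyError):
    """Raised when a named signal channel is absent from an EDF file."""


@dataclass(frozen=True)
class RespiratoryEvent:
    """One annotated respiratory event: ``[onset_s, onset_s + duration_s)``.

    ``label`` is free text (``APNEA``, ``HYPOPNEA``, or whatever the source
    annotation file uses); apneas and hypopneas are pooled into one positive
    class downstream, so the label is informative only.
    """

    onset_s: float
    duration_s: float
    label: str = "AH"

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise FormatError(f"event onset must be >= 0, got {self.onset_s}")
        if self.duration_s < 0:
            raise FormatError(f"event duration must be >= 0, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Recording:
    """Paired NF/SpO2 channels on a uniform grid with a validity mask.

    Invariants (checked on construction): the three arrays share one length;
    every annotation lies within ``[0, duration_s)``.
    """

    subject_id: str
    sample_rate_hz: float
    nf: np.ndarray
    spo2: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    annotations: list[RespiratoryEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nf = np.asarray(self.nf, dtype=float)
        self.spo2 = np.asarray(self.spo2, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.nf.shape, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not (len(self.nf) == len(self.spo2) == len(self.valid_mask)):
            raise ValueError(
                "nf, spo2 and valid_mask must have identical length, got "
                f"{len(self.nf)}/{len(self.spo2)}/{len(self.valid_mask)}"
            )
        for ev in self.annotations:
            if ev.onset_s >= self.duration_s:
                raise ValueError(
                    f"annotation at {ev.onset_s}s lies outside the recording "
                    f"({self.duration_s}s)"
                )

    @property
    def n_samples(self) -> int:
        return len(self.nf)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def copy(self) -> "Recording":
        return replace(
            self,
            nf=self.nf.copy(),
            spo2=self.spo2.copy(),
            valid_mask=self.valid_mask.copy(),
            annotations=list(self.annotations),
        )


# ---------------------------------------------------------------------------
# Rate conversion helpers
# ---------------------------------------------------------------------------

def _to_canonical_rate(x: np.ndarray, native_hz: float, *, hold: bool) -> np.ndarray:
    """Convert ``x`` from its native rate to the canonical 8 Hz grid.

    Slower channels are upsampled by sample-and-hold; faster channels are
    decimated, by block mean (``hold=False``, for NF) or by stride sampling
    (``hold=True``, for already-held SpO2).
    """
    if native_hz == CANONICAL_RATE_HZ:
        return x
    if native_hz < CANONICAL_RATE_HZ:
        factor = CANONICAL_RATE_HZ / native_hz
        if abs(factor - round(factor)) > 1e-9:
            raise FormatError(
                f"native rate {native_hz} Hz is not an integer divisor of "
                f"{CANONICAL_RATE_HZ} Hz"
            )
        return np.repeat(x, int(round(factor)))
    factor = native_hz / CANONICAL_RATE_HZ
    if abs(factor - round(factor)) > 1e-9:
        raise FormatError(
            f"native rate {native_hz} Hz is not an integer multiple of "
            f"{CANONICAL_RATE_HZ} Hz"
        )
    k = int(round(factor))
    n = (len(x) // k) * k
    if hold:
        return x[:n:k]
    return x[:n].reshape(-1, k).mean(axis=1)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_native_rates(path: Path) -> dict[str, float]:
    """Per-channel native sample rates, parsed from the EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        try:
            record_dur = float(header[244:252].decode("ascii").strip())
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path.name}: malformed EDF header") from exc
        chan_header = fh.read(256 * ns)
    labels = [
        chan_header[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    # samples-per-record field follows label/transducer/dim/phys/dig/prefilter
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    rates = {}
    for i, label in enumerate(labels):
        spr = int(chan_header[off + i * 8 : off + (i + 1) * 8].decode("ascii").strip())
        rates[label] = spr / record_dur
    return rates


def read_edf(
    path: str | Path,
    nf_channel: str = "Flow",
    spo2_channel: str = "SpO2",
) -> Recording:
    """Read NF and SpO2 channels from an EDF file onto the canonical 8 Hz grid.

    Channels are located by name.  mne decodes and scales the samples; since
    it interpolates slower channels up to the file's highest rate, each
    channel is first restored to its native grid (the native grid points are
    exact) and then converted to 8 Hz — sample-and-hold for slower SpO2,
    block-mean decimation for faster NF.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"could not read EDF file {path}: {exc}") from exc

    for name in (nf_channel, spo2_channel):
        if name not in raw.ch_names:
            raise MissingChannelError(
                f"channel {name!r} not found in {path.name}; "
                f"available: {raw.ch_names}"
            )
    native = _edf_native_rates(path)
    sfreq = float(raw.info["sfreq"])

    def _native(name: str) -> tuple[np.ndarray, float]:
        data = raw.get_data(picks=[name])[0]
        rate = native.get(name, sfreq)
        if rate < sfreq:
            k = sfreq / rate
            if abs(k - round(k)) > 1e-9:
                raise FormatError(
                    f"channel {name!r}: native rate {rate} Hz incompatible "
                    f"with file grid {sfreq} Hz"
                )
            data = data[:: int(round(k))]
        return data, rate

    nf, nf_rate = _native(nf_channel)
    spo2, spo2_rate = _native(spo2_channel)
    nf = _to_canonical_rate(nf, nf_rate, hold=False)
    spo2 = _to_canonical_rate(spo2, spo2_rate, hold=True)
    n = min(len(nf), len(spo2))
    return Recording(
        subject_id=path.stem,
        sample_rate_hz=CANONICAL_RATE_HZ,
        nf=nf[:n],
        spo2=spo2[:n],
    )


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as a minimal EDF file (16-bit, one data record per second).

    Covers the subset of the format needed for round-trip tests and interop
    with standard readers: a plain EDF header and int16 little-endian sample
    records; no EDF+ annotations.  Values are scaled to the per-channel
    physical min/max.
    """
    path = Path(path)
    fs = rec.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    spr = int(round(fs))  # samples per 1-s record, per channel
    n_rec = rec.n_samples // spr
    channels = [("Flow", rec.nf[: n_rec * spr]), ("SpO2", rec.spo2[: n_rec * spr])]

    def _pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            _pad("0", 8),  # version
            _pad(rec.subject_id, 80),  # patient id
            _pad(rec.subject_id, 80),  # recording id
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + len(channels))), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),  # record duration, s
            _pad(str(len(channels)), 4),
        ]
    )

    digital_min, digital_max = -32768, 32767
    scaled: list[np.ndarray] = []
    phys: list[tuple[float, float]] = []
    for _, data in channels:
        lo = float(np.min(data)) if len(data) else 0.0
        hi = float(np.max(data)) if len(data) else 1.0
        if hi <= lo:
            hi = lo + 1.0
        phys.append((lo, hi))
        dig = np.round(
            (data - lo) / (hi - lo) * (digital_max - digital_min) + digital_min
        ).astype(np.int16)
        scaled.append(dig)

    def _field(values: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in values)

    names = [name for name, _ in channels]
    header += _field(names, 16)  # label
    header += _field(["" for _ in channels], 80)  # transducer
    header += _field(["" for _ in channels], 8)  # physical dimension
    header += _field([f"{lo:.4f}"[:8] for lo, _ in phys], 8)
    header += _field([f"{hi:.4f}"[:8] for _, hi in phys], 8)
    header += _field([str(digital_min) for _ in channels], 8)
    header += _field([str(digital_max) for _ in channels], 8)
    header += _field(["" for _ in channels], 80)  # prefiltering
    header += _field([str(spr) for _ in channels], 8)
    header += _field(["" for _ in channels], 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for dig in scaled:
                block = dig[r * spr : (r + 1) * spr]
                fh.write(struct.pack(f"<{spr}h", *block))


# ---------------------------------------------------------------------------
# Delimited text recording dialect: columns time_s, nf, spo2
# ---------------------------------------------------------------------------

def read_csv_recording(path: str | Path, subject_id: str | None = None) -> Recording:
    """Read a delimited-text recording with columns ``time_s, nf, spo2``.

    Timestamps must form a uniform, strictly increasing grid; the grid spacing
    defines the sample rate.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"time_s", "nf", "spo2"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path.name}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) == 0:
        raise FormatError(f"{path.name}: empty recording file")
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError(f"{path.name}: time column must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-6:
            raise FormatError(f"{path.name}: non-uniform timestamp spacing")
        rate = 1.0 / dt[0]
    else:
        rate = CANONICAL_RATE_HZ
    mask = df["valid"].to_numpy(dtype=bool) if "valid" in df.columns else None
    return Recording(
        subject_id=subject_id or path.stem,
        sample_rate_hz=rate,
        nf=df["nf"].to_numpy(dtype=float),
        spo2=df["spo2"].to_numpy(dtype=float),
        valid_mask=mask,
    )


def write_csv_recording(rec: Recording, path: str | Path) -> None:
    """Write the ``time_s, nf, spo2, valid`` dialect read by :func:`read_csv_recording`."""
    t = np.arange(rec.n_samples) / rec.sample_rate_hz
    df = pd.DataFrame(
        {"time_s": t, "nf": rec.nf, "spo2": rec.spo2, "valid": rec.valid_mask.astype(int)}
    )
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Annotations: columns onset_s, duration_s, label  (or the UCDDB respevt text)
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | Path,
    dialect: str = "csv",
    record_start: str | None = None,
) -> list[RespiratoryEvent]:
    """Read respiratory-event annotations, sorted by onset.

    ``dialect="csv"`` expects columns ``onset_s, duration_s, label``.
    ``dialect="ucddb"`` accepts the St. Vincent's database respiratory-event
    text layout (clock ``Time``, ``Type`` and ``Duration`` columns, two header
    lines); ``record_start`` ("HH:MM:SS") anchors clock times to seconds from
    recording start, wrapping past midnight.
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, sep=None, engine="python")
        if df.empty and len(df.columns) <= 1:
            return []
        required = {"onset_s", "duration_s", "label"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"{path.name}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        events = [
            RespiratoryEvent(float(r.onset_s), float(r.duration_s), str(r.label))
            for r in df.itertuples()
        ]
    elif dialect == "ucddb":
        events = _read_ucddb_respevt(path, record_start)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return sorted(events, key=lambda e: (e.onset_s, e.duration_s))


def _read_ucddb_respevt(path: Path, record_start: str | None) -> list[RespiratoryEvent]:
    def clock_to_s(text: str) -> float:
        h, m, s = (int(p) for p in text.split(":"))
        return h * 3600.0 + m * 60.0 + s

    start = clock_to_s(record_start) if record_start else None
    events: list[RespiratoryEvent] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 3 or ":" not in parts[0]:
            continue  # header / blank lines
        onset = clock_to_s(parts[0])
        if start is not None:
            onset = (onset - start) % 86400.0
        label = parts[1]
        # Duration is the first numeric field after the type/PB-CS columns.
        duration = None
        for tok in parts[2:]:
            try:
                duration = float(tok)
                break
            except ValueError:
                continue
        if duration is None:
            raise FormatError(f"{path.name}: no duration field in line {line!r}")
        events.append(RespiratoryEvent(onset, duration, label))
    return events


def write_annotations(events: list[RespiratoryEvent], path: str | Path) -> None:
    """Write the ``onset_s, duration_s, label`` dialect read by :func:`read_annotations`."""
    df = pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "duration_s": [e.duration_s for e in events],
            "label": [e.label for e in events],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
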