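import struct

import numpy as np
import pytest

from ahcascade import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def clean_recording():
    """10-min synthetic recording, 30 events/h, no oximeter artifacts."""
    cfg = SynthConfig(duration_s=600, target_ahi=30, seed=42, artifact_rate=0.0)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def clean_recording_internals():
    cfg = SynthConfig(duration_s=600, target_ahi=30, seed=42, artifact_rate=0.0)
    return generate_recording(cfg, return_internals=True)


def write_mixed_rate_edf(path, channels):
    """Write a minimal EDF with per-channel native rates.

    ``channels`` is a list of (name, samples, rate_hz) with integer rates;
    record duration is 1 s.  Test-only helper for exercising rate conversion
    on read.
    """
    n_rec = min(len(d) // r for _, d, r in channels)

    def pad(s, w):
        b = s.encode("ascii")[:w]
        return b + b" " * (w - len(b))

    ns = len(channels)
    header = b"".join(
        [
            pad("0", 8), pad("test", 80), pad("test", 80),
            pad("01.01.00", 8), pad("00.00.00", 8),
            pad(str(256 * (1 + ns)), 8), pad("", 44),
            pad(str(n_rec), 8), pad("1", 8), pad(str(ns), 4),
        ]
    )
    phys, digs = [], []
    for _, d, _r in channels:
        d = np.asarray(d, dtype=float)
        lo, hi = float(d.min()), float(d.max())
        if hi <= lo:
            hi = lo + 1
        phys.append((lo, hi))
        digs.append(np.round((d - lo) / (hi - lo) * 65535 - 32768).astype(np.int16))

    field = lambda vals, w: b"".join(pad(v, w) for v in vals)  # noqa: E731
    header += field([c[0] for c in channels], 16)
    header += field([""] * ns, 80) + field([""] * ns, 8)
    header += field([f"{lo:.4f}"[:8] for lo, _ in phys], 8)
    header += field([f"{hi:.4f}"[:8] for _, hi in phys], 8)
    header += field(["-32768"] * ns, 8) + field(["32767"] * ns, 8)
    header += field([""] * ns, 80)
    header += field([str(c[2]) for c in channels], 8)
    header += field([""] * ns, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            for (_, _, rate), dig in zip(channels, digs):
                block = dig[rec * rate : (rec + 1) * rate]
                fh.write(struct.pack(f"<{rate}h", *block))
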