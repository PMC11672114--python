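"""Minimal European Data Format (EDF) reader and writer.

Supports plain EDF with 16-bit samples, one-second data records and
per-channel sampling rates — everything this pipeline needs to exchange
signals between devices with different clocks (256 Hz PSG, 250 Hz in-ear).
Physical/digital scaling is honoured on read; writing picks a per-channel
physical range covering the observed min/max, so a write/read round trip is
exact up to 16-bit quantization.
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np

_HDR_FIXED = 256
_HDR_PER_CHANNEL = 16 + 80 + 8 + 8 + 8 + 8 + 8 + 80 + 8 + 32
_RECORD_S = 1.0  # data record duration used by the writer


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, channels: dict[str, np.ndarray], fs: dict[str, float]) -> None:
    """Write channels to a plain EDF file with 1-second records.

    Each channel's sampling rate must be a positive integer; trailing samples
    that do not fill a whole record are dropped.
    """
    names = list(channels)
    if not names:
        raise ValueError("nothing to write")
    for n in names:
        if abs(fs[n] - round(fs[n])) > 1e-9 or fs[n] <= 0:
            raise ValueError(f"EDF writer needs integer sampling rates, got {fs[n]} for {n!r}")

    n_records = min(int(len(channels[n]) // fs[n]) for n in names)
    if n_records < 1:
        raise ValueError("less than one record of data")

    spr = {n: int(round(fs[n] * _RECORD_S)) for n in names}
    dmin, dmax = -32768, 32767
    pmin: dict[str, float] = {}
    pmax: dict[str, float] = {}
    digital: dict[str, np.ndarray] = {}
    for n in names:
        x = np.asarray(channels[n], dtype=float)[: n_records * spr[n]]
        lo, hi = float(x.min()), float(x.max())
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        gain = (hi - lo) / (dmax - dmin)
        digital[n] = np.clip(np.round((x - lo) / gain) + dmin, dmin, dmax).astype("<i2")
        pmin[n], pmax[n] = lo, hi

    ns = len(names)
    header_bytes = _HDR_FIXED + ns * _HDR_PER_CHANNEL
    parts = [
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(header_bytes), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field(f"{_RECORD_S:g}", 8),
        _field(str(ns), 4),
    ]
    for width, values in (
        (16, names),
        (80, [""] * ns),
        (8, ["uV"] * ns),
        (8, [f"{pmin[n]:.6g}"[:8] for n in names]),
        (8, [f"{pmax[n]:.6g}"[:8] for n in names]),
        (8, [str(dmin)] * ns),
        (8, [str(dmax)] * ns),
        (80, [""] * ns),
        (8, [str(spr[n]) for n in names]),
        (32, [""] * ns),
    ):
        parts.extend(_field(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        for r in range(n_records):
            for n in names:
                fh.write(digital[n][r * spr[n] : (r + 1) * spr[n]].tobytes())


def read_edf(path: str | Path) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Read a plain EDF file; returns (channels, sampling rates).

    Per-channel sampling rates are preserved exactly as stored — mixed-rate
    files are never resampled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    raw = path.read_bytes()
    if len(raw) < _HDR_FIXED:
        raise ValueError(f"unparseable EDF header in {path}: file too short")
    try:
        header_bytes = int(raw[184:192].decode("ascii").strip())
        n_records = int(raw[236:244].decode("ascii").strip())
        record_s = float(raw[244:252].decode("ascii").strip())
        ns = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise ValueError(f"unparseable EDF header in {path}: {exc}") from exc
    if ns < 1:
        raise ValueError(f"EDF file {path} declares zero channels")

    def block(offset: int, width: int) -> list[str]:
        out = []
        for i in range(ns):
            start = _HDR_FIXED + offset * ns + i * width
            out.append(raw[start : start + width].decode("ascii").strip())
        return out

    labels = block(0, 16)
    pmin = [float(v) for v in block(16 + 80 + 8, 8)]
    pmax = [float(v) for v in block(16 + 80 + 8 + 8, 8)]
    dmin = [int(v) for v in block(16 + 80 + 8 + 8 + 8, 8)]
    dmax = [int(v) for v in block(16 + 80 + 8 + 8 + 8 + 8, 8)]
    spr = [int(v) for v in block(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8)]

    rec_len = sum(spr)
    data = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    if n_records < 0:  # unknown record count: infer from file size
        n_records = len(data) // rec_len
    data = data[: n_records * rec_len].reshape(n_records, rec_len)

    channels: dict[str, np.ndarray] = {}
    fs: dict[str, float] = {}
    col = 0
    for i, name in enumerate(labels):
        seg = data[:, col : col + spr[i]].reshape(-1).astype(float)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        channels[name] = gain * (seg - dmin[i]) + pmin[i]
        fs[name] = spr[i] / record_s
        col += spr[i]
    return channels, fs
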