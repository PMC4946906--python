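"""EDF and event-table I/O.

Recordings are stored as EDF (European Data Format): a fixed-width ASCII
header followed by interleaved 16-bit little-endian integer data records,
with per-channel physical/digital calibration. The writer chooses a
symmetric physical range covering the observed extrema, so round-trip
error is bounded by one digitization step (physical range / 2^16). Only
classic single-rate EDF is supported (no EDF+ annotations).

Event tables are plain CSV with columns ``channel,start_s,end_s,label``
(plus optional per-event feature columns), sorted by (channel, start);
comment lines starting with ``#`` carry provenance and are ignored on
read.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EVENT_COLUMNS, EEGRecording

__all__ = ["read_edf", "write_edf", "read_events", "write_events"]

# symmetric digital range so that 0 µV maps to the exact code 0
_DIG_MIN, _DIG_MAX = -32767, 32767

# unit string (EDF "physical dimension") -> multiplier to µV
_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6, "": 1.0}


class EDFFormatError(ValueError):
    """Raised when an EDF header field cannot be parsed."""


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} does not fit in {width} ascii chars")
    return s.ljust(width).encode("ascii")


def _num(raw: bytes, field: str, kind=float):
    try:
        return kind(raw.decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as exc:
        raise EDFFormatError(f"malformed EDF header field {field!r}: {raw!r}") from exc


def _samples_per_record(n_samples: int, sampling_rate: float) -> int:
    """Largest divisor of n_samples not exceeding one second of samples."""
    cap = max(1, int(round(sampling_rate)))
    for k in range(min(cap, n_samples), 0, -1):
        if n_samples % k == 0:
            return k
    return 1


def write_edf(recording: EEGRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with µV physical units."""
    if not np.all(np.isfinite(recording.samples)):
        raise ValueError("cannot write non-finite samples to EDF")
    path = Path(path)
    ns = recording.n_channels
    spr = _samples_per_record(recording.n_samples, recording.sampling_rate)
    n_records = recording.n_samples // spr
    record_duration = spr / recording.sampling_rate

    peak = float(np.max(np.abs(recording.samples))) if recording.n_samples else 0.0
    peak = peak if peak > 0 else 1.0
    # round the range so the ASCII header field is exact
    phys_max = float(f"{peak:.6g}")
    if phys_max < peak:
        phys_max = float(f"{peak * (1 + 1e-5):.6g}")
    phys_min = -phys_max
    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)

    now = datetime.datetime(2000, 1, 1)  # fixed stamp: output is seed-reproducible
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X", 80),
            _ascii("swdkit", 80),
            _ascii(now.strftime("%d.%m.%y"), 8),
            _ascii(now.strftime("%H.%M.%S"), 8),
            _ascii(256 * (1 + ns), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(f"{record_duration:.6g}", 8),
            _ascii(ns, 4),
        ]
    )
    sig = b"".join(_ascii(lbl[:16], 16) for lbl in recording.channel_labels)
    sig += b"".join(_ascii("", 80) for _ in range(ns))
    sig += b"".join(_ascii("uV", 8) for _ in range(ns))
    sig += b"".join(_ascii(f"{phys_min:.6g}", 8) for _ in range(ns))
    sig += b"".join(_ascii(f"{phys_max:.6g}", 8) for _ in range(ns))
    sig += b"".join(_ascii(_DIG_MIN, 8) for _ in range(ns))
    sig += b"".join(_ascii(_DIG_MAX, 8) for _ in range(ns))
    sig += b"".join(_ascii("BP:0.1-1000Hz", 80) for _ in range(ns))
    sig += b"".join(_ascii(spr, 8) for _ in range(ns))
    sig += b"".join(_ascii("", 32) for _ in range(ns))

    digital = np.round((recording.samples - phys_min) / gain + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
    # interleave: records x channels x samples_per_record
    interleaved = (
        digital[:, : n_records * spr]
        .reshape(ns, n_records, spr)
        .transpose(1, 0, 2)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(interleaved.tobytes())


def read_edf(path: str | Path) -> EEGRecording:
    """Read a classic EDF file into an :class:`EEGRecording` (µV).

    Samples are converted to µV via the per-channel physical dimension
    and calibration fields. All channels must share one sampling rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    raw = path.read_bytes()
    if len(raw) < 256:
        raise EDFFormatError(f"file too short for an EDF header: {path}")
    n_records = _num(raw[236:244], "number of data records", int)
    record_duration = _num(raw[244:252], "duration of a data record")
    ns = _num(raw[252:256], "number of signals", int)
    if ns < 1:
        raise EDFFormatError(f"malformed EDF header field 'number of signals': {ns}")
    need = 256 + 256 * ns
    if len(raw) < need:
        raise EDFFormatError("file too short for its signal headers")

    def field(offset: int, width: int, i: int) -> bytes:
        base = 256 + offset * ns
        return raw[base + i * width : base + (i + 1) * width]

    # per-signal header layout offsets (in bytes, cumulative per field block)
    labels = [field(0, 16, i).decode("ascii", "replace").strip() for i in range(ns)]
    dims = [raw[256 + 96 * ns + 8 * i : 256 + 96 * ns + 8 * (i + 1)].decode("ascii", "replace").strip() for i in range(ns)]
    phys_min = [_num(raw[256 + 104 * ns + 8 * i : 256 + 104 * ns + 8 * (i + 1)], "physical minimum") for i in range(ns)]
    phys_max = [_num(raw[256 + 112 * ns + 8 * i : 256 + 112 * ns + 8 * (i + 1)], "physical maximum") for i in range(ns)]
    dig_min = [_num(raw[256 + 120 * ns + 8 * i : 256 + 120 * ns + 8 * (i + 1)], "digital minimum", int) for i in range(ns)]
    dig_max = [_num(raw[256 + 128 * ns + 8 * i : 256 + 128 * ns + 8 * (i + 1)], "digital maximum", int) for i in range(ns)]
    spr = [_num(raw[256 + 216 * ns + 8 * i : 256 + 216 * ns + 8 * (i + 1)], "samples per record", int) for i in range(ns)]

    if len(set(spr)) != 1:
        raise EDFFormatError(
            f"unsupported layout: mixed per-channel sampling rates (samples/record {spr})"
        )
    spr0 = spr[0]
    if record_duration <= 0:
        raise EDFFormatError(
            f"malformed EDF header field 'duration of a data record': {record_duration}"
        )
    sampling_rate = spr0 / record_duration

    data = np.frombuffer(raw[need:], dtype="<i2")
    expected = n_records * ns * spr0
    if data.size < expected:
        raise EDFFormatError(
            f"truncated data: expected {expected} samples, found {data.size}"
        )
    cube = data[:expected].reshape(n_records, ns, spr0).transpose(1, 0, 2)
    samples = cube.reshape(ns, n_records * spr0).astype(np.float64)
    for i in range(ns):
        if dig_max[i] == dig_min[i]:
            raise EDFFormatError(f"malformed EDF header field 'digital maximum' for signal {i}")
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        samples[i] = (samples[i] - dig_min[i]) * gain + phys_min[i]
        if dims[i] not in _UNIT_TO_UV:
            raise EDFFormatError(
                f"malformed EDF header field 'physical dimension': {dims[i]!r}"
            )
        samples[i] *= _UNIT_TO_UV[dims[i]]
    return EEGRecording(samples, sampling_rate, labels)


# ---------------------------------------------------------------------------
# Event tables (CSV)


def write_events(
    table: pd.DataFrame, path: str | Path, header_comments: list[str] | None = None
) -> None:
    """Write an event table as CSV, sorted by (channel, start).

    ``table`` must carry at least the columns
    ``channel,start_s,end_s,label``; extra per-event columns are kept.
    ``header_comments`` are written as leading ``#`` lines (provenance).
    """
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    bad = table.index[table["end_s"] <= table["start_s"]]
    if len(bad):
        raise ValueError(f"row {bad[0]}: end_s <= start_s")
    out = table.sort_values(["channel", "start_s"], kind="stable").reset_index(drop=True)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event-table CSV; validates intervals, returns sorted table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such event file: {path}")
    table = pd.read_csv(path, comment="#")
    if table.empty and not set(EVENT_COLUMNS) <= set(table.columns):
        return pd.DataFrame(columns=EVENT_COLUMNS)
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event file {path} missing columns: {missing}")
    bad = table.index[table["end_s"] <= table["start_s"]]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0]}: end_s <= start_s")
    return table.sort_values(["channel", "start_s"], kind="stable").reset_index(drop=True)
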