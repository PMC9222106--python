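"""Minimal EDF (European Data Format) reader and writer.

Supports the plain EDF profile used for multi-channel EEG/LFP interchange:
16-bit samples, per-signal sampling rates (via samples-per-record), no
annotations.  Sufficient for round-tripping recordings produced by this
package and for reading Pinnacle-style exports.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["EdfSignalHeader", "read_edf", "write_edf", "EdfFormatError", "read_edf_header"]

_DIG_MIN, _DIG_MAX = -32768, 32767


class EdfFormatError(ValueError):
    """Raised when a file does not parse as EDF; names the offending field."""


@dataclass
class EdfSignalHeader:
    label: str
    units: str
    physical_min: float
    physical_max: float
    digital_min: int
    digital_max: int
    samples_per_record: int
    transducer: str = ""
    prefiltering: str = ""


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def _num(text: str, width: int) -> bytes:
    return _pad(text, width)


def write_edf(
    path: str | Path,
    signals: list[np.ndarray],
    headers: list[EdfSignalHeader],
    record_duration: float = 1.0,
    patient_id: str = "X",
    recording_id: str = "X",
    start: _dt.datetime | None = None,
) -> None:
    """Write signals to an EDF file.

    Each ``signals[i]`` must contain an integer multiple of
    ``headers[i].samples_per_record`` samples and all signals must span the
    same number of records.
    """
    if len(signals) != len(headers):
        raise ValueError("one header per signal required")
    if not signals:
        raise ValueError("need at least one signal")
    n_records = None
    for sig, hdr in zip(signals, headers):
        if sig.size % hdr.samples_per_record:
            raise ValueError(
                f"signal {hdr.label!r}: length {sig.size} is not a multiple of "
                f"samples_per_record {hdr.samples_per_record}"
            )
        nr = sig.size // hdr.samples_per_record
        if n_records is None:
            n_records = nr
        elif nr != n_records:
            raise ValueError("all signals must span the same number of records")
    assert n_records is not None

    start = start or _dt.datetime(2000, 1, 1, 0, 0, 0)
    ns = len(signals)
    header_bytes = 256 * (1 + ns)

    parts = [
        _pad("0", 8),
        _pad(patient_id, 80),
        _pad(recording_id, 80),
        _pad(start.strftime("%d.%m.%y"), 8),
        _pad(start.strftime("%H.%M.%S"), 8),
        _num(str(header_bytes), 8),
        _pad("", 44),
        _num(str(n_records), 8),
        _num(_fmt_float(record_duration), 8),
        _num(str(ns), 4),
    ]
    for field, width in (
        ("label", 16),
        ("transducer", 80),
        ("units", 8),
        ("physical_min", 8),
        ("physical_max", 8),
        ("digital_min", 8),
        ("digital_max", 8),
        ("prefiltering", 80),
        ("samples_per_record", 8),
    ):
        for hdr in headers:
            val = getattr(hdr, field)
            text = _fmt_float(val) if isinstance(val, float) else str(val)
            parts.append(_pad(text, width))
    parts.append(_pad("", 32) * ns)

    digitized = []
    for sig, hdr in zip(signals, headers):
        pmin, pmax = hdr.physical_min, hdr.physical_max
        if not pmax > pmin:
            raise ValueError(f"signal {hdr.label!r}: physical_max must exceed physical_min")
        gain = (hdr.digital_max - hdr.digital_min) / (pmax - pmin)
        dig = np.round((np.asarray(sig, dtype=float) - pmin) * gain + hdr.digital_min)
        dig = np.clip(dig, hdr.digital_min, hdr.digital_max).astype("<i2")
        digitized.append(dig.reshape(n_records, hdr.samples_per_record))

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        for rec in range(n_records):
            for dig in digitized:
                fh.write(dig[rec].tobytes())


def _fmt_float(x: float) -> str:
    if x == int(x) and abs(x) < 1e7:
        return str(int(x))
    return f"{x:.6g}"


def _read_field(raw: bytes, offset: int, width: int, name: str, numeric: bool = False):
    text = raw[offset : offset + width].decode("ascii", errors="replace").strip()
    if not numeric:
        return text
    try:
        return float(text)
    except ValueError as exc:
        raise EdfFormatError(f"field {name!r} is not numeric: {text!r}") from exc


def read_edf_header(path: str | Path) -> dict:
    """Parse the fixed and per-signal EDF headers (no sample data)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise EdfFormatError("file shorter than the 256-byte fixed header")
    ns = int(_read_field(raw, 252, 4, "number_of_signals", numeric=True))
    if ns < 1:
        raise EdfFormatError("number_of_signals must be >= 1")
    header_bytes = int(_read_field(raw, 184, 8, "header_bytes", numeric=True))
    if header_bytes != 256 * (1 + ns):
        raise EdfFormatError(
            f"header_bytes {header_bytes} inconsistent with {ns} signals"
        )
    if len(raw) < header_bytes:
        raise EdfFormatError("file shorter than declared header")
    n_records = int(_read_field(raw, 236, 8, "number_of_records", numeric=True))
    record_duration = _read_field(raw, 244, 8, "record_duration", numeric=True)
    if record_duration <= 0:
        raise EdfFormatError("record_duration must be positive")

    def col(base: int, width: int, name: str, numeric: bool = False):
        return [
            _read_field(raw, 256 + base * ns + i * width, width, f"{name}[{i}]", numeric)
            for i in range(ns)
        ]

    headers = []
    labels = col(0, 16, "label")
    transducers = col(16, 80, "transducer")
    units = col(96, 8, "units")
    pmins = col(104, 8, "physical_min", numeric=True)
    pmaxs = col(112, 8, "physical_max", numeric=True)
    dmins = col(120, 8, "digital_min", numeric=True)
    dmaxs = col(128, 8, "digital_max", numeric=True)
    prefilts = col(136, 80, "prefiltering")
    sprs = col(216, 8, "samples_per_record", numeric=True)
    for i in range(ns):
        if sprs[i] < 1:
            raise EdfFormatError(f"samples_per_record[{i}] must be >= 1")
        headers.append(
            EdfSignalHeader(
                label=labels[i],
                units=units[i],
                physical_min=pmins[i],
                physical_max=pmaxs[i],
                digital_min=int(dmins[i]),
                digital_max=int(dmaxs[i]),
                samples_per_record=int(sprs[i]),
                transducer=transducers[i],
                prefiltering=prefilts[i],
            )
        )
    return {
        "n_signals": ns,
        "n_records": n_records,
        "record_duration": record_duration,
        "header_bytes": header_bytes,
        "signal_headers": headers,
    }


def read_edf(path: str | Path) -> tuple[list[np.ndarray], list[EdfSignalHeader], float]:
    """Read an EDF file.

    Returns
    -------
    signals, headers, record_duration
        Physical-unit sample arrays (one per signal, at the signal's native
        rate), the per-signal headers, and the record duration in seconds.
    """
    meta = read_edf_header(path)
    headers: list[EdfSignalHeader] = meta["signal_headers"]
    n_records = meta["n_records"]
    raw = Path(path).read_bytes()
    body = raw[meta["header_bytes"] :]
    spr = np.array([h.samples_per_record for h in headers])
    rec_len = int(spr.sum())
    expected = n_records * rec_len * 2
    if len(body) < expected:
        raise EdfFormatError(
            f"data section truncated: {len(body)} bytes, expected {expected}"
        )
    data = np.frombuffer(body[:expected], dtype="<i2").reshape(n_records, rec_len)
    offsets = np.concatenate([[0], np.cumsum(spr)])
    signals = []
    for i, hdr in enumerate(headers):
        dig = data[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(float)
        gain = (hdr.physical_max - hdr.physical_min) / (hdr.digital_max - hdr.digital_min)
        signals.append(hdr.physical_min + (dig - hdr.digital_min) * gain)
    return signals, headers, meta["record_duration"]
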