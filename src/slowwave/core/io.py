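"""Recording I/O: EDF and CSV time series with a JSON metadata sidecar.

CSV dialect: header row required, comma separated, ``.`` decimal, first
column ``t`` in seconds, one column per channel.  EDF is the interchange
format for multi-hour recordings and preserves per-channel native rates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf as _edf
from .types import Group, Hemisphere, Recording, TimeSeries

__all__ = ["load_recording", "save_recording", "StructuralError"]


class StructuralError(ValueError):
    """Input file parses but violates the expected structure."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _apply_sidecar(path: Path, channels: dict[str, TimeSeries]) -> Recording:
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    hemi = {
        k: Hemisphere(v) for k, v in meta.get("hemisphere_map", {}).items() if k in channels
    }
    return Recording(
        channels=channels,
        animal_id=meta.get("animal_id", path.stem),
        group=Group(meta.get("group", "control")),
        hemisphere_map=hemi,
    )


def load_recording(path: str | Path, format: str | None = None) -> Recording:
    """Load a Recording from EDF or CSV (format inferred from suffix).

    A sidecar ``<file>.json`` with ``animal_id``, ``group`` and
    ``hemisphere_map`` is applied when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        channels = _load_edf_channels(path)
    elif fmt == "csv":
        channels = _load_csv_channels(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _apply_sidecar(path, channels)


def _load_edf_channels(path: Path) -> dict[str, TimeSeries]:
    signals, headers, record_duration = _edf.read_edf(path)
    channels: dict[str, TimeSeries] = {}
    for sig, hdr in zip(signals, headers):
        fs = hdr.samples_per_record / record_duration
        label = hdr.label or f"ch{len(channels)}"
        channels[label] = TimeSeries(sig, fs=fs, label=label, units=hdr.units or "mV")
    return channels


def _load_csv_channels(path: Path) -> dict[str, TimeSeries]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise StructuralError("CSV needs a time column plus at least one channel column")
    tcol = df.columns[0]
    if tcol not in ("t", "time", "time_s"):
        raise StructuralError(f"first CSV column must be a time column, got {tcol!r}")
    t = df[tcol].to_numpy(dtype=float)
    if t.size < 2:
        raise StructuralError("CSV shorter than 2 rows")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt.mean():
        raise StructuralError("time column must be uniformly increasing")
    if df.isna().any().any():
        raise StructuralError("CSV channels have mismatched lengths (NaN padding found)")
    fs = 1.0 / dt.mean()
    channels = {}
    for col in df.columns[1:]:
        channels[col] = TimeSeries(
            df[col].to_numpy(dtype=float), fs=fs, t0=float(t[0]), label=col
        )
    return channels


def save_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a Recording to EDF or CSV plus a JSON metadata sidecar."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        _save_edf(rec, path)
    elif fmt == "csv":
        _save_csv(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    _sidecar_path(path).write_text(json.dumps(rec.metadata(), indent=2))
    return path


def _save_edf(rec: Recording, path: Path) -> None:
    signals, headers = [], []
    for label, ts in rec.channels.items():
        spr = ts.fs
        if abs(spr - round(spr)) > 1e-9:
            raise ValueError("EDF export requires an integer number of samples per second")
        spr = int(round(spr))
        n_records = int(np.ceil(ts.n / spr))
        sig = np.zeros(n_records * spr)
        sig[: ts.n] = ts.samples
        lo, hi = float(sig.min()), float(sig.max())
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        margin = 0.01 * (hi - lo)
        signals.append(sig)
        headers.append(
            _edf.EdfSignalHeader(
                label=label,
                units=ts.units,
                physical_min=lo - margin,
                physical_max=hi + margin,
                digital_min=_edf._DIG_MIN,
                digital_max=_edf._DIG_MAX,
                samples_per_record=spr,
            )
        )
    n_records = {s.size // h.samples_per_record for s, h in zip(signals, headers)}
    if len(n_records) != 1:
        nr = max(n_records)
        for i, (s, h) in enumerate(zip(signals, headers)):
            need = nr * h.samples_per_record
            if s.size < need:
                signals[i] = np.pad(s, (0, need - s.size))
    _edf.write_edf(path, signals, headers, record_duration=1.0, recording_id=rec.animal_id)


def _save_csv(rec: Recording, path: Path) -> None:
    rates = {ts.fs for ts in rec.channels.values()}
    if len(rates) != 1:
        raise ValueError("CSV export requires all channels at the same rate; use EDF")
    first = next(iter(rec.channels.values()))
    data = {"t": first.times}
    for label, ts in rec.channels.items():
        if ts.n != first.n:
            raise ValueError("CSV export requires equal-length channels")
        data[label] = ts.samples
    pd.DataFrame(data).to_csv(path, index=False)
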