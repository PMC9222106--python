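"""Shared domain containers for sampled signals, intervals and events.

Conventions used throughout the package:

* time is continuous seconds from the start of the recording;
* intervals are half-open ``[t_start, t_end)`` so that adjacent intervals
  never double-count a boundary sample;
* event membership in an interval is decided by the event peak time only.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "Recording",
    "IntervalSet",
    "EventTable",
    "PairedTable",
    "Group",
    "Hemisphere",
    "EVENT_COLUMNS",
]


class Group(str, enum.Enum):
    """Experimental cohort of an animal."""

    control = "control"
    mosaic_pup = "mosaic_pup"
    mosaic_P25 = "mosaic_P25"
    mosaic_adult = "mosaic_adult"


class Hemisphere(str, enum.Enum):
    injected = "injected"
    control_hemisphere = "control_hemisphere"
    none = "none"


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples
        Amplitude values (mV for LFP/EEG/EMG, arbitrary units for
        fluorescence).
    fs
        Sampling rate in Hz, strictly positive.
    t0
        Time of the first sample in seconds.
    label
        Channel name.
    units
        Unit string, e.g. ``"mV"`` or ``"a.u."``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""
    units: str = "mV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def copy_with(self, samples: np.ndarray, label: str | None = None) -> "TimeSeries":
        return TimeSeries(
            samples=samples,
            fs=self.fs,
            t0=self.t0,
            label=self.label if label is None else label,
            units=self.units,
        )

    def slice(self, t_lo: float, t_hi: float) -> "TimeSeries":
        """Return the samples within [t_lo, t_hi) as a new TimeSeries."""
        i_lo = max(0, int(np.ceil((t_lo - self.t0) * self.fs)))
        i_hi = min(self.n, int(np.ceil((t_hi - self.t0) * self.fs)))
        if i_hi - i_lo < 2:
            raise ValueError("slice shorter than 2 samples")
        return TimeSeries(
            samples=self.samples[i_lo:i_hi],
            fs=self.fs,
            t0=self.t0 + i_lo / self.fs,
            label=self.label,
            units=self.units,
        )


@dataclass
class Recording:
    """A set of simultaneously recorded channels plus animal metadata."""

    channels: dict[str, TimeSeries]
    animal_id: str = ""
    group: Group = Group.control
    hemisphere_map: dict[str, Hemisphere] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a Recording needs at least one channel")
        t0s = {ts.t0 for ts in self.channels.values()}
        if len(t0s) != 1:
            raise ValueError("all channels must share the same start time")
        for label, ts in self.channels.items():
            self.hemisphere_map.setdefault(label, Hemisphere.none)

    def __getitem__(self, label: str) -> TimeSeries:
        return self.channels[label]

    @property
    def labels(self) -> list[str]:
        return list(self.channels)

    def by_hemisphere(self, hemi: Hemisphere) -> list[TimeSeries]:
        return [
            self.channels[lbl]
            for lbl, h in self.hemisphere_map.items()
            if h == hemi and lbl in self.channels
        ]

    def metadata(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "group": self.group.value,
            "hemisphere_map": {k: v.value for k, v in self.hemisphere_map.items()},
        }

    def write_metadata(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=2))


class IntervalSet:
    """Sorted, pairwise-disjoint half-open intervals ``[t_start, t_end)``.

    Overlapping or touching input intervals are merged on construction so
    the invariants hold for every instance.
    """

    def __init__(self, intervals: Iterable[tuple[float, float]] = (), label: str = "custom"):
        arr = np.asarray(list(intervals), dtype=float).reshape(-1, 2)
        if arr.size and np.any(arr[:, 0] >= arr[:, 1]):
            raise ValueError("every interval needs t_start < t_end")
        self.intervals = _merge_sorted(arr)
        self.label = label

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals.shape == other.intervals.shape and np.allclose(
            self.intervals, other.intervals
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, label={self.label!r})"

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.intervals[:, 1]

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum()) if len(self) else 0.0

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean membership of each time point (half-open intervals)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if not len(self):
            return np.zeros(t.shape, dtype=bool)
        idx = np.searchsorted(self.starts, t, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(t.shape, dtype=bool)
        inside[ok] = t[ok] < self.ends[idx[ok]]
        return inside

    def shift(self, dt: float) -> "IntervalSet":
        return IntervalSet(self.intervals + dt, label=self.label)

    def clip(self, t_lo: float, t_hi: float) -> "IntervalSet":
        """Restrict to the window [t_lo, t_hi)."""
        out = []
        for s, e in self.intervals:
            s2, e2 = max(s, t_lo), min(e, t_hi)
            if s2 < e2:
                out.append((s2, e2))
        return IntervalSet(out, label=self.label)

    def complement(self, t_lo: float, t_hi: float, label: str = "custom") -> "IntervalSet":
        """Gaps within [t_lo, t_hi) not covered by this set."""
        gaps, cursor = [], t_lo
        for s, e in self.clip(t_lo, t_hi).intervals:
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < t_hi:
            gaps.append((cursor, t_hi))
        return IntervalSet(gaps, label=label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_start": self.starts, "t_end": self.ends, "label": self.label}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IntervalSet":
        df = pd.read_csv(path)
        label = str(df["label"].iloc[0]) if len(df) else "custom"
        return cls(zip(df["t_start"], df["t_end"]), label=label)


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    if arr.shape[0] == 0:
        return arr.reshape(0, 2)
    arr = arr[np.argsort(arr[:, 0])]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


EVENT_COLUMNS = ["t_peak", "t_start", "t_end", "amplitude", "duration", "channel", "type"]


class EventTable:
    """Discrete detected events, one row each, sorted by peak time."""

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        missing = set(EVENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"EventTable missing columns: {sorted(missing)}")
        df = df[EVENT_COLUMNS].copy()
        if len(df):
            bad = (df["t_start"] > df["t_peak"]) | (df["t_peak"] > df["t_end"])
            if bad.any():
                raise ValueError("events must satisfy t_start <= t_peak <= t_end")
            df["duration"] = df["t_end"] - df["t_start"]
            df = df.sort_values("t_peak", kind="stable").reset_index(drop=True)
        self.df = df

    @classmethod
    def from_rows(cls, rows: Iterable[Mapping]) -> "EventTable":
        rows = list(rows)
        if not rows:
            return cls()
        return cls(pd.DataFrame(rows))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def t_peak(self) -> np.ndarray:
        return self.df["t_peak"].to_numpy(dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return self.df["amplitude"].to_numpy(dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return self.df["duration"].to_numpy(dtype=float)

    def of_type(self, kind: str) -> "EventTable":
        return EventTable(self.df[self.df["type"] == kind])

    def shift(self, dt: float) -> "EventTable":
        df = self.df.copy()
        for c in ("t_peak", "t_start", "t_end"):
            df[c] = df[c] + dt
        return EventTable(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTable":
        return cls(pd.read_csv(path))


class PairedTable:
    """Per-animal metric values, paired by hemisphere or unpaired by group.

    Paired rows: ``(animal_id, metric, value_injected,
    value_control_hemisphere)``.  Unpaired rows: ``(animal_id, group,
    metric, value)``.
    """

    PAIRED_COLUMNS = ["animal_id", "metric", "value_injected", "value_control_hemisphere"]
    UNPAIRED_COLUMNS = ["animal_id", "group", "metric", "value"]

    def __init__(self, df: pd.DataFrame, paired: bool = True):
        cols = self.PAIRED_COLUMNS if paired else self.UNPAIRED_COLUMNS
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"PairedTable missing columns: {sorted(missing)}")
        df = df[cols].copy()
        value_cols = cols[2:] if paired else ["value"]
        for c in value_cols:
            vals = df[c].to_numpy(dtype=float)
            if len(df) and not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite values in column {c!r}")
        if df.duplicated(subset=["animal_id", "metric"]).any():
            raise ValueError("one row per animal per metric")
        self.df = df.reset_index(drop=True)
        self.paired = paired

    def __len__(self) -> int:
        return len(self.df)

    def metric(self, name: str) -> pd.DataFrame:
        return self.df[self.df["metric"] == name]

    def metrics(self) -> list[str]:
        return sorted(self.df["metric"].unique())

    def differences(self, name: str) -> np.ndarray:
        """injected − control_hemisphere per animal for one metric."""
        if not self.paired:
            raise ValueError("differences need a paired table")
        sub = self.metric(name)
        return (
            sub["value_injected"].to_numpy(dtype=float)
            - sub["value_control_hemisphere"].to_numpy(dtype=float)
        )

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedTable":
        df = pd.read_csv(path)
        return cls(df, paired="value_injected" in df.columns)
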