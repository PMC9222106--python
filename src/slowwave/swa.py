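"""Up/down-state segmentation and slow-wave metrics.

Segmentation uses hysteresis thresholding on the z-scored delta-band
(0.5-4 Hz) signal: an up state opens at the upward crossing of ``theta_hi``
and closes at the downward crossing of ``theta_lo``.  Electrode polarity is
auto-selected by keeping whichever polarity puts more gamma-band (40-100
Hz) power inside the candidate up states, since up states carry the
high-frequency activity.

Transition slopes are computed on the delta-filtered trace: segment 1 runs
from the US onset to the first local extremum inside the US, segment 2 from
the last local extremum to the US offset; both the maximum and the mean of
|d/dt| are reported in mV/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import IntervalSet, PairedTable, Recording, TimeSeries, Hemisphere
from .spectral import DELTA, GAMMA, band_rms, bandpass

__all__ = ["UpDownParams", "StateSegmentation", "SlopeStats", "detect_updown", "us_slopes", "swa_metrics"]


@dataclass
class UpDownParams:
    theta_hi: float = 0.2  # z-units, US opens above this
    theta_lo: float = -0.3  # z-units, US closes below this
    min_us_s: float = 0.15
    min_ds_s: float = 0.1
    merge_gap_s: float = 0.1
    polarity: str = "auto"  # "auto" | "positive_up" | "negative_up"

    def __post_init__(self) -> None:
        if self.theta_hi <= self.theta_lo:
            raise ValueError("theta_hi must exceed theta_lo")
        if self.polarity not in ("auto", "positive_up", "negative_up"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class StateSegmentation:
    us: IntervalSet
    ds: IntervalSet
    polarity: str
    theta_hi: float
    theta_lo: float
    channel: str = ""

    @property
    def n_us(self) -> int:
        return len(self.us)

    def us_rate_per_min(self, duration: float) -> float:
        return 60.0 * len(self.us) / duration

    @property
    def mean_us_duration(self) -> float:
        return float(self.us.durations.mean()) if len(self.us) else float("nan")


@dataclass
class SlopeStats:
    """Per-US transition slopes plus the per-animal summary (mean over USs)."""

    per_us: pd.DataFrame  # us_index, slope1_max, slope1_avg, slope2_max, slope2_avg
    n_flagged: int = 0

    def summary(self) -> dict[str, float]:
        cols = ["slope1_max", "slope1_avg", "slope2_max", "slope2_avg"]
        if not len(self.per_us):
            return {c: float("nan") for c in cols}
        return {c: float(self.per_us[c].mean()) for c in cols}


class FlatSignalError(ValueError):
    """Signal variance too small to segment."""


def _hysteresis_intervals(z: np.ndarray, fs: float, t0: float, hi: float, lo: float):
    """Half-open [onset, offset) runs from hysteresis threshold crossings."""
    above_hi = z > hi
    above_lo = z > lo
    out = []
    in_us = False
    start = 0
    for i in range(z.size):
        if not in_us and above_hi[i]:
            in_us = True
            start = i
        elif in_us and not above_lo[i]:
            out.append((t0 + start / fs, t0 + i / fs))
            in_us = False
    if in_us:
        out.append((t0 + start / fs, t0 + z.size / fs))
    return out


def _enforce_durations(rows, p: UpDownParams, t_lo: float, t_hi: float) -> IntervalSet:
    # merge USs separated by gaps shorter than merge_gap / min_ds
    gap = max(p.merge_gap_s, p.min_ds_s)
    merged = []
    for s, e in rows:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if e - s >= p.min_us_s]
    return IntervalSet(kept, label="US").clip(t_lo, t_hi)


def detect_updown(ts: TimeSeries, params: UpDownParams | None = None) -> StateSegmentation:
    """Segment an LFP record into up and down states.

    Deterministic; raises :class:`FlatSignalError` on a near-constant
    signal.  Requires at least 60 s of data.
    """
    p = params or UpDownParams()
    if ts.duration < 60.0:
        raise ValueError("detect_updown needs at least 60 s of LFP")
    delta = bandpass(ts, DELTA)
    sd = float(delta.samples.std())
    if sd < 1e-12:
        raise FlatSignalError("delta-band signal is flat; no states detectable")
    z = (delta.samples - delta.samples.mean()) / sd

    candidates = {}
    polarities = (
        ("positive_up", "negative_up") if p.polarity == "auto" else (p.polarity,)
    )
    for pol in polarities:
        zz = z if pol == "positive_up" else -z
        rows = _hysteresis_intervals(zz, ts.fs, ts.t0, p.theta_hi, p.theta_lo)
        candidates[pol] = _enforce_durations(rows, p, ts.t0, ts.t0 + ts.duration)

    if p.polarity == "auto":
        chosen = _select_polarity_by_gamma(ts, candidates)
    else:
        chosen = p.polarity
    us = candidates[chosen]
    ds = us.complement(ts.t0, ts.t0 + ts.duration, label="DS")
    return StateSegmentation(
        us=us, ds=ds, polarity=chosen, theta_hi=p.theta_hi, theta_lo=p.theta_lo,
        channel=ts.label,
    )


def _select_polarity_by_gamma(ts: TimeSeries, candidates: dict[str, IntervalSet]) -> str:
    try:
        gamma = bandpass(ts, GAMMA)
    except ValueError:  # Nyquist too low for the gamma band: fall back
        return "positive_up"
    power = gamma.samples**2
    times = ts.times
    scores = {}
    for pol, us in candidates.items():
        if len(us) == 0:
            scores[pol] = -np.inf
            continue
        mask = us.contains(times)
        scores[pol] = float(power[mask].mean()) if mask.any() else -np.inf
    return max(scores, key=scores.get)


def us_slopes(ts: TimeSeries, seg: StateSegmentation) -> SlopeStats:
    """Per-up-state transition slopes on the delta-filtered trace."""
    delta = bandpass(ts, DELTA)
    x = delta.samples if seg.polarity == "positive_up" else -delta.samples
    fs = ts.fs
    deriv = np.gradient(x) * fs  # mV/s
    rows = []
    flagged = 0
    for k, (s, e) in enumerate(seg.us):
        i_lo = max(0, int(np.ceil((s - ts.t0) * fs)))
        i_hi = min(ts.n, int(np.floor((e - ts.t0) * fs)))
        if i_hi - i_lo < 5:
            flagged += 1
            continue
        win = x[i_lo:i_hi]
        interior = _local_extrema(win)
        if interior.size == 0:
            flagged += 1
            continue
        first, last = interior[0], interior[-1]
        d1 = np.abs(deriv[i_lo : i_lo + first + 1])
        d2 = np.abs(deriv[i_lo + last : i_hi])
        if d1.size == 0 or d2.size == 0:
            flagged += 1
            continue
        rows.append(
            {
                "us_index": k,
                "slope1_max": float(d1.max()),
                "slope1_avg": float(d1.mean()),
                "slope2_max": float(d2.max()),
                "slope2_avg": float(d2.mean()),
            }
        )
    df = pd.DataFrame(rows, columns=["us_index", "slope1_max", "slope1_avg", "slope2_max", "slope2_avg"])
    return SlopeStats(per_us=df, n_flagged=flagged)


def _local_extrema(x: np.ndarray) -> np.ndarray:
    """Indices of interior local extrema of a 1-D array."""
    if x.size < 3:
        return np.zeros(0, dtype=int)
    d = np.diff(x)
    sign = np.sign(d)
    # treat flats as continuation of the previous trend
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turns = np.flatnonzero(sign[1:] * sign[:-1] < 0) + 1
    return turns


METRIC_NAMES = [
    "delta_rms",
    "slope1_max",
    "slope1_avg",
    "slope2_max",
    "slope2_avg",
    "us_rate_per_min",
    "mean_us_duration",
]


def swa_metrics(
    rec: Recording,
    segs: dict[str, StateSegmentation],
    injected_label: str | None = None,
    control_label: str | None = None,
) -> PairedTable:
    """Per-animal paired (injected vs control hemisphere) slow-wave metrics."""
    if injected_label is None or control_label is None:
        inv = {h: lbl for lbl, h in rec.hemisphere_map.items()}
        injected_label = injected_label or inv.get(Hemisphere.injected)
        control_label = control_label or inv.get(Hemisphere.control_hemisphere)
    if injected_label is None or control_label is None:
        raise ValueError("could not identify injected and control hemisphere channels")

    values = {}
    for side, label in (("inj", injected_label), ("ctl", control_label)):
        ts = rec[label]
        seg = segs[label]
        slopes = us_slopes(ts, seg).summary()
        values[side] = {
            "delta_rms": band_rms(ts, DELTA),
            **slopes,
            "us_rate_per_min": seg.us_rate_per_min(ts.duration),
            "mean_us_duration": seg.mean_us_duration,
        }
    rows = [
        {
            "animal_id": rec.animal_id,
            "metric": m,
            "value_injected": values["inj"][m],
            "value_control_hemisphere": values["ctl"][m],
        }
        for m in METRIC_NAMES
    ]
    return PairedTable(pd.DataFrame(rows), paired=True)
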