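"""Multi-unit activity extraction from the high-frequency band of the LFP.

Spikes are threshold crossings of the >300 Hz high-passed trace below
``-k * sigma_n``, where ``sigma_n = median(|x|) / 0.6745`` is the robust
noise scale; spike times sit at the local trough and a dead time suppresses
re-triggers.  No sorting is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import IntervalSet, TimeSeries
from .spectral import highpass
from .swa import StateSegmentation

__all__ = ["UnitParams", "SpikeTrain", "extract_units", "unit_rate", "units_in_us"]


@dataclass
class UnitParams:
    highpass_hz: float = 300.0
    k: float = 4.0
    # 4 ms: long enough to absorb the filter ringing around each trough,
    # short enough for multi-unit counting
    dead_time_s: float = 0.004
    bipolar: bool = False  # detect positive-going crossings too
    exclude: IntervalSet | None = None  # e.g. burst epochs


@dataclass
class SpikeTrain:
    times: np.ndarray  # strictly increasing, seconds
    threshold_mv: float
    noise_scale_mv: float
    channel: str = ""
    flat_input: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size


def extract_units(ts: TimeSeries, params: UnitParams | None = None) -> SpikeTrain:
    """Extract multi-unit spike times with an automatic robust threshold."""
    p = params or UnitParams()
    if ts.fs < 1000.0:
        raise ValueError(
            f"unit extraction needs fs >= 1 kHz (got {ts.fs} Hz) for a "
            f"{p.highpass_hz} Hz high-pass"
        )
    hp = highpass(ts, p.highpass_hz)
    x = hp.samples
    sigma = float(np.median(np.abs(x)) / 0.6745)
    if sigma < 1e-12:
        return SpikeTrain(
            times=np.zeros(0), threshold_mv=0.0, noise_scale_mv=0.0,
            channel=ts.label, flat_input=True,
        )
    thr = p.k * sigma
    detect = np.abs(x) if p.bipolar else -x
    dead = max(1, int(round(p.dead_time_s * ts.fs)))
    # distance-constrained peak picking keeps the deepest trough of each
    # cluster (crossing + ringing side lobes count as one unit)
    from scipy.signal import find_peaks

    idx, _ = find_peaks(detect, height=thr, distance=dead)
    t_arr = ts.t0 + idx / ts.fs
    if p.exclude is not None and t_arr.size:
        t_arr = t_arr[~p.exclude.contains(t_arr)]
    return SpikeTrain(
        times=t_arr, threshold_mv=-thr if not p.bipolar else thr,
        noise_scale_mv=sigma, channel=ts.label,
    )


def unit_rate(st: SpikeTrain, duration_s: float) -> float:
    """Overall firing rate in Hz."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return st.n / duration_s


def units_in_us(st: SpikeTrain, seg: StateSegmentation | IntervalSet) -> dict:
    """Percentage of spikes inside up states, plus the chance level.

    Chance is the up-state duty cycle (in percent) over the span of the
    segmentation.  An empty train yields ``defined=False``.
    """
    us = seg.us if isinstance(seg, StateSegmentation) else seg
    if len(us) == 0:
        raise ValueError("empty up-state set")
    span_lo = us.starts[0]
    span_hi = us.ends[-1]
    if isinstance(seg, StateSegmentation) and len(seg.ds):
        span_lo = min(span_lo, seg.ds.starts[0])
        span_hi = max(span_hi, seg.ds.ends[-1])
    chance = 100.0 * us.clip(span_lo, span_hi).total_duration / (span_hi - span_lo)
    if st.n == 0:
        return {"percentage": None, "chance": chance, "n_spikes": 0, "defined": False}
    frac = float(us.contains(st.times).mean())
    return {
        "percentage": 100.0 * frac,
        "chance": chance,
        "n_spikes": int(st.n),
        "defined": True,
    }
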