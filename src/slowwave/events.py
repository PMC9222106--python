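"""Epileptiform-event detection: beta bursts and hypersynchronous spikes.

Burst detection thresholds the smoothed Hilbert envelope of the 9-25 Hz
band-passed signal at median + 3 MAD-scaled deviations; supra-threshold
runs at least ``min_duration`` long (after closing sub-``merge_gap`` gaps)
become events.  Spike detection runs on a 1-40 Hz band-passed trace and
keeps candidates whose absolute amplitude clears both an absolute (mV) and
a robust-z threshold, with boundaries placed at a configurable fraction of
the peak and hard duration bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import EventTable, IntervalSet, duty_cycle, events_in_intervals, group_test
from .spectral import BETA, BandDefinition, bandpass

__all__ = [
    "BurstParams",
    "SpikeEventParams",
    "PhenotypeCall",
    "PhaseLocking",
    "detect_beta_bursts",
    "detect_hypersync_spikes",
    "event_rate",
    "phase_locking",
    "phase_locking_cohort",
    "classify_phenotype",
]

_MAD_TO_SD = 1.4826


@dataclass
class BurstParams:
    """Beta-burst detection.

    The band envelope is divided by its own running median
    (``normalize_window_s``) before thresholding, so the threshold adapts
    to state-dependent background power (chronic EEG alternates Wake/NREM
    background); set it to ``None`` for a global threshold.
    """

    band: BandDefinition = BETA
    envelope_smooth_s: float = 0.1
    threshold_z: float = 6.0
    min_duration_s: float = 0.5
    merge_gap_s: float = 0.2
    normalize_window_s: float | None = 30.0


@dataclass
class SpikeEventParams:
    """Hypersynchronous-spike detection.

    Candidates come from the ``band`` (default 5-40 Hz, above the slow-wave
    band so down-state events are not masked); amplitude and the
    25%-of-peak boundaries are measured on the nearly unfiltered
    ``measure_band`` trace, which preserves the morphology of brief
    unipolar discharges.
    """

    band: BandDefinition = BandDefinition("spike_detect", 5.0, 40.0)
    measure_band: BandDefinition = BandDefinition("spike_measure", 0.1, 40.0)
    threshold_mv: float = 0.1
    threshold_z: float = 6.0
    min_duration_s: float = 0.05
    max_duration_s: float = 0.5
    dead_time_s: float = 0.5
    boundary_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not self.min_duration_s < self.max_duration_s:
            raise ValueError("duration bounds must be ordered")
        if not 0 < self.boundary_fraction < 1:
            raise ValueError("boundary_fraction must be in (0, 1)")


@dataclass
class PhenotypeCall:
    beta_rate_per_hour: float
    hypersync_rate_per_hour: float
    frequent_bursts: bool  # strictly more than 3 beta bursts per hour
    hyperexcitable: bool  # strictly more than 5 beta bursts per hour

    def to_dict(self) -> dict:
        return {
            "beta_rate_per_hour": float(self.beta_rate_per_hour),
            "hypersync_rate_per_hour": float(self.hypersync_rate_per_hour),
            "frequent_bursts": bool(self.frequent_bursts),
            "hyperexcitable": bool(self.hyperexcitable),
        }


def _running_median(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Running median on a coarse grid, linearly interpolated in between."""
    n = x.size
    w = int(round(window_s * fs))
    half = w // 2
    step = max(1, w // 30)
    centers = np.arange(0, n, step)
    grid = np.array([np.median(x[max(0, c - half) : min(n, c + half)]) for c in centers])
    return np.interp(np.arange(n), centers, grid)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        stops = np.concatenate([stops, [mask.size]])
    return list(zip(starts, stops))


def detect_beta_bursts(ts, p: BurstParams | None = None) -> EventTable:
    """Detect sustained beta-band oscillation packets."""
    p = p or BurstParams()
    if ts.duration < 60.0:
        raise ValueError("detect_beta_bursts needs at least 60 s of signal")
    band = bandpass(ts, p.band)
    env = np.abs(sps.hilbert(band.samples))
    w = max(1, int(round(p.envelope_smooth_s * ts.fs)))
    env = np.convolve(env, np.ones(w) / w, mode="same")
    if p.normalize_window_s is not None and ts.duration > 2 * p.normalize_window_s:
        score = env / np.maximum(_running_median(env, ts.fs, p.normalize_window_s), 1e-15)
    else:
        score = env
    med = np.median(score)
    mad = np.median(np.abs(score - med)) * _MAD_TO_SD
    thr = med + p.threshold_z * max(mad, 1e-15)
    mask = score > thr

    runs = _runs(mask)
    # close gaps shorter than merge_gap
    merged: list[list[int]] = []
    gap = int(round(p.merge_gap_s * ts.fs))
    for a, b in runs:
        if merged and a - merged[-1][1] <= gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    min_len = int(round(p.min_duration_s * ts.fs))
    rows = []
    for a, b in merged:
        if b - a < min_len:
            continue
        seg = env[a:b]
        pk = a + int(np.argmax(seg))
        rows.append(
            {
                "t_peak": ts.t0 + pk / ts.fs,
                "t_start": ts.t0 + a / ts.fs,
                "t_end": ts.t0 + b / ts.fs,
                "amplitude": float(env[pk]),
                "duration": (b - a) / ts.fs,
                "channel": ts.label,
                "type": "beta_burst",
            }
        )
    return EventTable.from_rows(rows)


def detect_hypersync_spikes(ts, p: SpikeEventParams | None = None) -> EventTable:
    """Detect brief large-amplitude discharges (interictal-spike-like)."""
    p = p or SpikeEventParams()
    if ts.duration < 60.0:
        raise ValueError("detect_hypersync_spikes needs at least 60 s of signal")
    x = bandpass(ts, p.band).samples
    m = bandpass(ts, p.measure_band).samples
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * _MAD_TO_SD
    thr = max(p.threshold_mv, p.threshold_z * max(mad, 1e-15))
    absx = np.abs(x)
    mask = absx > thr

    rows = []
    fs = ts.fs
    dead = int(round(p.dead_time_s * fs))
    pad = int(round(0.1 * fs))  # search margin around the candidate run
    absm = np.abs(m)
    last_end = -10 * dead
    for a, b in _runs(mask):
        if a < last_end + dead:
            continue
        w_lo, w_hi = max(0, a - pad), min(x.size, b + pad)
        pk = w_lo + int(np.argmax(absm[w_lo:w_hi]))
        peak_val = float(m[pk])
        level = p.boundary_fraction * abs(peak_val)
        lo = pk
        while lo > 0 and absm[lo - 1] >= level:
            lo -= 1
        hi = pk
        while hi < m.size - 1 and absm[hi + 1] >= level:
            hi += 1
        duration = (hi - lo + 1) / fs
        if not (p.min_duration_s <= duration <= p.max_duration_s):
            continue
        rows.append(
            {
                "t_peak": ts.t0 + pk / fs,
                "t_start": ts.t0 + lo / fs,
                "t_end": ts.t0 + (hi + 1) / fs,
                "amplitude": peak_val,
                "duration": duration,
                "channel": ts.label,
                "type": "hypersync_spike",
            }
        )
        last_end = hi
    return EventTable.from_rows(rows)


def event_rate(ev: EventTable, duration_s: float) -> float:
    """Events per hour."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(ev) * 3600.0 / duration_s


@dataclass
class PhaseLocking:
    fraction: float | None
    chance: float
    n_events: int
    defined: bool

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "chance": self.chance,
            "n_events": self.n_events,
            "defined": self.defined,
        }


def phase_locking(
    ev: EventTable,
    contralateral_us: IntervalSet,
    window: tuple[float, float],
    min_events: int = 5,
) -> PhaseLocking:
    """Fraction of event peaks inside the contralateral up states.

    Chance level is the up-state duty cycle over the analysis window.  With
    fewer than ``min_events`` events the fraction is flagged undefined.
    """
    chance = duty_cycle(contralateral_us, *window)
    if len(ev) < min_events:
        return PhaseLocking(fraction=None, chance=chance, n_events=len(ev), defined=False)
    mem = events_in_intervals(ev, contralateral_us)
    return PhaseLocking(
        fraction=mem.fraction, chance=chance, n_events=len(ev), defined=True
    )


def phase_locking_cohort(per_animal: list[PhaseLocking]):
    """One-sample t of per-animal in-US fractions against their mean chance."""
    usable = [p for p in per_animal if p.defined]
    if len(usable) < 3:
        raise ValueError("need at least 3 animals with defined fractions")
    fractions = np.array([p.fraction for p in usable])
    chance = float(np.mean([p.chance for p in usable]))
    res = group_test(fractions, method="one_sample_t", mu0=chance)
    return {
        "mean_fraction": float(fractions.mean()),
        "chance": chance,
        "n_animals": len(usable),
        "t_statistic": res.statistic,
        "p_value": res.p_value,
    }


def classify_phenotype(beta_rate_per_hour: float, hypersync_rate_per_hour: float) -> PhenotypeCall:
    """Threshold calls: frequent bursts at > 3/h, hyperexcitable at > 5/h."""
    if beta_rate_per_hour < 0 or hypersync_rate_per_hour < 0:
        raise ValueError("rates must be >= 0")
    return PhenotypeCall(
        beta_rate_per_hour=beta_rate_per_hour,
        hypersync_rate_per_hour=hypersync_rate_per_hour,
        frequent_bursts=beta_rate_per_hour > 3.0,
        hyperexcitable=beta_rate_per_hour > 5.0,
    )
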