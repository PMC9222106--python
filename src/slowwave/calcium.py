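"""Calcium-trace analysis: dF/F, transient scoring and population statistics.

A transient opens when dF/F exceeds ``k * sigma`` (robust sigma) for at
least the sustain window and closes when the trace decays below
``1 * sigma``; the detector is refractory until the close, so closely
spaced kernels merge into one event.  "Active" means at least one detected
transient; the hyperactive criterion is strictly more than 4 transients per
minute.  Frequency statistics are computed over active neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import IntervalSet, TimeSeries, group_test
from .swa import StateSegmentation

__all__ = [
    "NeuronTrace",
    "TransientParams",
    "TransientTable",
    "FOVActivity",
    "compute_dff",
    "detect_transients",
    "score_population",
    "population_stats",
    "fov_activity",
    "transients_in_us",
    "HYPERACTIVE_PER_MIN",
]

HYPERACTIVE_PER_MIN = 4.0
_MAD_TO_SD = 1.4826


@dataclass
class NeuronTrace:
    """Raw fluorescence of one ROI."""

    roi_id: int
    F: np.ndarray
    fs: float
    genotype_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if np.any(self.F <= 0):
            raise ValueError("raw fluorescence must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.F.size / self.fs


@dataclass
class TransientParams:
    k: float = 3.0
    sustain_s: float = 0.3
    end_sigma: float = 1.0
    baseline_window_s: float = 30.0
    baseline_percentile: float = 20.0


class TransientTable:
    """Per-neuron transient scores: times, frequency, activity flags."""

    COLUMNS = ["roi_id", "genotype_tag", "n_events", "frequency_hz", "per_min", "active", "hyperactive"]

    def __init__(self, rows: list[dict], event_times: dict[int, np.ndarray], duration_s: float):
        self.df = pd.DataFrame(rows, columns=self.COLUMNS)
        self.event_times = event_times
        self.duration_s = duration_s

    def __len__(self) -> int:
        return len(self.df)

    @property
    def active(self) -> pd.DataFrame:
        return self.df[self.df["active"]]

    def all_event_times(self) -> np.ndarray:
        if not self.event_times:
            return np.zeros(0)
        parts = [v for v in self.event_times.values() if v.size]
        return np.sort(np.concatenate(parts)) if parts else np.zeros(0)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def compute_dff(
    tr: NeuronTrace,
    baseline_window_s: float = 30.0,
    percentile: float = 20.0,
) -> TimeSeries:
    """dF/F with a running-percentile baseline.

    F0 is the given percentile of F in a centered running window (floored
    at a small positive constant); dF/F = (F - F0) / F0.
    """
    n = tr.F.size
    w = int(round(baseline_window_s * tr.fs))
    if n < 2 * w:
        raise ValueError(
            f"trace of {tr.duration:.0f} s shorter than 2x the baseline window"
        )
    half = w // 2
    # percentile over strided windows at a coarse grid, then interpolated;
    # exact at the grid points, cheap in between
    step = max(1, w // 10)
    centers = np.arange(0, n, step)
    f0_grid = np.empty(centers.size)
    for i, c in enumerate(centers):
        lo, hi = max(0, c - half), min(n, c + half)
        f0_grid[i] = np.percentile(tr.F[lo:hi], percentile)
    f0 = np.interp(np.arange(n), centers, f0_grid)
    f0 = np.maximum(f0, 1e-9)
    if np.any(f0 <= 0):
        raise ValueError("nonpositive baseline after flooring")
    dff = (tr.F - f0) / f0
    return TimeSeries(dff, fs=tr.fs, label=f"roi{tr.roi_id}", units="dF/F")


def detect_transients(dff: TimeSeries, params: TransientParams | None = None) -> tuple[np.ndarray, dict]:
    """Detect transient onsets in a dF/F trace.

    Returns (onset times, summary dict with n_events / frequency_hz /
    per_min).  Deterministic.
    """
    p = params or TransientParams()
    if dff.duration < 60.0:
        raise ValueError("need at least 60 s to estimate the noise scale")
    x = dff.samples
    med = np.median(x)
    sigma = float(np.median(np.abs(x - med)) * _MAD_TO_SD)
    sigma = max(sigma, 1e-12)
    hi = med + p.k * sigma
    lo = med + p.end_sigma * sigma
    sustain = max(1, int(round(p.sustain_s * dff.fs)))

    onsets = []
    i = 0
    n = x.size
    while i < n:
        if x[i] > hi:
            j = i
            while j + 1 < n and x[j + 1] > hi:
                j += 1
            if j - i + 1 >= sustain:
                # refine the onset back to the start of the rise (first
                # sample above the end threshold) to cancel crossing latency
                o = i
                while o > 0 and x[o - 1] > lo:
                    o -= 1
                # the rise began between samples o-1 and o
                onsets.append(dff.t0 + max(o - 1, 0) / dff.fs)
                # refractory until decay below the end threshold or 25% of
                # the event peak, whichever is crossed first; a re-rise of
                # k*sigma above the local minimum splits off a new event
                peak = x[i : j + 1].max()
                local_min = peak
                k = j
                while k + 1 < n and x[k + 1] > max(lo, med + 0.25 * (peak - med)):
                    k += 1
                    local_min = min(local_min, x[k])
                    if x[k] - local_min > p.k * sigma and x[k] > hi:
                        onsets.append(dff.t0 + k / dff.fs)
                        peak = x[k]
                        local_min = x[k]
                i = k + 1
            else:
                i = j + 1
        else:
            i += 1
    times = np.asarray(onsets)
    freq = times.size / dff.duration
    return times, {
        "n_events": int(times.size),
        "frequency_hz": float(freq),
        "per_min": float(freq * 60.0),
    }


def score_population(
    traces,  # synth.NeuronTraceSet or list[NeuronTrace]
    params: TransientParams | None = None,
) -> TransientTable:
    """Run dF/F + transient detection over a population of traces."""
    p = params or TransientParams()
    if hasattr(traces, "F"):  # NeuronTraceSet
        neurons = [
            NeuronTrace(roi_id=rid, F=traces.F[i], fs=traces.fs, genotype_tag=tag)
            for i, (rid, tag) in enumerate(zip(traces.roi_ids, traces.genotype_tags))
        ]
    else:
        neurons = list(traces)
    rows, ev = [], {}
    duration = neurons[0].duration if neurons else 0.0
    for tr in neurons:
        dff = compute_dff(tr, p.baseline_window_s, p.baseline_percentile)
        times, summ = detect_transients(dff, p)
        ev[tr.roi_id] = times
        per_min = summ["per_min"]
        rows.append(
            {
                "roi_id": tr.roi_id,
                "genotype_tag": tr.genotype_tag,
                "n_events": summ["n_events"],
                "frequency_hz": summ["frequency_hz"],
                "per_min": per_min,
                "active": summ["n_events"] >= 1,
                "hyperactive": per_min > HYPERACTIVE_PER_MIN,
            }
        )
    return TransientTable(rows, ev, duration)


def population_stats(table: TransientTable, other: TransientTable | None = None) -> dict:
    """Frequency statistics over active neurons, optionally vs a comparison.

    Requires at least 20 active neurons per condition.  ``hyperactive_pct``
    uses the strict > 4/min criterion over *all* scored neurons; dispersion
    is compared with Bartlett's test on active-neuron frequencies.
    """
    def one(t: TransientTable) -> dict:
        act = t.active
        if len(act) < 20:
            raise ValueError(f"need >= 20 active neurons, got {len(act)}")
        freqs = act["frequency_hz"].to_numpy()
        return {
            "n_neurons": int(len(t.df)),
            "n_active": int(len(act)),
            "median_frequency_hz": float(np.median(freqs)),
            "variance_hz2": float(np.var(freqs, ddof=1)),
            "hyperactive_pct": 100.0 * float(t.df["hyperactive"].mean()),
        }

    out = {"primary": one(table)}
    if other is not None:
        out["comparison"] = one(other)
        a = table.active["frequency_hz"].to_numpy()
        b = other.active["frequency_hz"].to_numpy()
        res = group_test(a, method="bartlett", values_b=b)
        out["dispersion_test"] = res.to_dict()
        mw = group_test(a, method="mann_whitney", values_b=b)
        out["frequency_test"] = mw.to_dict()
    return out


@dataclass
class FOVActivity:
    """Per-frame count of supra-threshold ROIs (or pixels)."""

    counts: np.ndarray
    fs: float
    total: int

    def __post_init__(self) -> None:
        if np.any(self.counts < 0) or np.any(self.counts > self.total):
            raise ValueError("counts must lie in [0, total]")


def fov_activity(
    stack: np.ndarray | None = None,
    traces=None,
    k: float = 3.0,
    smooth_s: float = 0.3,
    fs: float | None = None,
) -> FOVActivity:
    """Field-of-view activity: per-frame supra-threshold element count.

    Pass either a (t, y, x) image stack or a population of traces (the
    fallback counts supra-threshold ROI dF/F values per frame).
    """
    if stack is not None:
        if stack.ndim != 3 or stack.size == 0:
            raise ValueError("stack must be a nonempty (t, y, x) array")
        if fs is None:
            raise ValueError("fs required with a stack")
        flat = stack.reshape(stack.shape[0], -1).astype(float)
        base = np.median(flat, axis=0)
        mad = np.median(np.abs(flat - base), axis=0) * _MAD_TO_SD
        thr = base + k * np.maximum(mad, 1e-12)
        counts = (flat > thr).sum(axis=1).astype(float)
        total = flat.shape[1]
    elif traces is not None:
        tt = score_dff_matrix(traces)
        dff, fs = tt
        med = np.median(dff, axis=1, keepdims=True)
        mad = np.median(np.abs(dff - med), axis=1, keepdims=True) * _MAD_TO_SD
        counts = (dff > med + k * np.maximum(mad, 1e-12)).sum(axis=0).astype(float)
        total = dff.shape[0]
    else:
        raise ValueError("provide a stack or traces")
    w = max(1, int(round(smooth_s * fs)))
    counts = np.convolve(counts, np.ones(w) / w, mode="same")
    return FOVActivity(counts=counts, fs=fs, total=total)


def score_dff_matrix(traces) -> tuple[np.ndarray, float]:
    """dF/F matrix (n_neurons, n_frames) for a NeuronTraceSet or trace list."""
    if hasattr(traces, "F"):
        neurons = [
            NeuronTrace(roi_id=rid, F=traces.F[i], fs=traces.fs)
            for i, rid in enumerate(traces.roi_ids)
        ]
    else:
        neurons = list(traces)
    if not neurons:
        raise ValueError("need at least one trace")
    dff = np.vstack([compute_dff(tr).samples for tr in neurons])
    return dff, neurons[0].fs


def transients_in_us(
    table: TransientTable,
    seg: StateSegmentation | IntervalSet,
    offset_s: float = 0.0,
) -> dict:
    """Percent of pooled transient onsets inside up states (per field).

    ``offset_s`` aligns the imaging clock to the LFP clock.  Also reports
    the per-neuron mean percentage alongside the pooled value.
    """
    us = seg.us if isinstance(seg, StateSegmentation) else seg
    if len(us) == 0:
        raise ValueError("empty up-state set")
    span = (us.starts[0], us.ends[-1])
    chance = 100.0 * us.total_duration / (span[1] - span[0])
    pooled = table.all_event_times() + offset_s
    if pooled.size == 0:
        return {"percentage": None, "chance": chance, "n_transients": 0, "defined": False}
    pct = 100.0 * float(us.contains(pooled).mean())
    per_neuron = [
        100.0 * float(us.contains(v + offset_s).mean())
        for v in table.event_times.values()
        if v.size
    ]
    return {
        "percentage": pct,
        "per_neuron_mean": float(np.mean(per_neuron)),
        "chance": chance,
        "n_transients": int(pooled.size),
        "defined": True,
    }
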