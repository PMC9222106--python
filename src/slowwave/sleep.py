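"""Threshold-based Wake/NREM/REM scoring of chronic EEG + EMG.

Per epoch (default 4 s): Wake if the EMG RMS exceeds an automatic
threshold; otherwise NREM if the delta (0.5-4 Hz) share of 0.5-30 Hz EEG
power exceeds ``theta_delta``; otherwise REM if the theta(6-9)/delta power
ratio exceeds ``theta_theta``; otherwise NREM.  Labels are then majority
smoothed over 3 epochs.  The EMG threshold separates the low/high-variance
epoch clusters via Otsu's criterion on log RMS (a fixed percentile is
available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import EventTable, IntervalSet, TimeSeries, group_test

__all__ = ["SleepParams", "Hypnogram", "score_sleep", "burst_state_coupling", "nrem_coupling_cohort"]

STAGES = ("Wake", "NREM", "REM")


@dataclass
class SleepParams:
    epoch_s: float = 4.0
    theta_delta: float = 0.45  # delta / total(0.5-30) ratio for NREM
    theta_theta: float = 1.0  # theta(6-9) / delta ratio for REM
    emg_threshold: str = "otsu"  # "otsu" or "percentile"
    emg_percentile: float = 60.0
    smooth_epochs: int = 3


@dataclass
class Hypnogram:
    epoch_s: float
    labels: np.ndarray  # per-epoch stage strings
    features: pd.DataFrame  # delta_ratio, theta_delta_ratio, emg_rms
    t0: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {bad}")

    @property
    def n_epochs(self) -> int:
        return self.labels.size

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_s

    def intervals(self, stage: str) -> IntervalSet:
        rows = [
            (self.t0 + i * self.epoch_s, self.t0 + (i + 1) * self.epoch_s)
            for i in range(self.n_epochs)
            if self.labels[i] == stage
        ]
        return IntervalSet(rows, label=stage)

    def occupancy(self) -> dict[str, float]:
        return {s: float(np.mean(self.labels == s)) for s in STAGES}

    def stage_at(self, times: np.ndarray) -> np.ndarray:
        idx = np.floor((np.asarray(times) - self.t0) / self.epoch_s).astype(int)
        idx = np.clip(idx, 0, self.n_epochs - 1)
        return self.labels[idx]

    def to_frame(self) -> pd.DataFrame:
        df = self.features.copy()
        df.insert(0, "t_start", self.t0 + np.arange(self.n_epochs) * self.epoch_s)
        df.insert(1, "stage", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _band_power(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> float:
    nperseg = min(x.size, int(4 * fs))
    freqs, p = sps.welch(x, fs=fs, nperseg=nperseg)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(p[sel], freqs[sel]))


def _otsu_threshold(values: np.ndarray) -> float:
    """Two-class variance-maximizing split of a 1-D sample."""
    v = np.sort(values)
    best, best_t = -np.inf, v[v.size // 2]
    for i in range(1, v.size):
        n1, n2 = i, v.size - i
        m1, m2 = v[:i].mean(), v[i:].mean()
        score = n1 * n2 * (m1 - m2) ** 2
        if score > best:
            best, best_t = score, 0.5 * (v[i - 1] + v[i])
    return float(best_t)


def score_sleep(
    eeg: TimeSeries, emg: TimeSeries, epoch_s: float | None = None,
    params: SleepParams | None = None,
) -> Hypnogram:
    """Score a simultaneous EEG + EMG record into Wake/NREM/REM epochs."""
    p = params or SleepParams()
    if epoch_s is not None:
        p = SleepParams(**{**p.__dict__, "epoch_s": epoch_s})
    if abs(eeg.duration - emg.duration) > p.epoch_s:
        raise ValueError(
            f"EEG ({eeg.duration:.0f} s) and EMG ({emg.duration:.0f} s) differ in duration"
        )
    if eeg.duration < 600.0:
        raise ValueError("sleep scoring needs at least 10 min of data")

    n_ep = int(eeg.duration // p.epoch_s)
    eeg_len = int(p.epoch_s * eeg.fs)
    emg_len = int(p.epoch_s * emg.fs)
    delta_ratio = np.empty(n_ep)
    theta_delta = np.empty(n_ep)
    emg_rms = np.empty(n_ep)
    for i in range(n_ep):
        xe = eeg.samples[i * eeg_len : (i + 1) * eeg_len]
        xm = emg.samples[i * emg_len : (i + 1) * emg_len]
        delta = _band_power(xe, eeg.fs, 0.5, 4.0)
        theta = _band_power(xe, eeg.fs, 6.0, 9.0)
        total = _band_power(xe, eeg.fs, 0.5, 30.0)
        delta_ratio[i] = delta / total if total > 0 else 0.0
        theta_delta[i] = theta / delta if delta > 0 else np.inf
        emg_rms[i] = np.sqrt(np.mean(xm**2))

    log_rms = np.log(np.maximum(emg_rms, 1e-15))
    if p.emg_threshold == "otsu":
        thr = _otsu_threshold(log_rms)
    elif p.emg_threshold == "percentile":
        thr = float(np.percentile(log_rms, p.emg_percentile))
    else:
        raise ValueError(f"unknown emg_threshold {p.emg_threshold!r}")

    labels = np.empty(n_ep, dtype=object)
    for i in range(n_ep):
        if log_rms[i] > thr:
            labels[i] = "Wake"
        elif delta_ratio[i] > p.theta_delta:
            labels[i] = "NREM"
        elif theta_delta[i] > p.theta_theta:
            labels[i] = "REM"
        else:
            labels[i] = "NREM"

    labels = _majority_smooth(labels, p.smooth_epochs)
    features = pd.DataFrame(
        {"delta_ratio": delta_ratio, "theta_delta_ratio": theta_delta, "emg_rms": emg_rms}
    )
    return Hypnogram(epoch_s=p.epoch_s, labels=labels, features=features, t0=eeg.t0)


def _majority_smooth(labels: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return labels
    half = window // 2
    out = labels.copy()
    for i in range(labels.size):
        lo, hi = max(0, i - half), min(labels.size, i + half + 1)
        vals, counts = np.unique(labels[lo:hi], return_counts=True)
        top = counts.max()
        winners = set(vals[counts == top])
        # keep the raw label on ties: smoothing never invents a stage
        out[i] = labels[i] if labels[i] in winners else vals[counts.argmax()]
    return out


def burst_state_coupling(ev: EventTable, hyp: Hypnogram, min_events: int = 5) -> dict:
    """Percent of burst peaks inside NREM epochs, with the chance level."""
    nrem_frac = hyp.occupancy()["NREM"]
    if len(ev) < min_events:
        return {
            "percent_nrem": None,
            "chance_percent": 100.0 * nrem_frac,
            "n_events": len(ev),
            "defined": False,
        }
    stages = hyp.stage_at(ev.t_peak)
    pct = 100.0 * float(np.mean(stages == "NREM"))
    return {
        "percent_nrem": pct,
        "chance_percent": 100.0 * nrem_frac,
        "n_events": len(ev),
        "defined": True,
    }


def nrem_coupling_cohort(per_animal: list[dict]) -> dict:
    """One-sample t of per-animal NREM percentages against mean chance."""
    usable = [d for d in per_animal if d.get("defined")]
    if len(usable) < 3:
        raise ValueError("need at least 3 animals with defined coupling")
    pct = np.array([d["percent_nrem"] for d in usable])
    chance = float(np.mean([d["chance_percent"] for d in usable]))
    res = group_test(pct, method="one_sample_t", mu0=chance)
    return {
        "mean_percent_nrem": float(pct.mean()),
        "chance_percent": chance,
        "n_animals": len(usable),
        "t_statistic": res.statistic,
        "p_value": res.p_value,
    }
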