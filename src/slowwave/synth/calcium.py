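"""Calcium-population synthesis: lognormal transient rates, US coupling.

Per-neuron transient rates are drawn from a lognormal whose sigma is
derived in closed form from (median, target fraction of rates above the
hyperactive threshold of 4/min), so detector-side hyperactive fractions are
a parameter-recovery exercise.  By default rates are drawn by stratified
inversion of the lognormal CDF (one jittered draw per equal-probability
stratum): the sample is still lognormal-distributed but the empirical tail
fraction has near-zero sampling variance, which is what a calibration
generator needs.  Set ``rate_sampling="iid"`` for plain i.i.d. draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import lognorm

from ..core import IntervalSet
from .config import GroundTruth, SynthConfig, lognormal_sigma_for_tail
from .states import generate_state_sequence

__all__ = ["generate_calcium", "NeuronTraceSet", "draw_lognormal_rates"]


@dataclass
class NeuronTraceSet:
    """Raw fluorescence traces for one imaging field."""

    F: np.ndarray  # (n_neurons, n_samples), arbitrary units, positive
    fs: float
    roi_ids: list[int]
    genotype_tags: list[str]

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def duration(self) -> float:
        return self.F.shape[1] / self.fs

    def to_frame(self):
        import pandas as pd

        cols = {f"roi{rid}": self.F[i] for i, rid in enumerate(self.roi_ids)}
        t = np.arange(self.F.shape[1]) / self.fs
        return pd.DataFrame({"t": t, **cols})


def draw_lognormal_rates(
    rng: np.random.Generator,
    n: int,
    median_hz: float,
    sigma_log: float,
    sampling: str = "stratified",
) -> np.ndarray:
    dist = lognorm(s=sigma_log, scale=median_hz)
    if sampling == "iid":
        return np.asarray(dist.rvs(size=n, random_state=rng))
    if sampling == "stratified":
        u = (np.arange(n) + rng.uniform(0, 1, size=n)) / n
        rates = np.asarray(dist.ppf(u))
        rng.shuffle(rates)
        return rates
    raise ValueError(f"unknown sampling {sampling!r}")


def _kernel(fs: float, rise: float, decay: float, amplitude: float) -> np.ndarray:
    t = np.arange(0, 6 * decay, 1.0 / fs)
    k = (1.0 - np.exp(-t / rise)) * np.exp(-t / decay)
    return amplitude * k / k.max()


def generate_calcium(
    cfg: SynthConfig,
    profile: str = "control",
    rate_sampling: str = "stratified",
) -> tuple[NeuronTraceSet, GroundTruth]:
    """Generate fluorescence traces plus ground-truth transients.

    Fluorescence = baseline + slow drift + transient kernels + white noise.
    Each transient is relocated into a concurrent up state with the
    profile's coupling probability (otherwise into a down state), so the
    in-US fraction of ground-truth transients equals the coupling
    probability exactly in expectation.
    """
    if profile not in ("control", "mosaic"):
        raise ValueError(f"unknown profile {profile!r}")
    cal = cfg.calcium
    if cal.n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if profile == "mosaic":
        median, tail, p_us = (
            cfg.mosaic.calcium_median_hz,
            cfg.mosaic.calcium_tail,
            cfg.mosaic.calcium_p_us,
        )
    else:
        median, tail, p_us = cal.median_hz, cal.hyperactive_tail, cal.p_us
    sigma = lognormal_sigma_for_tail(median, tail)

    fs, T = cal.fs_hz, cfg.duration_s
    n = int(round(T * fs))
    rng = cfg.rng(f"calcium/{profile}")
    us, ds = generate_state_sequence(cfg.state, duration=T, rng=cfg.rng("calcium/states"))

    rates = draw_lognormal_rates(rng, cal.n_neurons, median, sigma, rate_sampling)
    # clipping preserves the hyperactive tail fraction (threshold << cap)
    rates = np.minimum(rates, cal.rate_max_hz)
    kern = _kernel(fs, cal.kernel_rise_s, cal.kernel_decay_s, cal.amplitude_dff)

    F = np.empty((cal.n_neurons, n))
    t = np.arange(n) / fs
    transient_times: list[np.ndarray] = []
    us_inner = us.clip(0.5, T - 0.5)
    ds_inner = ds.clip(0.5, T - 0.5)
    for i in range(cal.n_neurons):
        k = rng.poisson(rates[i] * T)
        ev = np.zeros(0)
        if k:
            coupled = rng.random(k) < p_us
            ev = np.empty(k)
            for j in range(k):
                target = us_inner if coupled[j] else ds_inner
                w = target.durations / target.total_duration
                idx = rng.choice(len(target), p=w)
                s, e = target.intervals[idx]
                m = 0.1 * (e - s)
                ev[j] = rng.uniform(s + m, e - m)
            ev.sort()
        transient_times.append(ev)
        dff = np.zeros(n)
        for t_ev in ev:
            i0 = int(round(t_ev * fs))
            hi = min(n, i0 + kern.size)
            if hi > i0:
                dff[i0:hi] += kern[: hi - i0]
        drift = 1.0 + cal.drift_frac * np.sin(2 * np.pi * 0.005 * t + rng.uniform(0, 2 * np.pi))
        noise = cal.noise_sigma_dff * rng.standard_normal(n)
        F[i] = cal.baseline_au * drift * (1.0 + dff + noise)

    F = np.maximum(F, 1e-3)
    tags = ["green_knockout" if rng.random() < 0.5 else "red_wildtype" for _ in range(cal.n_neurons)]
    traces = NeuronTraceSet(F=F, fs=fs, roi_ids=list(range(cal.n_neurons)), genotype_tags=tags)
    gt = GroundTruth(
        us=us, ds=ds, transient_times=transient_times, true_rates_hz=rates
    )
    gt.validate_within(T)
    return traces, gt
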