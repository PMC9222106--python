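"""Paired-hemisphere LFP synthesis with full ground truth.

Each channel is the sum of: a state-locked slow (delta) deflection with
logistic transition ramps, 1/f**chi colored background plus a white noise
floor, up-state-gated gamma-band noise, state-dependent Poisson multi-unit
spike waveforms, and — under the mosaic profile — injected beta-band bursts
and hypersynchronous discharge templates coupled to the contralateral
up-state sequence.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from ..core import EventTable, Group, Hemisphere, IntervalSet, Recording, TimeSeries
from ..spectral import GAMMA, pink_noise
from .config import GroundTruth, SynthConfig
from .states import generate_state_sequence

__all__ = [
    "generate_lfp_pair",
    "hypersync_template",
    "smooth_indicator",
    "draw_event_count",
    "place_coupled_times",
    "poisson_times_in_intervals",
]

INJECTED = "lfp_injected"
CONTROL = "lfp_control"


def smooth_indicator(mask: np.ndarray, fs: float, tau_s: float) -> np.ndarray:
    """Smooth a binary state indicator with a logistic-CDF step response.

    Convolution with the logistic density of scale ``tau_s`` turns each
    state transition into a logistic ramp of time constant ``tau_s``.
    """
    x = mask.astype(float)
    if tau_s < 1.0 / fs:
        return x
    half = int(np.ceil(6 * tau_s * fs))
    t = np.arange(-half, half + 1) / fs
    u = t / tau_s
    kernel = 0.25 / tau_s / np.cosh(u / 2.0) ** 2  # logistic pdf
    kernel = kernel / kernel.sum()
    return np.convolve(np.pad(x, half, mode="edge"), kernel, mode="same")[half:-half]


def hypersync_template(
    fs: float, amplitude: float, width_s: float, ratio: float = 0.15
) -> tuple[np.ndarray, int]:
    """Difference-of-exponentials discharge template.

    Calibrated so the peak equals ``amplitude`` and the width at 25% of the
    peak equals ``width_s``.  Returns the sampled template and the index of
    its peak.
    """
    # unit-scale shape: h(t) = exp(-t) - exp(-t / ratio), peak normalized to 1
    grid = np.linspace(0, 12.0, 200_000)
    h = np.exp(-grid) - np.exp(-grid / ratio)
    h /= h.max()
    above = np.flatnonzero(h >= 0.25)
    width_unit = grid[above[-1]] - grid[above[0]]
    tau_d = width_s / width_unit
    n = int(np.ceil(10 * tau_d * fs))
    t = np.arange(n) / fs
    shape = np.exp(-t / tau_d) - np.exp(-t / (ratio * tau_d))
    shape /= shape.max()
    return amplitude * shape, int(np.argmax(shape))


def draw_event_count(
    rng: np.random.Generator, rate_per_hour: float, duration: float, mode: str
) -> int:
    expected = rate_per_hour * duration / 3600.0
    if mode == "fixed":
        return int(round(expected))
    if mode == "poisson":
        return int(rng.poisson(expected))
    raise ValueError(f"unknown count_mode {mode!r}")


def place_coupled_times(
    rng: np.random.Generator,
    n: int,
    inside: IntervalSet,
    outside: IntervalSet,
    p_inside: float,
    min_separation: float = 0.0,
    margin_frac: float = 0.1,
    exact_fraction: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw event times with a Bernoulli coupling to ``inside`` intervals.

    Each event draws coupled ~ Bernoulli(p_inside); coupled events land
    inside an ``inside`` interval, the rest inside an ``outside`` interval
    (never ambiguous).  Within the chosen interval the time is uniform over
    its central ``1 - 2*margin_frac`` portion, so membership is robust to
    small boundary-estimation errors downstream.  With
    ``exact_fraction=True`` exactly ``round(p_inside * n)`` events are
    coupled (a shuffled deterministic allocation for calibration runs).
    """
    if exact_fraction:
        k = int(round(p_inside * n))
        coupled = np.zeros(n, dtype=bool)
        coupled[:k] = True
        rng.shuffle(coupled)
    else:
        coupled = rng.random(n) < p_inside
    times = np.empty(n)
    accepted: list[float] = []
    for i in range(n):
        target = inside if coupled[i] else outside
        if len(target) == 0:
            raise ValueError("no interval available for the requested coupling draw")
        w = target.durations / target.total_duration
        for _ in range(2000):
            j = rng.choice(len(target), p=w)
            s, e = target.intervals[j]
            m = margin_frac * (e - s)
            t = rng.uniform(s + m, e - m)
            if all(abs(t - u) >= min_separation for u in accepted):
                break
        else:
            raise RuntimeError("could not place events with the requested separation")
        accepted.append(t)
        times[i] = t
    order = np.argsort(times)
    return times[order], coupled[order]


def poisson_times_in_intervals(
    rng: np.random.Generator, iv: IntervalSet, rate_hz: float
) -> np.ndarray:
    """Homogeneous Poisson event times restricted to an interval set."""
    if rate_hz <= 0 or len(iv) == 0:
        return np.zeros(0)
    out = []
    for s, e in iv:
        k = rng.poisson(rate_hz * (e - s))
        if k:
            out.append(rng.uniform(s, e, size=k))
    if not out:
        return np.zeros(0)
    return np.sort(np.concatenate(out))


def _gated_band_noise(
    rng: np.random.Generator, n: int, fs: float, f_lo: float, f_hi: float,
    rms: float, gate: np.ndarray,
) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sps.butter(4, [f_lo, min(f_hi, 0.45 * fs)], btype="band", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, white)
    band *= rms / max(np.sqrt(np.mean(band**2)), 1e-12)
    return band * gate


def _spike_waveform(fs: float, width_ms: float, amplitude_mv: float) -> np.ndarray:
    """Biphasic extracellular waveform: sharp trough then small rebound."""
    sigma = width_ms / 1000.0 / 2.355  # FWHM -> sigma
    t = np.arange(-4 * sigma, 8 * sigma, 1.0 / fs)
    w = -np.exp(-(t**2) / (2 * sigma**2)) + 0.4 * np.exp(
        -((t - 2.2 * sigma) ** 2) / (2 * (1.6 * sigma) ** 2)
    )
    return amplitude_mv * w / np.abs(w).max()


def _add_at(signal: np.ndarray, kernel: np.ndarray, center: int, peak_idx: int) -> None:
    lo = center - peak_idx
    hi = lo + kernel.size
    k_lo = max(0, -lo)
    k_hi = kernel.size - max(0, hi - signal.size)
    if k_lo < k_hi:
        signal[lo + k_lo : lo + k_hi] += kernel[k_lo:k_hi]


def _channel_params(cfg: SynthConfig, profile: str, injected: bool) -> dict:
    """Effective per-channel parameters after applying the profile deltas."""
    m = cfg.mosaic
    mosaic_side = profile == "mosaic" and injected
    return {
        "delta_amp": cfg.delta.amplitude_mv * (m.delta_amp_factor if mosaic_side else 1.0),
        "tau_tr": cfg.delta.tau_tr_s * (m.tau_tr_factor if mosaic_side else 1.0),
        "chi": m.chi if mosaic_side else cfg.background.chi,
        "rate_us": cfg.unit.rate_us_hz * (m.rate_us_factor if mosaic_side else 1.0),
        "rate_ds": cfg.unit.rate_ds_hz * (m.rate_ds_factor if mosaic_side else 1.0),
        "burst_rate": (m.burst_rate_per_hour if mosaic_side else cfg.burst.rate_per_hour),
        "hypersync_rate": (
            m.hypersync_rate_per_hour if mosaic_side else cfg.hypersync.rate_per_hour
        ),
    }


def generate_lfp_pair(
    cfg: SynthConfig,
    profile: str = "control",
    return_components: bool = False,
):
    """Generate a two-channel (injected + control hemisphere) LFP recording.

    Both hemispheres share one up/down sequence; the injected channel lags
    by ``cfg.lag_ms``.  Under ``profile="mosaic"`` the injected channel
    applies the configured deltas and carries beta bursts plus
    hypersynchronous discharges coupled (probability ``hypersync.p_us``) to
    the contralateral (control-hemisphere) up states.

    Returns ``(Recording, GroundTruth)``; with ``return_components=True`` a
    third dict maps channel label -> additive component arrays.
    """
    if profile not in ("control", "mosaic"):
        raise ValueError(f"unknown profile {profile!r}")
    fs, T = cfg.fs_lfp, cfg.duration_s
    n = int(round(T * fs))
    times = np.arange(n) / fs
    lag = cfg.lag_ms / 1000.0

    us, ds = generate_state_sequence(cfg)
    gt = GroundTruth(us=us, ds=ds)

    channels: dict[str, TimeSeries] = {}
    components: dict[str, dict[str, np.ndarray]] = {}
    burst_specs: list[tuple[float, float, float]] = []  # shared across hemispheres

    for label, injected in ((CONTROL, False), (INJECTED, True)):
        par = _channel_params(cfg, profile, injected)
        rng = cfg.rng(f"lfp/{label}")
        ch_lag = lag if injected else 0.0
        ch_us = us.shift(ch_lag).clip(0, T)
        ch_ds = ds.shift(ch_lag).clip(0, T)

        mask = ch_us.contains(times)
        smoothed = smooth_indicator(mask, fs, par["tau_tr"])
        delta_comp = par["delta_amp"] * (smoothed - smoothed.mean())
        bg = pink_noise(n, fs, par["chi"], cfg.background.rms_mv, rng)
        bg = bg + cfg.background.white_rms_mv * rng.standard_normal(n)
        gamma_comp = _gated_band_noise(
            rng, n, fs, GAMMA.f_lo, GAMMA.f_hi, cfg.gamma.amplitude_mv, smoothed
        )

        unit_comp = np.zeros(n)
        spike_times = np.concatenate(
            [
                poisson_times_in_intervals(rng, ch_us, par["rate_us"]),
                poisson_times_in_intervals(rng, ch_ds, par["rate_ds"]),
            ]
        )
        spike_times.sort()
        if spike_times.size:
            # enforce a 5 ms refractory so ground truth matches detector dead time
            keep = np.concatenate([[True], np.diff(spike_times) > 0.005])
            spike_times = spike_times[keep]
        wf = _spike_waveform(fs, cfg.unit.width_ms, cfg.unit.amplitude_mv)
        trough = int(np.argmin(wf))
        for t_sp in spike_times:
            _add_at(unit_comp, wf, int(round(t_sp * fs)), trough)
        gt.unit_times[label] = spike_times

        event_comp = np.zeros(n)
        if injected and par["burst_rate"] > 0:
            n_bursts = draw_event_count(rng, par["burst_rate"], T, cfg.burst.count_mode)
            shp = cfg.burst.duration_shape
            burst_rows = []
            t_cursor: list[float] = []
            for _ in range(n_bursts):
                dur = float(rng.gamma(shp, cfg.burst.duration_mean_s / shp))
                for _ in range(2000):
                    t_c = rng.uniform(0.05 * T, 0.95 * T)
                    if all(abs(t_c - u) > 2 * dur + 1.0 for u in t_cursor):
                        break
                t_cursor.append(t_c)
                phi = rng.uniform(0, 2 * np.pi)
                burst_specs.append((t_c, dur, phi))
                burst_rows.append(
                    {
                        "t_peak": t_c,
                        "t_start": t_c - dur / 2,
                        "t_end": t_c + dur / 2,
                        "amplitude": cfg.burst.amplitude_mv,
                        "duration": dur,
                        "channel": label,
                        "type": "beta_burst",
                    }
                )
            gt.bursts = EventTable.from_rows(burst_rows)

        if injected and par["hypersync_rate"] > 0:
            n_ev = draw_event_count(rng, par["hypersync_rate"], T, cfg.hypersync.count_mode)
            # coupling is to the *contralateral* (control-hemisphere) states
            ev_times, coupled = place_coupled_times(
                rng, n_ev, us.clip(1.0, T - 1.0), ds.clip(1.0, T - 1.0),
                cfg.hypersync.p_us, cfg.hypersync.min_separation_s,
                exact_fraction=cfg.hypersync.count_mode == "fixed",
            )
            template, pk = hypersync_template(
                fs, cfg.hypersync.amplitude_mv, cfg.hypersync.width_s
            )
            rows = []
            for t_ev in ev_times:
                _add_at(event_comp, template, int(round(t_ev * fs)), pk)
                rows.append(
                    {
                        "t_peak": t_ev,
                        "t_start": t_ev - cfg.hypersync.width_s * 0.25,
                        "t_end": t_ev + cfg.hypersync.width_s * 0.75,
                        "amplitude": cfg.hypersync.amplitude_mv,
                        "duration": cfg.hypersync.width_s,
                        "channel": label,
                        "type": "hypersync_spike",
                    }
                )
            gt.spikes = EventTable.from_rows(rows)
            gt.spike_coupled = coupled

        comp = {
            "delta": delta_comp,
            "background": bg,
            "gamma": gamma_comp,
            "units": unit_comp,
            "events": event_comp,
        }
        components[label] = comp
        channels[label] = TimeSeries(
            sum(comp.values()), fs=fs, label=label, units="mV"
        )

    # propagate bursts into both hemispheres (shared carrier, attenuated copy)
    if burst_specs:
        for label in (INJECTED, CONTROL):
            gain = 1.0 if label == INJECTED else cfg.burst.bilateral_gain
            sig = channels[label].samples
            extra = np.zeros(n)
            for t_c, dur, phi in burst_specs:
                m = int(round(dur * fs))
                if m < 2:
                    continue
                i0 = int(round((t_c - dur / 2) * fs))
                env = np.hanning(m)
                tt = np.arange(m) / fs
                kern = gain * cfg.burst.amplitude_mv * env * np.sin(
                    2 * np.pi * cfg.burst.carrier_hz * tt + phi
                )
                _add_at(extra, kern, i0 + m // 2, m // 2)
            components[label]["bursts"] = extra
            channels[label] = channels[label].copy_with(sig + extra)

    rec = Recording(
        channels=channels,
        animal_id=f"synth-{cfg.seed}",
        group=Group.control if profile == "control" else Group.mosaic_adult,
        hemisphere_map={
            INJECTED: Hemisphere.injected,
            CONTROL: Hemisphere.control_hemisphere,
        },
    )
    gt.validate_within(T)
    if return_components:
        return rec, gt, components
    return rec, gt
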