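"""Chronic EEG + EMG synthesis with a ground-truth hypnogram.

Stage sequence follows a Wake -> NREM -> (REM) -> Wake dwell chain.  EEG
content per stage: NREM carries strong delta, REM is theta-dominant
(6-9 Hz), Wake is low-amplitude broadband.  EMG variance is high in Wake
only.  Beta bursts are injected into the injected-hemisphere EEG with a
Bernoulli coupling to NREM.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from ..core import EventTable, Group, Hemisphere, IntervalSet, Recording, TimeSeries
from .config import GroundTruth, SynthConfig
from .lfp import draw_event_count, place_coupled_times, smooth_indicator, _add_at
from .states import sample_markov_stages

__all__ = ["generate_eeg_emg", "EEG_INJECTED", "EEG_CONTROL", "EMG"]

EEG_INJECTED = "eeg_injected"
EEG_CONTROL = "eeg_control"
EMG = "emg"

_STAGE_AMPS = {  # RMS (mV) of the stage-specific band component
    "Wake": 0.03,
    "NREM": 0.15,
    "REM": 0.08,
}


def _band_noise(rng, n, fs, f_lo, f_hi, rms):
    sos = sps.butter(4, [f_lo, min(f_hi, 0.45 * fs)], btype="band", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x * rms / max(np.sqrt(np.mean(x**2)), 1e-12)


def generate_eeg_emg(cfg: SynthConfig, profile: str = "control"):
    """Generate (Recording with 2 EEG + 1 EMG, GroundTruth).

    GroundTruth carries the stage hypnogram as an IntervalSet per stage and
    the injected beta bursts with their NREM-coupling draws.
    """
    if profile not in ("control", "mosaic"):
        raise ValueError(f"unknown profile {profile!r}")
    fs, T = cfg.fs_eeg, cfg.duration_s
    n = int(round(T * fs))
    times = np.arange(n) / fs
    hyp = cfg.hypnogram
    rng_states = cfg.rng("eeg/stages")
    segments = sample_markov_stages(
        rng_states, T,
        hyp.wake_mean_s, hyp.wake_shape,
        hyp.nrem_mean_s, hyp.nrem_shape,
        hyp.rem_mean_s, hyp.rem_shape,
        hyp.p_nrem_to_rem,
    )
    stage_iv = {
        stage: IntervalSet(
            [(s, e) for st, s, e in segments if st == stage], label=stage
        )
        for stage in ("Wake", "NREM", "REM")
    }
    gt = GroundTruth(hypnogram=stage_iv)

    gates = {
        stage: smooth_indicator(stage_iv[stage].contains(times), fs, 0.25)
        for stage in stage_iv
    }

    burst_rate = (
        cfg.mosaic.burst_rate_per_hour if profile == "mosaic" else cfg.burst.rate_per_hour
    )

    channels: dict[str, TimeSeries] = {}
    for label in (EEG_INJECTED, EEG_CONTROL):
        rng = cfg.rng(f"eeg/{label}")
        sig = 0.01 * rng.standard_normal(n)  # broadband floor
        sig += gates["NREM"] * _band_noise(rng, n, fs, 0.5, 4.0, _STAGE_AMPS["NREM"])
        # theta carrier kept clear of the 9 Hz beta edge to limit band leakage
        sig += gates["REM"] * _band_noise(rng, n, fs, 6.0, 8.4, _STAGE_AMPS["REM"])
        sig += gates["Wake"] * _band_noise(rng, n, fs, 0.5, 50.0, _STAGE_AMPS["Wake"])

        if label == EEG_INJECTED and burst_rate > 0:
            n_bursts = draw_event_count(rng, burst_rate, T, cfg.burst.count_mode)
            nrem = stage_iv["NREM"].clip(1.0, T - 1.0)
            other = stage_iv["NREM"].complement(1.0, T - 1.0)
            ev_times, in_nrem = place_coupled_times(
                rng, n_bursts, nrem, other, cfg.burst.p_nrem,
                min_separation=3 * cfg.burst.duration_mean_s + 2.0,
                exact_fraction=cfg.burst.count_mode == "fixed",
            )
            shp = cfg.burst.duration_shape
            rows = []
            for t_c in ev_times:
                dur = float(rng.gamma(shp, cfg.burst.duration_mean_s / shp))
                m = max(2, int(round(dur * fs)))
                tt = np.arange(m) / fs
                kern = (
                    cfg.burst.amplitude_mv
                    * np.hanning(m)
                    * np.sin(2 * np.pi * cfg.burst.carrier_hz * tt + rng.uniform(0, 2 * np.pi))
                )
                _add_at(sig, kern, int(round(t_c * fs)), m // 2)
                rows.append(
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
            gt.bursts = EventTable.from_rows(rows)
            gt.burst_in_nrem = in_nrem
        channels[label] = TimeSeries(sig, fs=fs, label=label, units="mV")

    rng_emg = cfg.rng("eeg/emg")
    emg_gate = 0.005 + (0.1 - 0.005) * gates["Wake"]
    channels[EMG] = TimeSeries(
        emg_gate * rng_emg.standard_normal(n), fs=fs, label=EMG, units="mV"
    )

    rec = Recording(
        channels=channels,
        animal_id=f"synth-eeg-{cfg.seed}",
        group=Group.control if profile == "control" else Group.mosaic_adult,
        hemisphere_map={
            EEG_INJECTED: Hemisphere.injected,
            EEG_CONTROL: Hemisphere.control_hemisphere,
            EMG: Hemisphere.none,
        },
    )
    gt.validate_within(T)
    return rec, gt
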