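"""Alternating up/down state sequences from gamma dwell-time distributions."""

from __future__ import annotations

import numpy as np

from ..core import IntervalSet
from .config import StateModel, SynthConfig

__all__ = ["generate_state_sequence", "draw_dwell", "sample_markov_stages"]


def draw_dwell(rng: np.random.Generator, mean: float, shape: float | None) -> float:
    """One dwell time; ``shape=None`` gives the deterministic mean."""
    if shape is None:
        return mean
    return float(rng.gamma(shape, mean / shape))


def generate_state_sequence(
    cfg: SynthConfig | StateModel,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[IntervalSet, IntervalSet]:
    """Alternating US/DS renewal sequence over [0, duration).

    Starts with a down state; dwell times are gamma distributed with the
    configured (shape, mean).  Deterministic under a fixed config seed.
    """
    if isinstance(cfg, SynthConfig):
        model = cfg.state
        duration = cfg.duration_s if duration is None else duration
        rng = cfg.rng("states") if rng is None else rng
    else:
        model = cfg
        if duration is None or rng is None:
            raise ValueError("duration and rng required with a bare StateModel")
    if duration <= 10 * model.cycle_mean:
        raise ValueError(
            f"duration {duration} s too short: need > {10 * model.cycle_mean:.1f} s"
        )
    us_rows, ds_rows = [], []
    t = 0.0
    in_us = False
    while t < duration:
        if in_us:
            dwell = draw_dwell(rng, model.us_mean, model.us_shape)
            us_rows.append((t, min(t + dwell, duration)))
        else:
            dwell = draw_dwell(rng, model.ds_mean, model.ds_shape)
            ds_rows.append((t, min(t + dwell, duration)))
        t += dwell
        in_us = not in_us
    return IntervalSet(us_rows, label="US"), IntervalSet(ds_rows, label="DS")


def sample_markov_stages(
    rng: np.random.Generator,
    duration: float,
    wake_mean: float,
    wake_shape: float,
    nrem_mean: float,
    nrem_shape: float,
    rem_mean: float,
    rem_shape: float,
    p_nrem_to_rem: float,
) -> list[tuple[str, float, float]]:
    """Wake -> NREM -> (REM with prob p) -> Wake dwell chain over [0, duration)."""
    out = []
    t = 0.0
    stage = "Wake"
    while t < duration:
        if stage == "Wake":
            dwell = draw_dwell(rng, wake_mean, wake_shape)
            nxt = "NREM"
        elif stage == "NREM":
            dwell = draw_dwell(rng, nrem_mean, nrem_shape)
            nxt = "REM" if rng.random() < p_nrem_to_rem else "Wake"
        else:
            dwell = draw_dwell(rng, rem_mean, rem_shape)
            nxt = "Wake"
        out.append((stage, t, min(t + dwell, duration)))
        t += dwell
        stage = nxt
    return out
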