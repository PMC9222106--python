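"""Generator parameterization and ground-truth containers.

Every quantity the analysis stages estimate has a configured counterpart
here, so analysis results can be validated as parameter recovery.  The
``mosaic`` block holds the multiplicative/absolute changes applied to the
injected channel when generating the mosaic condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from ..core import EventTable, IntervalSet

__all__ = [
    "StateModel",
    "DeltaModel",
    "BackgroundModel",
    "GammaModel",
    "UnitModel",
    "BurstModel",
    "HypersyncModel",
    "HypnogramModel",
    "CalciumModel",
    "MosaicDeltas",
    "SynthConfig",
    "GroundTruth",
    "lognormal_sigma_for_tail",
    "HYPERACTIVE_THRESHOLD_HZ",
]

#: hyperactive criterion: more than 4 transients per minute
HYPERACTIVE_THRESHOLD_HZ = 4.0 / 60.0


@dataclass
class StateModel:
    """Gamma-distributed up/down dwell times; ``shape=None`` => deterministic."""

    us_mean: float = 0.5
    us_shape: float | None = 5.0
    ds_mean: float = 0.3
    ds_shape: float | None = 5.0

    @property
    def cycle_mean(self) -> float:
        return self.us_mean + self.ds_mean

    @property
    def expected_duty(self) -> float:
        return self.us_mean / self.cycle_mean


@dataclass
class DeltaModel:
    """State-locked slow deflection; ``tau_tr`` shapes the US transition ramp."""

    amplitude_mv: float = 0.4
    tau_tr_s: float = 0.025


@dataclass
class BackgroundModel:
    """1/f**chi colored noise plus a white noise floor (for the MUA band)."""

    chi: float = 2.0
    rms_mv: float = 0.05
    white_rms_mv: float = 0.01


@dataclass
class GammaModel:
    """High-frequency (40-100 Hz) noise gated to up states."""

    amplitude_mv: float = 0.03


@dataclass
class UnitModel:
    """State-dependent Poisson multi-unit spikes added to the LFP."""

    rate_us_hz: float = 20.0
    rate_ds_hz: float = 0.5
    width_ms: float = 1.0
    # trough depth; negative-going at the electrode.  Sized so the trough
    # after a 300 Hz high-pass at 1 kHz sampling sits near 8x the band noise.
    amplitude_mv: float = 0.1


@dataclass
class BurstModel:
    """Transient 9-25 Hz oscillation packets."""

    rate_per_hour: float = 0.0
    duration_mean_s: float = 1.5
    duration_shape: float = 25.0
    carrier_hz: float = 15.0
    amplitude_mv: float = 0.2
    p_nrem: float = 0.87
    bilateral_gain: float = 0.5  # attenuation of the contralateral copy
    count_mode: str = "poisson"  # or "fixed": exactly round(rate * T)


@dataclass
class HypersyncModel:
    """Brief large-amplitude population discharges (interictal-spike-like)."""

    rate_per_hour: float = 0.0
    amplitude_mv: float = 0.49
    width_s: float = 0.23  # width at 25% of peak amplitude
    p_us: float = 0.81  # probability of lying in a contralateral up state
    count_mode: str = "poisson"
    min_separation_s: float = 1.5


@dataclass
class HypnogramModel:
    """Semi-Markov Wake/NREM/REM alternation (gamma dwell times)."""

    wake_mean_s: float = 240.0
    wake_shape: float = 3.0
    nrem_mean_s: float = 280.0
    nrem_shape: float = 3.0
    rem_mean_s: float = 60.0
    rem_shape: float = 3.0
    p_nrem_to_rem: float = 0.5

    def expected_occupancy(self) -> dict[str, float]:
        """Stationary stage fractions of the Wake->NREM->(REM?)->Wake chain."""
        wake, nrem = self.wake_mean_s, self.nrem_mean_s
        rem = self.rem_mean_s * self.p_nrem_to_rem
        total = wake + nrem + rem
        return {"Wake": wake / total, "NREM": nrem / total, "REM": rem / total}


@dataclass
class CalciumModel:
    """Population of neurons with lognormal transient rates."""

    n_neurons: int = 300
    fs_hz: float = 10.0
    median_hz: float = 0.018
    hyperactive_tail: float = 0.078  # P(rate > 4/min)
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 0.5
    amplitude_dff: float = 0.6
    noise_sigma_dff: float = 0.05
    baseline_au: float = 100.0
    drift_frac: float = 0.03
    p_us: float = 0.9
    rate_max_hz: float = 0.5  # cap: indicators cannot resolve faster trains

    @property
    def sigma_log(self) -> float:
        return lognormal_sigma_for_tail(self.median_hz, self.hyperactive_tail)


@dataclass
class MosaicDeltas:
    """Changes applied to the injected channel / population under mosaic."""

    delta_amp_factor: float = 0.5
    tau_tr_factor: float = 2.0
    rate_us_factor: float = 0.4
    rate_ds_factor: float = 4.0
    chi: float = 1.6
    burst_rate_per_hour: float = 12.0
    hypersync_rate_per_hour: float = 150.0
    calcium_median_hz: float = 0.022
    calcium_tail: float = 0.261
    calcium_p_us: float = 0.6


@dataclass
class SynthConfig:
    """Full, seeded generator parameterization."""

    seed: int = 0
    fs_lfp: float = 1000.0
    fs_eeg: float = 200.0
    duration_s: float = 600.0
    lag_ms: float = 10.0
    state: StateModel = field(default_factory=StateModel)
    delta: DeltaModel = field(default_factory=DeltaModel)
    background: BackgroundModel = field(default_factory=BackgroundModel)
    gamma: GammaModel = field(default_factory=GammaModel)
    unit: UnitModel = field(default_factory=UnitModel)
    burst: BurstModel = field(default_factory=BurstModel)
    hypersync: HypersyncModel = field(default_factory=HypersyncModel)
    hypnogram: HypnogramModel = field(default_factory=HypnogramModel)
    calcium: CalciumModel = field(default_factory=CalciumModel)
    mosaic: MosaicDeltas = field(default_factory=MosaicDeltas)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fs_lfp <= 0 or self.fs_eeg <= 0:
            raise ValueError("sampling rates must be positive")
        if self.duration_s <= 10 * self.state.cycle_mean:
            raise ValueError(
                "duration must exceed 10x the mean up+down cycle "
                f"({10 * self.state.cycle_mean:.1f} s)"
            )
        for name, p in (
            ("burst.p_nrem", self.burst.p_nrem),
            ("hypersync.p_us", self.hypersync.p_us),
            ("calcium.p_us", self.calcium.p_us),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name, r in (
            ("unit.rate_us_hz", self.unit.rate_us_hz),
            ("unit.rate_ds_hz", self.unit.rate_ds_hz),
            ("burst.rate_per_hour", self.burst.rate_per_hour),
            ("hypersync.rate_per_hour", self.hypersync.rate_per_hour),
        ):
            if r < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: str = "") -> np.random.Generator:
        """Independent deterministic stream derived from (seed, stream)."""
        import zlib

        tag = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence([self.seed, tag])
        return np.random.default_rng(ss)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        kwargs = dict(d)
        for key, sub in (
            ("state", StateModel),
            ("delta", DeltaModel),
            ("background", BackgroundModel),
            ("gamma", GammaModel),
            ("unit", UnitModel),
            ("burst", BurstModel),
            ("hypersync", HypersyncModel),
            ("hypnogram", HypnogramModel),
            ("calcium", CalciumModel),
            ("mosaic", MosaicDeltas),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Everything the generator injected, on the global clock."""

    us: IntervalSet = field(default_factory=lambda: IntervalSet(label="US"))
    ds: IntervalSet = field(default_factory=lambda: IntervalSet(label="DS"))
    bursts: EventTable = field(default_factory=EventTable)
    spikes: EventTable = field(default_factory=EventTable)
    unit_times: dict[str, np.ndarray] = field(default_factory=dict)
    hypnogram: dict[str, IntervalSet] = field(default_factory=dict)
    transient_times: list[np.ndarray] = field(default_factory=list)
    true_rates_hz: np.ndarray = field(default_factory=lambda: np.zeros(0))
    spike_coupled: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    burst_in_nrem: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def validate_within(self, duration: float) -> None:
        for iv in [self.us, self.ds, *self.hypnogram.values()]:
            if len(iv) and (iv.starts[0] < -1e-9 or iv.ends[-1] > duration + 1e-9):
                raise ValueError("ground-truth interval outside [0, duration]")
        for tbl in (self.bursts, self.spikes):
            if len(tbl) and (
                tbl.t_peak.min() < -1e-9 or tbl.t_peak.max() > duration + 1e-9
            ):
                raise ValueError("ground-truth event outside [0, duration]")


def lognormal_sigma_for_tail(
    median_hz: float, tail: float, threshold_hz: float = HYPERACTIVE_THRESHOLD_HZ
) -> float:
    """Closed-form lognormal sigma giving P(rate > threshold) == tail.

    With rate ~ LogNormal(mu=ln median, sigma), P(rate > thr) =
    1 - Phi((ln thr - ln median)/sigma); invert for sigma.
    """
    from scipy.stats import norm

    if not 0 < tail < 1:
        raise ValueError("tail must be in (0, 1)")
    if median_hz <= 0 or threshold_hz <= median_hz:
        raise ValueError("need 0 < median < threshold")
    z = norm.ppf(1.0 - tail)
    if z <= 0:
        raise ValueError("tail >= 0.5 requires median above the threshold")
    return float(np.log(threshold_hz / median_hz) / z)
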