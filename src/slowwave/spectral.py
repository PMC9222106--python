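"""Band filtering, power spectra and the spectral-exponent E:I proxy.

Filters are 4th-order Butterworth applied forward-backward (zero phase).
Welch defaults (4 s segments, 50% overlap, Hann taper) resolve the 0.5 Hz
lower edge of the slow-wave band.  The exponent of the power-spectrum decay
below 50 Hz serves as a proxy for the excitation:inhibition balance — a
flatter spectrum indicates relatively more excitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import IntervalSet, TimeSeries

__all__ = [
    "BandDefinition",
    "DELTA",
    "BETA",
    "GAMMA",
    "Spectrum",
    "ExponentFit",
    "bandpass",
    "band_rms",
    "welch_psd",
    "cross_spectrum",
    "fit_spectral_exponent",
    "pink_noise",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("need 0 < f_lo < f_hi")

    def validate_for(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.f_hi} Hz >= Nyquist {fs / 2} Hz"
            )

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo


DELTA = BandDefinition("delta", 0.5, 4.0)
BETA = BandDefinition("beta", 9.0, 25.0)
GAMMA = BandDefinition("gamma", 40.0, 100.0)


@dataclass
class Spectrum:
    """One-sided power spectral density."""

    freqs: np.ndarray
    power: np.ndarray
    segment_s: float
    overlap: float
    n_segments: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power density must be nonnegative")

    def band_power(self, f_lo: float, f_hi: float) -> float:
        """Integrated power within [f_lo, f_hi] (trapezoidal)."""
        sel = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if sel.sum() < 2:
            raise ValueError("fewer than 2 bins in the requested band")
        return float(np.trapezoid(self.power[sel], self.freqs[sel]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"freq_hz": self.freqs, "power": self.power})


@dataclass
class ExponentFit:
    """Least-squares decay-exponent fit of a power spectrum.

    For ``semilog_exponential`` the model is ``P(f) ~ 10**(a - exponent*f
    * log10(e))`` i.e. an exponential decay per Hz; for
    ``loglog_powerlaw`` it is ``P(f) ~ f**(-exponent)``.  ``exponent`` is
    positive for decaying spectra.
    """

    exponent: float
    intercept: float
    f_lo: float
    f_hi: float
    model: str
    r_squared: float
    excluded: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "exponent": float(self.exponent),
            "intercept": float(self.intercept),
            "f_lo": self.f_lo,
            "f_hi": self.f_hi,
            "model": self.model,
            "r_squared": float(self.r_squared),
            "excluded": list(self.excluded) if self.excluded else None,
        }


def _butter_band(band: BandDefinition, fs: float, order: int = 4):
    band.validate_for(fs)
    return sps.butter(order, [band.f_lo, band.f_hi], btype="band", fs=fs, output="sos")


def bandpass(ts: TimeSeries, band: BandDefinition, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    sos = _butter_band(band, ts.fs, order)
    out = sps.sosfiltfilt(sos, ts.samples)
    return ts.copy_with(out, label=f"{ts.label}[{band.name}]")


def highpass(ts: TimeSeries, f_lo: float, order: int = 4) -> TimeSeries:
    if f_lo >= ts.fs / 2:
        raise ValueError(f"high-pass edge {f_lo} Hz >= Nyquist {ts.fs / 2} Hz")
    sos = sps.butter(order, f_lo, btype="high", fs=ts.fs, output="sos")
    return ts.copy_with(sps.sosfiltfilt(sos, ts.samples))


def band_rms(ts: TimeSeries, band: BandDefinition, window: IntervalSet | None = None) -> float:
    """RMS of the band-passed signal, optionally restricted to intervals."""
    if ts.duration < 10.0 / band.f_lo:
        raise ValueError(
            f"record of {ts.duration:.1f} s too short for band_rms at f_lo={band.f_lo} Hz "
            f"(need >= {10.0 / band.f_lo:.1f} s)"
        )
    filtered = bandpass(ts, band)
    x = filtered.samples
    if window is not None:
        mask = window.contains(filtered.times)
        if not mask.any():
            raise ValueError("window does not overlap the record")
        x = x[mask]
    return float(np.sqrt(np.mean(x**2)))


def welch_psd(ts: TimeSeries, segment_s: float = 4.0, overlap: float = 0.5) -> Spectrum:
    """One-sided Welch density (Hann taper)."""
    nperseg = int(round(segment_s * ts.fs))
    if nperseg < 64:
        raise ValueError("segment must contain at least 64 samples")
    if nperseg > ts.n:
        raise ValueError("segment longer than the record")
    noverlap = int(round(overlap * nperseg))
    freqs, power = sps.welch(
        ts.samples, fs=ts.fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant",
    )
    step = nperseg - noverlap
    n_segments = 1 + (ts.n - nperseg) // step
    # drop the DC bin: detrending makes it meaningless and exponent fits use log power
    return Spectrum(freqs[1:], power[1:], segment_s, overlap, n_segments)


def cross_spectrum(
    a: TimeSeries,
    b: TimeSeries,
    windows: IntervalSet | None = None,
    segment_s: float = 1.0,
    overlap: float = 0.5,
) -> Spectrum:
    """Magnitude of the Welch cross-density, restricted to ``windows``.

    Segments are taken only from stretches fully inside the given windows,
    then averaged coherently per window and combined across windows.
    """
    if a.fs != b.fs:
        raise ValueError("cross_spectrum requires equal sampling rates")
    nperseg = int(round(segment_s * a.fs))
    if windows is None:
        windows = IntervalSet([(a.t0, a.t0 + min(a.duration, b.duration))])
    if len(windows) == 0:
        raise ValueError("windows must be nonempty")
    noverlap = int(round(overlap * nperseg))
    acc = None
    n_segments = 0
    freqs = None
    for s, e in windows:
        i_lo = max(0, int(np.ceil((s - a.t0) * a.fs)))
        i_hi = min(a.n, b.n, int(np.floor((e - a.t0) * a.fs)))
        if i_hi - i_lo < nperseg:
            continue
        xa = a.samples[i_lo:i_hi]
        xb = b.samples[i_lo:i_hi]
        freqs, pxy = sps.csd(
            xa, xb, fs=a.fs, window="hann", nperseg=nperseg, noverlap=noverlap,
            detrend="constant",
        )
        step = nperseg - noverlap
        k = 1 + (xa.size - nperseg) // step
        acc = pxy * k if acc is None else acc + pxy * k
        n_segments += k
    if acc is None:
        raise ValueError("no window is as long as one segment")
    mag = np.abs(acc / n_segments)
    return Spectrum(freqs[1:], mag[1:], segment_s, overlap, n_segments)


def fit_spectral_exponent(
    spec: Spectrum,
    f_lo: float = 1.0,
    f_hi: float = 50.0,
    model: str = "semilog_exponential",
    exclude: tuple[float, float] | None = (45.0, 55.0),
) -> ExponentFit:
    """Fit the decay exponent of a spectrum over [f_lo, f_hi].

    ``semilog_exponential`` regresses log10 power on frequency (exponent in
    1/Hz); ``loglog_powerlaw`` regresses log10 power on log10 frequency
    (dimensionless exponent).  An optional notch band (default 45-55 Hz,
    line-noise guard) is excluded from the fit.
    """
    if model not in ("semilog_exponential", "loglog_powerlaw"):
        raise ValueError(f"unknown model {model!r}")
    sel = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if exclude is not None:
        sel &= ~((spec.freqs >= exclude[0]) & (spec.freqs <= exclude[1]))
    if sel.sum() < 8:
        raise ValueError("need at least 8 frequency bins within the fit band")
    f = spec.freqs[sel]
    p = spec.power[sel]
    if np.any(p <= 0):
        bad = f[p <= 0]
        raise ValueError(f"nonpositive power at bins {bad[:5].tolist()}; cannot take log")
    y = np.log10(p)
    x = f if model == "semilog_exponential" else np.log10(f)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    # convert the log10 slope into a decay exponent, positive for decay
    if model == "semilog_exponential":
        exponent = -slope * np.log(10.0)  # P ~ exp(-exponent * f)
    else:
        exponent = -slope  # P ~ f ** (-exponent)
    return ExponentFit(
        exponent=float(exponent),
        intercept=float(intercept),
        f_lo=f_lo,
        f_hi=f_hi,
        model=model,
        r_squared=max(0.0, min(1.0, r2)),
        excluded=exclude,
    )


def pink_noise(n: int, fs: float, chi: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Synthesize 1/f**chi noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-chi / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n=n)
    scale = np.sqrt(np.mean(shaped**2))
    if scale == 0:
        return shaped
    return shaped * (rms / scale)
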