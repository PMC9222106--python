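"""Filtering, spectra and exponent fits against analytic oracles."""

import numpy as np
import pytest

from slowwave.core import IntervalSet, TimeSeries
from slowwave.spectral import (
    BETA,
    BandDefinition,
    DELTA,
    GAMMA,
    band_rms,
    bandpass,
    cross_spectrum,
    fit_spectral_exponent,
    pink_noise,
    welch_psd,
)


class TestBandpass:
    def test_in_band_identity(self, make_sine):
        ts = make_sine(2.0, duration=120.0)
        out = bandpass(ts, DELTA)
        mid = slice(10_000, -10_000)
        amp = np.max(np.abs(out.samples[mid]))
        assert amp == pytest.approx(1.0, rel=0.02)
        assert out.n == ts.n

    def test_stopband_rejection(self, make_sine):
        ts = make_sine(30.0, duration=120.0)
        out = bandpass(ts, DELTA)
        mid = slice(5000, -5000)  # exclude filter edge transients
        rms_in = np.sqrt(np.mean(ts.samples[mid] ** 2))
        rms_out = np.sqrt(np.mean(out.samples[mid] ** 2))
        assert rms_out < 0.01 * rms_in

    def test_white_noise_variance_ratio(self, rng):
        x = TimeSeries(rng.standard_normal(600_000), fs=1000.0)
        out = bandpass(x, BETA)
        # crude flat-spectrum integral (brick-wall band / Nyquist)
        brick = BETA.width / 500.0
        assert np.var(out.samples) == pytest.approx(brick, rel=0.15)
        # exact flat-spectrum oracle: integrate the realized |H|^2 response
        # (forward-backward Butterworth: power gain |H(f)|^4)
        from scipy.signal import butter, sosfreqz

        sos = butter(4, [BETA.f_lo, BETA.f_hi], btype="band", fs=1000.0, output="sos")
        freqs, h = sosfreqz(sos, worN=1 << 16, fs=1000.0)
        expected = np.trapezoid(np.abs(h) ** 4, freqs) / 500.0
        assert np.var(out.samples) == pytest.approx(expected, rel=0.03)

    def test_band_outside_nyquist(self, make_sine):
        ts = make_sine(2.0, fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ts, GAMMA)

    def test_zero_phase(self, make_sine):
        # cross-correlation lag between input and band-passed 2 Hz sine is 0
        ts = make_sine(2.0, duration=60.0)
        out = bandpass(ts, DELTA)
        mid = slice(5000, 55_000)
        lags = np.arange(-5, 6)
        cc = [np.dot(ts.samples[mid], np.roll(out.samples, l)[mid]) for l in lags]
        assert lags[int(np.argmax(cc))] == 0


class TestBandRms:
    def test_sine_analytic(self, make_sine):
        ts = make_sine(2.0, duration=60.0, amplitude=0.8)
        assert band_rms(ts, DELTA) == pytest.approx(0.8 / np.sqrt(2), rel=0.02)

    def test_zero_signal(self):
        ts = TimeSeries(np.zeros(60_000), fs=1000.0)
        assert band_rms(ts, DELTA) == pytest.approx(0.0, abs=1e-12)

    def test_too_short(self, make_sine):
        ts = make_sine(2.0, duration=5.0)
        with pytest.raises(ValueError, match="too short"):
            band_rms(ts, DELTA)

    def test_agrees_with_psd_integral(self, rng):
        cfg_rms = 0.2
        x = pink_noise(300_000, 1000.0, 1.0, cfg_rms, rng)
        ts = TimeSeries(x, fs=1000.0)
        via_filter = band_rms(ts, DELTA)
        spec = welch_psd(ts, segment_s=8.0)
        via_psd = np.sqrt(spec.band_power(0.5, 4.0))
        assert via_filter == pytest.approx(via_psd, rel=0.10)


class TestWelch:
    def test_flat_density_white_noise(self, rng):
        x = TimeSeries(rng.standard_normal(400_000), fs=1000.0)
        spec = welch_psd(x)
        sel = (spec.freqs > 10) & (spec.freqs < 400)
        assert spec.power[sel].mean() == pytest.approx(1.0 / 500.0, rel=0.10)

    def test_sine_peak_bin(self, make_sine):
        spec = welch_psd(make_sine(10.0, duration=120.0))
        assert spec.freqs[int(np.argmax(spec.power))] == pytest.approx(10.0, abs=0.3)

    def test_parseval(self, rng):
        # stationary LFP-like mixture: slow-wave + beta + broadband noise
        t = np.arange(200_000) / 1000.0
        x = (
            0.3 * np.sin(2 * np.pi * 1.25 * t)
            + 0.05 * np.sin(2 * np.pi * 15.0 * t + 1.0)
            + 0.1 * rng.standard_normal(t.size)
        )
        ts = TimeSeries(x, fs=1000.0)
        spec = welch_psd(ts)
        total = np.trapezoid(spec.power, spec.freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_segment_longer_than_record(self, make_sine):
        with pytest.raises(ValueError, match="longer than the record"):
            welch_psd(make_sine(2.0, duration=2.0), segment_s=4.0)

    def test_too_few_samples_per_segment(self, make_sine):
        with pytest.raises(ValueError, match="64 samples"):
            welch_psd(make_sine(2.0, fs=10.0, duration=100.0), segment_s=4.0)


class TestCrossSpectrum:
    def test_identical_signals_equal_autospectrum(self, rng):
        x = TimeSeries(rng.standard_normal(60_000), fs=1000.0)
        cross = cross_spectrum(x, x, segment_s=1.0)
        auto = welch_psd(x, segment_s=1.0)
        np.testing.assert_allclose(cross.power, auto.power, rtol=1e-8)

    def test_independent_noise_decays_with_segments(self, rng):
        fs = 1000.0
        mags = []
        for n_seg in (4, 64):
            n = int(n_seg * fs)
            a = TimeSeries(rng.standard_normal(n), fs=fs)
            b = TimeSeries(rng.standard_normal(n), fs=fs)
            cross = cross_spectrum(a, b, segment_s=1.0, overlap=0.0)
            mags.append(cross.power.mean())
        assert mags[1] < mags[0]

    def test_burst_windows_show_shared_carrier(self, rng):
        fs = 1000.0
        n = 120_000
        t = np.arange(n) / fs
        shared = 0.5 * np.sin(2 * np.pi * 15.0 * t)
        windows = IntervalSet([(10, 20), (50, 60)])
        gate = windows.contains(t)
        a = TimeSeries(rng.standard_normal(n) * 0.3 + shared * gate, fs=fs)
        b = TimeSeries(rng.standard_normal(n) * 0.3 + shared * gate, fs=fs)
        in_burst = cross_spectrum(a, b, windows, segment_s=1.0)
        out_burst = cross_spectrum(a, b, windows.complement(0, 120.0), segment_s=1.0)
        f15 = np.argmin(np.abs(in_burst.freqs - 15.0))
        assert in_burst.power[f15] > 10 * np.median(in_burst.power)
        assert out_burst.power[f15] < 3 * np.median(out_burst.power)

    def test_rate_mismatch(self, rng):
        a = TimeSeries(rng.standard_normal(4000), fs=1000.0)
        b = TimeSeries(rng.standard_normal(2000), fs=500.0)
        with pytest.raises(ValueError, match="equal sampling"):
            cross_spectrum(a, b)

    def test_windows_too_short(self, rng):
        a = TimeSeries(rng.standard_normal(10_000), fs=1000.0)
        with pytest.raises(ValueError, match="segment"):
            cross_spectrum(a, a, IntervalSet([(0.0, 0.2)]), segment_s=1.0)


class TestExponentFit:
    def test_white_noise_near_zero(self, rng):
        x = TimeSeries(rng.standard_normal(400_000), fs=1000.0)
        spec = welch_psd(x)
        for model in ("semilog_exponential", "loglog_powerlaw"):
            fit = fit_spectral_exponent(spec, model=model)
            assert abs(fit.exponent) < 0.05

    def test_powerlaw_recovery(self, rng):
        x = TimeSeries(pink_noise(400_000, 1000.0, 2.0, 0.1, rng), fs=1000.0)
        fit = fit_spectral_exponent(welch_psd(x), model="loglog_powerlaw")
        assert fit.exponent == pytest.approx(2.0, abs=0.15)
        assert fit.r_squared > 0.95

    def test_scale_invariance(self, rng):
        x = pink_noise(200_000, 1000.0, 1.8, 0.1, rng)
        f1 = fit_spectral_exponent(welch_psd(TimeSeries(x, fs=1000.0)))
        f2 = fit_spectral_exponent(welch_psd(TimeSeries(7.0 * x, fs=1000.0)))
        assert f1.exponent == pytest.approx(f2.exponent, rel=1e-6)
        assert f2.intercept != pytest.approx(f1.intercept, abs=0.1)

    def test_inhibition_surrogate_increases_exponent(self, rng):
        # extra low-frequency 1/f^chi power (GABA-like surrogate) steepens
        # the fit
        base = pink_noise(300_000, 1000.0, 1.5, 0.1, rng)
        extra = pink_noise(300_000, 1000.0, 3.0, 0.15, rng)
        f_base = fit_spectral_exponent(welch_psd(TimeSeries(base, fs=1000.0)))
        f_gaba = fit_spectral_exponent(welch_psd(TimeSeries(base + extra, fs=1000.0)))
        assert f_gaba.exponent > f_base.exponent

    def test_too_few_bins(self, rng):
        x = TimeSeries(rng.standard_normal(100_000), fs=1000.0)
        spec = welch_psd(x)
        with pytest.raises(ValueError, match="8 frequency bins"):
            fit_spectral_exponent(spec, f_lo=1.0, f_hi=1.5)

    def test_band_presets(self):
        assert (DELTA.f_lo, DELTA.f_hi) == (0.5, 4.0)
        assert (BETA.f_lo, BETA.f_hi) == (9.0, 25.0)
        assert (GAMMA.f_lo, GAMMA.f_hi) == (40.0, 100.0)

    def test_bad_band(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 5.0, 2.0)
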