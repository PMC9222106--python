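"""dF/F, transient detection and population statistics."""

import numpy as np
import pytest

from slowwave.calcium import (
    HYPERACTIVE_PER_MIN,
    NeuronTrace,
    TransientParams,
    compute_dff,
    detect_transients,
    fov_activity,
    population_stats,
    score_population,
    transients_in_us,
)
from slowwave.synth import SynthConfig, generate_calcium


def _trace_from(F, fs=10.0, roi=0):
    return NeuronTrace(roi_id=roi, F=np.asarray(F, dtype=float), fs=fs)


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        tr = _trace_from(np.full(2000, 50.0))
        dff = compute_dff(tr)
        np.testing.assert_allclose(dff.samples, 0.0, atol=1e-9)

    def test_step_to_double_baseline(self):
        F = np.full(4000, 100.0)
        F[2000:2005] = 200.0
        dff = compute_dff(_trace_from(F))
        assert dff.samples[2002] == pytest.approx(1.0, abs=0.05)

    def test_gain_invariance(self, rng):
        F = 100.0 * (1.0 + 0.05 * rng.standard_normal(3000).clip(-3, 3))
        d1 = compute_dff(_trace_from(F))
        d2 = compute_dff(_trace_from(7.0 * F))
        np.testing.assert_allclose(d1.samples, d2.samples, atol=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="baseline window"):
            compute_dff(_trace_from(np.full(100, 1.0)))

    def test_drift_tolerant_amplitudes(self):
        cfg = SynthConfig(seed=5, duration_s=300.0)
        cfg.calcium.n_neurons = 1
        cfg.calcium.median_hz = 0.05
        cfg.calcium.hyperactive_tail = 0.05
        cfg.calcium.noise_sigma_dff = 1e-6
        traces, gt = generate_calcium(cfg, "control")
        # with drift
        dff = compute_dff(_trace_from(traces.F[0]))
        ev = gt.transient_times[0]
        if ev.size:
            peaks = [dff.samples[int(t * 10) : int(t * 10) + 15].max() for t in ev]
            assert np.mean(peaks) == pytest.approx(cfg.calcium.amplitude_dff, rel=0.10)


class TestDetectTransients:
    def test_noise_only_mostly_silent(self, rng):
        fp = 0
        for _ in range(50):
            x = 0.05 * rng.standard_normal(1200)
            from slowwave.core import TimeSeries

            times, _ = detect_transients(TimeSeries(x, fs=10.0, units="dF/F"))
            fp += times.size > 0
        assert fp <= 5

    def test_ground_truth_recall_precision(self):
        cfg = SynthConfig(seed=6, duration_s=600.0)
        cfg.calcium.n_neurons = 30
        cfg.calcium.median_hz = 2.0 / 60.0  # ~2 per minute
        cfg.calcium.hyperactive_tail = 0.10
        traces, gt = generate_calcium(cfg, "control")
        table = score_population(traces)
        tp = fp = fn = 0
        for i in range(30):
            det = table.event_times[i]
            true = gt.transient_times[i]
            for t in det:
                (tp, fp) = (tp + 1, fp) if true.size and np.min(np.abs(true - t)) < 0.3 else (tp, fp + 1)
            for t in true:
                if det.size == 0 or np.min(np.abs(det - t)) >= 0.3:
                    fn += 1
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_close_kernels_merge(self):
        from slowwave.core import TimeSeries

        fs = 10.0
        t = np.arange(0, 120, 1 / fs)
        kern = lambda t0: 0.6 * np.exp(-np.maximum(t - t0, 0) / 0.5) * (t >= t0)
        x = kern(60.0) + kern(60.4) + 0.01 * np.sin(t)  # tiny ripple, no noise
        times, _ = detect_transients(TimeSeries(x, fs=fs, units="dF/F"))
        assert times.size == 1  # refractory merges the pair

    def test_deterministic(self, rng):
        from slowwave.core import TimeSeries

        x = 0.05 * rng.standard_normal(1200)
        ts = TimeSeries(x, fs=10.0)
        t1, _ = detect_transients(ts)
        t2, _ = detect_transients(ts)
        np.testing.assert_array_equal(t1, t2)


class TestPopulationStats:
    def test_boundary_exactly_4_per_min_not_hyperactive(self):
        rows = [
            dict(roi_id=i, genotype_tag="unknown", n_events=40, frequency_hz=4.0 / 60,
                 per_min=4.0, active=True, hyperactive=4.0 > HYPERACTIVE_PER_MIN)
            for i in range(25)
        ]
        from slowwave.calcium import TransientTable

        table = TransientTable(rows, {i: np.zeros(40) for i in range(25)}, 600.0)
        stats = population_stats(table)["primary"]
        assert stats["hyperactive_pct"] == 0.0

    def test_tail_recovery(self):
        cfg = SynthConfig(seed=3, duration_s=900.0)
        traces_c, _ = generate_calcium(cfg, "control")
        tab_c = score_population(traces_c)
        stats = population_stats(tab_c)["primary"]
        assert stats["hyperactive_pct"] == pytest.approx(7.8, abs=3.0)
        assert stats["median_frequency_hz"] < 0.02

    def test_mosaic_dispersion_and_tail(self):
        cfg = SynthConfig(seed=4, duration_s=900.0)
        traces_c, _ = generate_calcium(cfg, "control")
        traces_m, _ = generate_calcium(cfg, "mosaic")
        tab_c = score_population(traces_c)
        tab_m = score_population(traces_m)
        out = population_stats(tab_m, tab_c)
        assert out["primary"]["hyperactive_pct"] == pytest.approx(26.1, abs=3.0)
        assert out["dispersion_test"]["p_value"] < 0.01

    def test_too_few_neurons(self):
        from slowwave.calcium import TransientTable

        rows = [
            dict(roi_id=i, genotype_tag="unknown", n_events=1, frequency_hz=0.01,
                 per_min=0.6, active=True, hyperactive=False)
            for i in range(5)
        ]
        table = TransientTable(rows, {}, 600.0)
        with pytest.raises(ValueError, match="20 active"):
            population_stats(table)

    def test_hyperactive_monotone(self):
        cfg = SynthConfig(seed=8, duration_s=600.0)
        cfg.calcium.n_neurons = 40
        traces, gt = generate_calcium(cfg, "mosaic")
        table = score_population(traces)
        df = table.df.sort_values("per_min")
        flags = df["hyperactive"].to_numpy()
        # once flagged by rising measured rate, never un-flagged
        first_true = np.argmax(flags) if flags.any() else len(flags)
        assert not flags[:first_true].any()
        assert flags[first_true:].all() or not flags.any()


class TestFovActivity:
    def test_all_zero_stack(self):
        stack = np.zeros((50, 8, 8))
        out = fov_activity(stack=stack, fs=10.0, smooth_s=0.0)
        np.testing.assert_allclose(out.counts, 0.0)

    def test_flashing_roi_pixel_area(self, rng):
        stack = rng.normal(100.0, 0.5, size=(200, 10, 10))
        flash_frames = [50, 120]
        for f in flash_frames:
            stack[f, 2:5, 3:6] += 50.0  # 9-pixel ROI
        out = fov_activity(stack=stack, fs=10.0, smooth_s=0.0)
        for f in flash_frames:
            assert out.counts[f] == pytest.approx(9, abs=1)
        quiet = np.delete(out.counts, flash_frames)
        assert np.median(quiet) <= 1

    def test_traces_fallback_phase_locked_to_us(self):
        cfg = SynthConfig(seed=9, duration_s=300.0)
        cfg.calcium.n_neurons = 80
        cfg.calcium.median_hz = 0.05
        cfg.calcium.hyperactive_tail = 0.05
        cfg.calcium.p_us = 1.0
        traces, gt = generate_calcium(cfg, "control")
        out = fov_activity(traces=traces)
        t = np.arange(out.counts.size) / out.fs
        us_ind = gt.us.contains(t).astype(float)
        a = out.counts - out.counts.mean()
        b = us_ind - us_ind.mean()
        # peak cross-correlation at lag ~0 (within the kernel rise time)
        lags = np.arange(-50, 51)
        cc = [np.dot(a, np.roll(b, l)) for l in lags]
        assert abs(lags[int(np.argmax(cc))]) <= 5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fov_activity(stack=np.zeros((0, 4, 4)), fs=10.0)


class TestTransientsInUs:
    def test_full_coupling_100pct(self):
        cfg = SynthConfig(seed=10, duration_s=300.0)
        cfg.calcium.n_neurons = 50
        cfg.calcium.median_hz = 0.05
        cfg.calcium.hyperactive_tail = 0.05
        cfg.calcium.p_us = 1.0
        traces, gt = generate_calcium(cfg, "control")
        table = score_population(traces)
        res = transients_in_us(table, gt.us)
        assert res["percentage"] >= 95.0

    def test_zero_coupling_low(self):
        cfg = SynthConfig(seed=11, duration_s=300.0)
        cfg.calcium.n_neurons = 50
        cfg.calcium.median_hz = 0.05
        cfg.calcium.hyperactive_tail = 0.05
        cfg.calcium.p_us = 0.0
        traces, gt = generate_calcium(cfg, "control")
        table = score_population(traces)
        res = transients_in_us(table, gt.us)
        # uncoupled transients are placed in down states
        assert res["percentage"] < res["chance"]

    def test_no_transients_undefined(self):
        from slowwave.calcium import TransientTable
        from slowwave.core import IntervalSet

        table = TransientTable([], {}, 600.0)
        res = transients_in_us(table, IntervalSet([(0, 1)]))
        assert not res["defined"]

    def test_mosaic_less_synchronized(self):
        ordering = 0
        n = 10
        for seed in range(n):
            cfg = SynthConfig(seed=seed, duration_s=300.0)
            cfg.calcium.n_neurons = 60
            traces_c, gt_c = generate_calcium(cfg, "control")
            traces_m, gt_m = generate_calcium(cfg, "mosaic")
            pc = transients_in_us(score_population(traces_c), gt_c.us)["percentage"]
            pm = transients_in_us(score_population(traces_m), gt_m.us)["percentage"]
            if pm < pc:
                ordering += 1
        assert ordering >= n - 1
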