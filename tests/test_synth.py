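"""Generator-side checks: determinism, configured moments, ground truth."""

import numpy as np
import pytest
from scipy import stats as sps

from slowwave.core import IntervalSet
from slowwave.spectral import DELTA, band_rms
from slowwave.synth import (
    CONTROL,
    EEG_INJECTED,
    EMG,
    INJECTED,
    HYPERACTIVE_THRESHOLD_HZ,
    StateModel,
    SynthConfig,
    draw_lognormal_rates,
    generate_calcium,
    generate_eeg_emg,
    generate_lfp_pair,
    generate_state_sequence,
    hypersync_template,
    lognormal_sigma_for_tail,
)


class TestStateSequence:
    def test_duty_cycle_renewal_expectation(self):
        cfg = SynthConfig(seed=3, duration_s=600.0)
        us, ds = generate_state_sequence(cfg)
        duty = us.total_duration / 600.0
        model = cfg.state
        expected = model.expected_duty  # 0.5 / 0.8
        # renewal process: ~ duration/cycle_mean cycles contribute
        n_cycles = 600.0 / model.cycle_mean
        se = expected * (1 - expected) / np.sqrt(n_cycles)
        assert abs(duty - 0.625) < 3 * se

    def test_zero_variance_is_periodic(self, rng):
        model = StateModel(us_mean=0.5, us_shape=None, ds_mean=0.3, ds_shape=None)
        us, ds = generate_state_sequence(model, duration=60.0, rng=rng)
        np.testing.assert_allclose(us.durations[:-1], 0.5, atol=1e-12)
        np.testing.assert_allclose(np.diff(us.starts), 0.8, atol=1e-12)

    def test_deterministic_under_seed(self):
        cfg = SynthConfig(seed=11, duration_s=120.0)
        us1, _ = generate_state_sequence(cfg)
        us2, _ = generate_state_sequence(cfg)
        assert us1 == us2

    def test_alternation(self):
        cfg = SynthConfig(seed=5, duration_s=120.0)
        us, ds = generate_state_sequence(cfg)
        merged = np.sort(np.concatenate([us.starts, ds.starts]))
        assert np.all(np.diff(merged) > 0)

    def test_too_short_duration(self):
        with pytest.raises(ValueError, match="duration"):
            SynthConfig(seed=0, duration_s=5.0)


class TestLfpPair:
    def test_determinism(self, short_cfg):
        r1, _ = generate_lfp_pair(short_cfg, "mosaic")
        r2, _ = generate_lfp_pair(short_cfg, "mosaic")
        np.testing.assert_array_equal(r1[INJECTED].samples, r2[INJECTED].samples)

    def test_control_profile_has_no_events(self, short_cfg):
        _, gt = generate_lfp_pair(short_cfg, "control")
        assert len(gt.bursts) == 0
        assert len(gt.spikes) == 0

    def test_delta_rms_matches_component_oracle(self, short_cfg):
        rec, gt, comp = generate_lfp_pair(short_cfg, "control", return_components=True)
        measured = band_rms(rec[CONTROL], DELTA)
        # oracle: band RMS of the noiseless deflection + background sum
        from slowwave.core import TimeSeries

        noiseless = comp[CONTROL]["delta"] + comp[CONTROL]["background"]
        oracle = band_rms(TimeSeries(noiseless, fs=short_cfg.fs_lfp), DELTA)
        assert measured == pytest.approx(oracle, rel=0.10)

    def test_mosaic_reduces_delta_rms(self):
        # direction per configured deltas, checked over seeds
        worse = 0
        for seed in range(20):
            cfg = SynthConfig(seed=seed, duration_s=90.0)
            rec, _ = generate_lfp_pair(cfg, "mosaic")
            if band_rms(rec[INJECTED], DELTA) >= band_rms(rec[CONTROL], DELTA):
                worse += 1
        assert worse == 0

    def test_ground_truth_event_coupling_consistent(self):
        cfg = SynthConfig(seed=9, duration_s=300.0)
        cfg.hypersync.rate_per_hour = 0.0
        rec, gt = generate_lfp_pair(cfg, "mosaic")
        if len(gt.spikes):
            inside = gt.us.contains(gt.spikes.t_peak)
            np.testing.assert_array_equal(inside, gt.spike_coupled)

    def test_hypersync_template_calibration(self):
        tpl, pk = hypersync_template(1000.0, 0.49, 0.23)
        assert tpl.max() == pytest.approx(0.49, rel=1e-6)
        above = np.flatnonzero(tpl >= 0.25 * tpl.max())
        width = (above[-1] - above[0]) / 1000.0
        assert width == pytest.approx(0.23, abs=0.005)

    def test_interhemispheric_lag(self, short_cfg):
        _, gt = generate_lfp_pair(short_cfg, "control")
        assert gt.us.starts[0] >= 0.0


class TestEegEmg:
    def test_p_nrem_one_places_all_bursts_in_nrem(self):
        cfg = SynthConfig(seed=2, duration_s=3600.0)
        cfg.burst.p_nrem = 1.0
        cfg.mosaic.burst_rate_per_hour = 30.0
        rec, gt = generate_eeg_emg(cfg, "mosaic")
        assert len(gt.bursts) > 0
        inside = gt.hypnogram["NREM"].contains(gt.bursts.t_peak)
        assert inside.all()

    def test_occupancy_matches_renewal_expectation(self):
        cfg = SynthConfig(seed=4, duration_s=6 * 3600.0, fs_eeg=100.0)
        rec, gt = generate_eeg_emg(cfg, "control")
        expected = cfg.hypnogram.expected_occupancy()
        total = cfg.duration_s
        for stage in ("Wake", "NREM"):
            occ = gt.hypnogram[stage].total_duration / total
            # ~ 40 dwell cycles in 6 h: allow 3 SE of the renewal estimate
            n_bouts = max(len(gt.hypnogram[stage]), 1)
            se = expected[stage] / np.sqrt(n_bouts)
            assert abs(occ - expected[stage]) < 3 * se

    def test_determinism(self):
        cfg = SynthConfig(seed=8, duration_s=1200.0)
        r1, _ = generate_eeg_emg(cfg, "control")
        r2, _ = generate_eeg_emg(cfg, "control")
        np.testing.assert_array_equal(r1[EEG_INJECTED].samples, r2[EEG_INJECTED].samples)

    def test_emg_variance_high_in_wake_only(self):
        cfg = SynthConfig(seed=6, duration_s=3600.0)
        rec, gt = generate_eeg_emg(cfg, "control")
        emg = rec[EMG]
        t = emg.times
        wake = gt.hypnogram["Wake"].contains(t)
        v_wake = np.var(emg.samples[wake])
        v_sleep = np.var(emg.samples[~wake])
        assert v_wake > 20 * v_sleep


class TestCalcium:
    def test_sigma_closed_form(self):
        sigma = lognormal_sigma_for_tail(0.018, 0.078)
        z = sps.norm.ppf(1 - 0.078)
        assert sigma == pytest.approx(np.log(HYPERACTIVE_THRESHOLD_HZ / 0.018) / z)
        # round trip: P(rate > threshold) equals the requested tail
        tail = sps.lognorm(s=sigma, scale=0.018).sf(HYPERACTIVE_THRESHOLD_HZ)
        assert tail == pytest.approx(0.078, abs=1e-9)

    def test_stratified_rates_match_tail(self, rng):
        sigma = lognormal_sigma_for_tail(0.018, 0.078)
        rates = draw_lognormal_rates(rng, 300, 0.018, sigma, "stratified")
        frac = np.mean(rates > HYPERACTIVE_THRESHOLD_HZ)
        assert frac == pytest.approx(0.078, abs=0.005)

    def test_zero_rate_population_is_flat(self):
        cfg = SynthConfig(seed=1, duration_s=120.0)
        cfg.calcium.n_neurons = 5
        cfg.calcium.median_hz = 1e-9
        cfg.calcium.hyperactive_tail = 1e-9
        traces, gt = generate_calcium(cfg, "control")
        assert all(v.size == 0 for v in gt.transient_times)
        # traces are baseline + noise + drift only
        assert traces.F.std() < 0.1 * cfg.calcium.baseline_au

    def test_poisson_counts_gof(self):
        # chi-square goodness of fit of per-neuron counts vs Poisson(rate*T)
        cfg = SynthConfig(seed=10, duration_s=600.0)
        cfg.calcium.n_neurons = 100
        traces, gt = generate_calcium(cfg, "control", rate_sampling="iid")
        counts = np.array([v.size for v in gt.transient_times])
        lam = gt.true_rates_hz * 600.0
        # standardized residuals should follow ~N(0,1); chi^2 test
        z = (counts - lam) / np.sqrt(np.maximum(lam, 1e-12))
        stat = np.sum(z**2)
        p = 1 - sps.chi2.cdf(stat, df=100)
        assert p > 0.01

    def test_mosaic_dispersion_direction(self):
        rejected = 0
        for seed in range(10):
            cfg = SynthConfig(seed=seed, duration_s=120.0)
            cfg.calcium.n_neurons = 300
            _, gt_c = generate_calcium(cfg, "control")
            _, gt_m = generate_calcium(cfg, "mosaic")
            log_c = np.log(gt_c.true_rates_hz)
            log_m = np.log(gt_m.true_rates_hz)
            _, p = sps.bartlett(log_c, log_m)
            if p < 0.01 and np.var(log_m) > np.var(log_c):
                rejected += 1
        assert rejected == 10

    def test_determinism(self):
        cfg = SynthConfig(seed=3, duration_s=120.0)
        cfg.calcium.n_neurons = 10
        t1, _ = generate_calcium(cfg, "control")
        t2, _ = generate_calcium(cfg, "control")
        np.testing.assert_array_equal(t1.F, t2.F)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path, short_cfg):
        path = tmp_path / "cfg.yaml"
        short_cfg.to_yaml(path)
        back = SynthConfig.from_yaml(path)
        assert back.to_dict() == short_cfg.to_dict()

    def test_probability_validation(self):
        cfg_dict = SynthConfig(seed=0).to_dict()
        cfg_dict["hypersync"]["p_us"] = 1.5
        with pytest.raises(ValueError, match="p_us"):
            SynthConfig.from_dict(cfg_dict)

    def test_negative_rate_rejected(self):
        cfg_dict = SynthConfig(seed=0).to_dict()
        cfg_dict["burst"]["rate_per_hour"] = -1.0
        with pytest.raises(ValueError, match="rate_per_hour"):
            SynthConfig.from_dict(cfg_dict)
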