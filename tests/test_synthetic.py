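"""The waveform generator: determinism, calibration, amplitude model."""

import numpy as np
import pytest

import icpulse as ip
from icpulse.config import ConfigurationError


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"sampling_rate": 25.0},
        {"duration_s": -5.0},
        {"heart_rate": 30.0},
        {"heart_rate": 200.0},
        {"reactivity_coupling": 1.5},
        {"slow_wave_band": (0.05, 0.005)},
    ])
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ip.SimConfig(duration_s=kwargs.pop("duration_s", 60.0), **kwargs)

    def test_negative_icp_trajectory_rejected(self):
        cfg = ip.SimConfig(duration_s=60.0, icp_trajectory=[(0.0, 10.0), (60.0, -5.0)])
        abp = ip.generate_abp(cfg)
        with pytest.raises(ConfigurationError):
            ip.generate_icp(cfg, abp)


class TestDeterminismAndComposition:
    def test_same_seed_bit_identical(self):
        cfg = ip.SimConfig(duration_s=120.0, seed=5)
        a1, a2 = ip.generate_abp(cfg), ip.generate_abp(cfg)
        assert np.array_equal(a1.samples, a2.samples)
        i1, i2 = ip.generate_icp(cfg, a1), ip.generate_icp(cfg, a2)
        assert np.array_equal(i1.samples, i2.samples)

    def test_noise_free_abp_is_exact_pulse_train(self):
        cfg = ip.SimConfig(duration_s=60.0, noise_sd=0.0, slow_wave_amplitude=0.0,
                           heart_rate=60.0, abp_pulse_amplitude=10.0,
                           map_baseline=90.0, seed=0)
        abp = ip.generate_abp(cfg)
        t = np.arange(len(abp.samples)) / cfg.sampling_rate
        phase = 2 * np.pi * np.cumsum(np.full(len(t), 1.0)) / cfg.sampling_rate
        expected = 90.0 + 10.0 * np.sin(phase) + 3.0 * np.sin(2 * phase)
        assert np.allclose(abp.samples, expected, atol=1e-9)

    def test_default_mean_tracks_baseline(self):
        cfg = ip.SimConfig(duration_s=1800.0, seed=2)
        abp = ip.generate_abp(cfg)
        # oracle: brute-force mean of the generated array
        assert abs(float(abp.samples.mean()) - cfg.map_baseline) < 0.5

    def test_perfect_passive_transmission(self):
        cfg = ip.SimConfig(duration_s=600.0, reactivity_coupling=1.0,
                           noise_sd=0.0, icp_trajectory=15.0, seed=3)
        abp = ip.generate_abp(cfg)
        icp = ip.generate_icp(cfg, abp)
        summ = ip.summarize_recording(abp, icp)
        r = np.corrcoef(summ["mean_abp"], summ["mean_icp"])[0, 1]
        assert r > 0.999


class TestAmplitudeModel:
    def test_monotone_without_collapse(self):
        cfg = ip.SimConfig(duration_s=600.0, noise_sd=0.0,
                           icp_trajectory=[(0.0, 10.0), (600.0, 60.0)], seed=0)
        p = np.linspace(10, 60, 100)
        a = ip.amp_model(cfg, p)
        assert (np.diff(a) >= 0).all()

    def test_collapse_formula_and_breakpoint(self):
        cfg = ip.SimConfig(duration_s=600.0, map_baseline=95.0,
                           collapse_threshold=30.0, seed=0)
        p_col = 95.0 - 30.0
        # independent evaluation of the stated amplitude law
        a_below = cfg.amp_baseline * np.exp(
            cfg.elastance_coefficient * (p_col - cfg.reference_pressure))
        assert ip.amp_model(cfg, p_col) == pytest.approx(a_below)
        assert ip.amp_model(cfg, p_col + 10) == pytest.approx(
            max(a_below - cfg.collapse_slope * 10, 0.05))
        assert ip.amp_model(cfg, p_col + 10) < ip.amp_model(cfg, p_col)

    def test_collapse_visible_in_windows(self):
        cfg = ip.SimConfig(duration_s=1200.0, noise_sd=0.0, map_baseline=95.0,
                           collapse_threshold=30.0, slow_wave_amplitude=0.0,
                           icp_slow_amplitude=0.0,
                           icp_trajectory=[(0.0, 10.0), (1200.0, 85.0)], seed=0)
        abp = ip.generate_abp(cfg)
        icp = ip.generate_icp(cfg, abp)
        summ = ip.summarize_recording(abp, icp)
        amp = summ["amp"].to_numpy()
        assert amp[-1] < amp.max()

    def test_monotone_windows_when_no_collapse(self):
        cfg = ip.SimConfig(duration_s=1200.0, noise_sd=0.0, slow_wave_amplitude=0.0,
                           icp_slow_amplitude=0.0,
                           icp_trajectory=[(0.0, 10.0), (1200.0, 60.0)], seed=0)
        abp = ip.generate_abp(cfg)
        icp = ip.generate_icp(cfg, abp)
        amp = ip.summarize_recording(abp, icp)["amp"].to_numpy()
        assert (np.diff(amp) > -0.05).all()      # extraction tolerance only


class TestPbto2:
    def test_plateau_decline_and_floor(self):
        assert ip.generate_pbto2(np.array([90.0]))[0] == pytest.approx(27.0)
        assert ip.generate_pbto2(np.array([50.0]))[0] == pytest.approx(17.0)
        assert ip.generate_pbto2(np.array([-10.0]))[0] == 0.0

    def test_slope_half_mmhg_per_mmhg(self):
        cpp = np.array([70.0, 60.0, 40.0])
        p = ip.generate_pbto2(cpp)
        assert np.allclose(np.diff(p) / np.diff(cpp), 0.5)


class TestCohort:
    def test_single_phenotype_mix(self):
        pats = ip.generate_cohort(4, {"upper_breakpoint": 1.0}, seed=0,
                                  duration_s=120.0)
        assert all(p.truth.phenotype == "upper_breakpoint" for p in pats)

    def test_reference_cohort_counts(self):
        # 33 patients at the reference phenotype proportions -> 6/13/12/2
        pats = ip.generate_cohort(33, seed=0, duration_s=120.0)
        counts = {}
        for p in pats:
            counts[p.truth.phenotype] = counts.get(p.truth.phenotype, 0) + 1
        assert counts == {"upper_breakpoint": 6, "rightward_deflection": 13,
                          "monotonic_increase": 12, "monotonic_decrease": 2}

    def test_cohort_deterministic(self):
        a = ip.generate_cohort(3, seed=9, duration_s=120.0)
        b = ip.generate_cohort(3, seed=9, duration_s=120.0)
        for pa, pb in zip(a, b):
            assert pa.metadata == pb.metadata
            assert np.array_equal(pa.recordings["ICP"].samples,
                                  pb.recordings["ICP"].samples)

    def test_metadata_ranges(self):
        pats = ip.generate_cohort(20, seed=4, duration_s=120.0)
        for p in pats:
            assert 16.0 <= p.metadata["age"] <= 80.0
            assert p.metadata["sex"] in ("M", "F")
            assert 3 <= p.metadata["gcs"] <= 15

    def test_truth_label_consistent_with_collapse_setting(self):
        pats = ip.generate_cohort(12, seed=6, duration_s=120.0)
        for p in pats:
            has_collapse = p.config.collapse_threshold is not None
            assert has_collapse == (p.truth.phenotype == "upper_breakpoint")
            assert has_collapse == (p.truth.breakpoint_icp is not None)

    def test_rejects_bad_mix(self):
        with pytest.raises(ConfigurationError):
            ip.generate_cohort(4, {"upper_breakpoint": 0.5}, duration_s=60.0)
        with pytest.raises(ConfigurationError):
            ip.generate_cohort(0, duration_s=60.0)


class TestCouplingCalibration:
    def test_window_correlation_tracks_target(self):
        # coupling grid: recovered 10-s-mean correlation has the right sign
        # and magnitude within 0.2, averaged over 5-min windows
        for c in (-0.8, -0.4, 0.0, 0.4, 0.8):
            cfg = ip.SimConfig(duration_s=3600.0, reactivity_coupling=c,
                               icp_trajectory=15.0, noise_sd=0.5, seed=31)
            abp = ip.generate_abp(cfg)
            icp = ip.generate_icp(cfg, abp)
            summ = ip.summarize_recording(abp, icp)
            _, r = ip.moving_correlation(summ["mean_abp"].to_numpy(),
                                         summ["mean_icp"].to_numpy())
            mean_r = float(np.nanmean(r))
            assert abs(mean_r - c) <= 0.2
            if c != 0.0:
                assert np.sign(mean_r) == np.sign(c)
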