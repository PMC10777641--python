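import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecaploop import cloop, synth
from ecaploop.cloop import (CLSessionLog, ControllerParams, controller_update,
                            percent_of_threshold, run_session, summarize_session)
from ecaploop.exceptions import ConfigurationError, DegenerateSessionError


def _program(seconds=60.0, frequency=50.0):
    return synth.StimulusProgram(frequency, 200.0, seconds)


class TestControllerUpdate:
    def test_zero_error_unchanged(self):
        assert controller_update(0.0, 0.05, 0.02, 0.005, 0.1) == 0.05

    def test_large_error_saturates_at_step_cap(self):
        nxt = controller_update(100.0, 0.05, 0.02, 0.005, 0.1)
        assert nxt == pytest.approx(0.055)
        nxt = controller_update(-100.0, 0.05, 0.02, 0.005, 0.1)
        assert nxt == pytest.approx(0.045)

    def test_clamped_to_range(self):
        assert controller_update(100.0, 0.099, 1.0, 0.05, 0.1) == 0.1
        assert controller_update(-100.0, 0.001, 1.0, 0.05, 0.1) == 0.0

    def test_nonfinite_error_rejected(self):
        with pytest.raises(ValueError):
            controller_update(float("nan"), 0.05, 0.02, 0.005, 0.1)

    def test_geometric_convergence(self, quiet_gt):
        # constant plant: linear recurrence converges for 0 < gain_i*slope < 2
        slope, ecapt = quiet_gt.slope_mv_per_ma, quiet_gt.ecapt_ma
        target = 0.3
        fixed_point = ecapt + target / slope
        gain_i = 1.2 / slope
        current = ecapt  # start well away from the fixed point
        errs = []
        for _ in range(60):
            amp = slope * max(current - ecapt, 0.0)
            current = controller_update(target - amp, current, gain_i, 1.0, 1.0)
            errs.append(abs(current - fixed_point))
        assert errs[-1] < 1e-12
        tail = [e for e in errs if e > 1e-13]
        assert all(b < a for a, b in zip(tail, tail[1:]))  # monotone contraction

    @given(errors=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_safety_clamp_under_any_error_sequence(self, errors):
        current, cap = 0.05, 0.1
        for e in errors:
            current = controller_update(e, current, 0.5, 0.01, cap)
            assert 0.0 <= current <= cap


class TestRunSession:
    def test_record_and_update_counts(self, quiet_gt):
        log = run_session("CL", quiet_gt, _program(10.0), 0.2, seed=0)
        assert log.n_records == 500
        assert log.n_updates == 500
        assert log.n_updates / 10.0 == 50.0  # pulse-on-pulse at 50 Hz

    def test_ol_current_constant(self, sham_gt):
        log = run_session("OL", sham_gt, _program(5.0), 0.2, seed=1)
        assert np.all(log.current_ma == log.current_ma[0])
        assert log.n_updates == 0

    def test_cl_fixed_point_noiseless(self, quiet_gt):
        target = 0.25
        log = run_session("CL", quiet_gt, _program(5.0), target, seed=0,
                          params=ControllerParams(meas_noise_sd_mv=0.0),
                          initial_current_ma=quiet_gt.ecapt_ma)
        expected = quiet_gt.ecapt_ma + target / quiet_gt.slope_mv_per_ma
        assert log.current_ma[-1] == pytest.approx(expected, rel=1e-9)
        assert log.amplitude_mv[-1] == pytest.approx(target, rel=1e-9)

    def test_paired_variance_reduction(self, sham_gt):
        for seed in range(20):
            cl = run_session("CL", sham_gt, _program(30.0), 0.2, seed=seed)
            ol = run_session("OL", sham_gt, _program(30.0), 0.2, seed=seed)
            cov_cl = np.std(cl.amplitude_mv) / np.mean(cl.amplitude_mv)
            cov_ol = np.std(ol.amplitude_mv) / np.mean(ol.amplitude_mv)
            assert cov_cl < cov_ol

    def test_current_stays_in_range(self, sham_gt):
        log = run_session("CL", sham_gt, _program(30.0), 0.5, seed=3)
        assert np.all(log.current_ma >= 0.0)
        assert np.all(log.current_ma <= sham_gt.mt_ma)

    def test_unreachable_target_sets_saturation_flag(self, quiet_gt):
        params = ControllerParams(current_cap_ma=0.5 * quiet_gt.mt_ma)
        log = run_session("CL", quiet_gt, _program(5.0),
                          0.9 * quiet_gt.mt_amplitude_mv, params=params, seed=0)
        assert log.saturated

    def test_invalid_target_rejected(self, quiet_gt):
        with pytest.raises(ConfigurationError):
            run_session("CL", quiet_gt, _program(1.0),
                        2 * quiet_gt.mt_amplitude_mv, seed=0)

    def test_invalid_mode_rejected(self, quiet_gt):
        with pytest.raises(ConfigurationError):
            run_session("open", quiet_gt, _program(1.0), 0.2, seed=0)

    def test_deterministic(self, sham_gt):
        a = run_session("CL", sham_gt, _program(5.0), 0.2, seed=11)
        b = run_session("CL", sham_gt, _program(5.0), 0.2, seed=11)
        np.testing.assert_array_equal(a.amplitude_mv, b.amplitude_mv)
        np.testing.assert_array_equal(a.current_ma, b.current_ma)


def _constant_log(n=1000, amplitude=0.15, current=0.03):
    return CLSessionLog(
        mode="CL", target_amplitude_mv=amplitude,
        time_s=np.arange(n) / 50.0,
        current_ma=np.full(n, current),
        amplitude_mv=np.full(n, amplitude),
        mt_current_ma=0.06, mt_amplitude_mv=0.65, ecapt_ma=0.014,
        frequency_hz=50.0)


class TestSummarize:
    def test_constant_sequence(self):
        s = summarize_session(_constant_log())
        assert s.amplitude_sd_mv == pytest.approx(0.0, abs=1e-12)
        assert s.n_excluded == 0
        assert s.amplitude_mean_mv == pytest.approx(0.15)

    def test_injected_spikes_excluded_exactly(self):
        rng = np.random.default_rng(0)
        n = 10_000
        # bounded background so only the injected spikes can cross 3 SD
        amp = 0.15 + rng.uniform(-0.003, 0.003, n)
        spike_idx = rng.choice(n, size=10, replace=False)
        amp[spike_idx] = 0.15 + 10 * 0.003
        log = _constant_log(n)
        log.amplitude_mv = amp
        s = summarize_session(log)
        assert s.n_excluded == 10
        assert s.n_included == n - 10

    def test_histograms_integrate_to_included_count(self, sham_gt):
        log = run_session("CL", sham_gt, _program(30.0), 0.2, seed=2)
        s = summarize_session(log)
        assert s.amplitude_error_hist[0].sum() == s.n_included
        assert s.current_minus_ecapt_hist[0].sum() == s.n_included
        assert s.n_included + s.n_excluded == log.n_records

    def test_percent_of_mt(self):
        s = summarize_session(_constant_log(amplitude=0.1495))
        assert s.percent_of_mt == pytest.approx(100 * 0.1495 / 0.65)

    def test_empty_log_rejected(self):
        log = _constant_log(n=1)
        log.time_s = log.current_ma = log.amplitude_mv = np.empty(0)
        with pytest.raises(DegenerateSessionError):
            summarize_session(log)

    def test_animal2_replication_fixture(self):
        # target 0.1495 mV against a plant with MT amplitude 0.6507 mV at
        # 0.060 mA and extrapolated threshold 0.014 mA
        gt = synth.GroundTruth(slope_mv_per_ma=0.6507 / (0.060 - 0.014),
                               ecapt_ma=0.014, mt_ma=0.060, cv_m_per_s=15.0)
        log = run_session("CL", gt, _program(300.0), 0.1495, seed=7)
        s = summarize_session(log)
        assert abs(s.amplitude_mean_mv - 0.1495) / 0.1495 < 0.01


class TestPercentOfThreshold:
    def test_worked_example(self):
        # 0.034 mA at an MT of 0.049 mA -> 69% of MT; 1.4 x a 0.024 mA ECAPT
        assert round(percent_of_threshold(0.034, 0.049)) == 69
        assert round(0.034 / 0.024, 1) == 1.4

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            percent_of_threshold(0.1, 0.0)
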