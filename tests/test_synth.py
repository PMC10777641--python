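import numpy as np
import pytest
from scipy import stats

from ecaploop import features, synth
from ecaploop.exceptions import ConfigurationError, DesignError, WindowError


class TestRecruitment:
    def test_zero_at_threshold(self, quiet_gt):
        assert synth.recruitment_amplitude(quiet_gt.ecapt_ma, quiet_gt) == 0.0
        assert synth.recruitment_amplitude(quiet_gt.ecapt_ma, quiet_gt, gain=2.7) == 0.0

    def test_printed_sham_point(self):
        # 20.53 mV/mA above a 0.038 mA threshold, probed at the 0.082 mA MT
        gt = synth.GroundTruth(slope_mv_per_ma=20.53, ecapt_ma=0.038, mt_ma=0.082)
        amp = synth.recruitment_amplitude(0.082, gt, gain=1.0)
        assert amp == pytest.approx(20.53 * 0.044, rel=1e-12)
        assert amp == pytest.approx(0.90332, abs=5e-6)

    def test_linearity_doubling(self, quiet_gt):
        e = quiet_gt.ecapt_ma
        a1 = synth.recruitment_amplitude(e + 0.01, quiet_gt, gain=1.3)
        a2 = synth.recruitment_amplitude(e + 0.02, quiet_gt, gain=1.3)
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_below_threshold_zero(self, quiet_gt):
        assert synth.recruitment_amplitude(quiet_gt.ecapt_ma / 2, quiet_gt) == 0.0

    def test_negative_current_rejected(self, quiet_gt):
        with pytest.raises(ValueError):
            synth.recruitment_amplitude(-0.01, quiet_gt)

    def test_nonpositive_gain_rejected(self, quiet_gt):
        with pytest.raises(ValueError):
            synth.recruitment_amplitude(0.05, quiet_gt, gain=0.0)


class TestDistanceAttenuation:
    DISTANCES = np.array([4.0, 8.0, 12.0, 16.0])
    PROFILE = np.array([0.63, 0.20, 0.09, 0.08])

    def test_identity_at_reference(self, quiet_gt):
        assert synth.distance_attenuation(0.63, 4.0, quiet_gt) == pytest.approx(0.63)

    def test_default_calibration_is_least_squares(self, quiet_gt):
        # oracle: dense grid search over decay lengths
        def sse(length):
            pred = self.PROFILE[0] * np.exp(-(self.DISTANCES - 4.0) / length)
            return np.sum((pred - self.PROFILE) ** 2)

        grid = np.linspace(0.5, 50.0, 20_000)
        best = min(sse(g) for g in grid)
        assert sse(synth.default_decay_length()) <= best + 1e-10

    def test_monotone_nonincreasing(self, quiet_gt):
        d = np.linspace(4.0, 40.0, 200)
        a = synth.distance_attenuation(1.0, d, quiet_gt)
        assert np.all(np.diff(a) <= 0)

    def test_below_reference_rejected(self, quiet_gt):
        with pytest.raises(ValueError):
            synth.distance_attenuation(0.5, 3.0, quiet_gt)

    def test_nonpositive_decay_length_rejected(self):
        with pytest.raises(ConfigurationError):
            synth.GroundTruth(decay_length_mm=-1.0)


class TestGainTrace:
    def test_zero_volatility_constant(self):
        g = synth.gain_trace(10.0, 50.0, synth.GainProcess(volatility=0.0), seed=0)
        assert g.shape == (500,)
        assert np.all(g == 1.0)

    def test_mean_near_one_over_90000_pulses(self):
        g = synth.gain_trace(1800.0, 50.0, synth.GainProcess(), seed=0)
        assert g.size == 90_000
        assert abs(g.mean() - 1.0) < 0.02

    def test_strictly_positive(self):
        g = synth.gain_trace(60.0, 50.0, synth.GainProcess(volatility=0.5), seed=3)
        assert np.all(g > 0)

    def test_mean_reversion_autocorrelation(self):
        g = synth.gain_trace(600.0, 50.0, synth.GainProcess(), seed=1)
        ac1 = np.corrcoef(g[:-1], g[1:])[0, 1]
        ac100 = np.corrcoef(g[:-100], g[100:])[0, 1]
        assert ac1 > ac100

    def test_deterministic(self):
        a = synth.gain_trace(10.0, 50.0, seed=42)
        b = synth.gain_trace(10.0, 50.0, seed=42)
        np.testing.assert_array_equal(a, b)


class TestSynthSweep:
    def test_deterministic_bit_identical(self, sham_gt, geometry):
        prog = synth.StimulusProgram(2.0, 200.0, 2.0, 0.06)
        a = synth.synth_sweep(sham_gt, geometry, prog, seed=7)
        b = synth.synth_sweep(sham_gt, geometry, prog, seed=7)
        np.testing.assert_array_equal(a.sweeps, b.sweeps)

    def test_zero_current_noise_only(self, sham_gt, geometry):
        prog = synth.StimulusProgram(2.0, 200.0, 10.0, 0.0)
        rec = synth.synth_sweep(sham_gt, geometry, prog, seed=2)
        for ch, amp in rec.truth["amplitude_mv"].items():
            assert np.all(amp == 0.0)
        ch = geometry.measurement_channel
        # averaged trace is pure noise: no structure beyond the noise floor
        mean_trace = rec.sweeps[:, ch, :].mean(axis=0)
        assert np.std(mean_trace) < 3 * sham_gt.noise_sd_mv / np.sqrt(rec.n_pulses)

    def test_n1_shift_matches_kinematics(self, quiet_gt, geometry):
        prog = synth.StimulusProgram(2.0, 200.0, 1.0, 0.07)
        rec = synth.synth_sweep(quiet_gt, geometry, prog, seed=0)
        lat = rec.truth["n1_latency_ms"]
        expected = geometry.spacing_mm / quiet_gt.cv_m_per_s
        sample_ms = 1000.0 / rec.sample_rate
        for near, far in [(2, 1), (1, 0)]:
            assert lat[far] - lat[near] == pytest.approx(expected, abs=sample_ms)

    def test_sham_n1_latency_band(self, sham_gt, geometry):
        # 2 Hz sham fixture: detected N1 at the 4-mm channel in 1.373-1.433 ms
        prog = synth.StimulusProgram(2.0, 200.0, 5.0, 0.07)
        rec = synth.synth_sweep(sham_gt, geometry, prog, seed=1)
        table = features.extract_per_current(rec, geometry.measurement_channel)
        assert bool(table.detected.iloc[0])
        assert 1.373 <= table.n1_latency_ms.iloc[0] <= 1.433

    def test_recruitment_linearity_above_threshold(self, quiet_gt, io_geometry):
        prog = synth.io_sweep_program(quiet_gt, 2.0)
        rec = synth.synth_sweep(quiet_gt, io_geometry, prog, seed=0)
        cur, amp = rec.truth["currents_ma"], rec.truth["ref_amplitude_mv"]
        above = cur > quiet_gt.ecapt_ma
        reg = stats.linregress(cur[above], amp[above])
        assert reg.rvalue ** 2 == pytest.approx(1.0, abs=1e-12)

    def test_stim_channel_has_artifact(self, sham_gt, geometry):
        prog = synth.StimulusProgram(2.0, 200.0, 1.0, 0.0)
        rec = synth.synth_sweep(sham_gt, geometry, prog, seed=0)
        assert rec.artifact_channels == (geometry.stim_index,)
        assert np.abs(rec.sweeps[0, geometry.stim_index, 0]) > 10.0

    def test_slow_cv_window_error(self, geometry):
        gt = synth.sham_ground_truth(cv_m_per_s=1.0)  # N1 beyond the sweep
        prog = synth.StimulusProgram(2.0, 200.0, 1.0, 0.06)
        with pytest.raises(WindowError):
            synth.synth_sweep(gt, geometry, prog, seed=0, window_ms=5.0)


class TestSynthBehavior:
    def test_structure(self):
        tab = synth.synth_behavior(seed=0)
        assert set(tab.group) == set(synth.GROUPS)
        assert set(tab.timepoint) == set(synth.TIMEPOINTS)
        per_animal = tab.groupby("animal_id").size()
        assert (per_animal == len(synth.TIMEPOINTS)).all()

    def test_default_bs2_means_match_printed_values(self):
        cfg = synth.default_effects()
        printed = {"sham": 5.01, "SNI": 3.13, "sham SCS-OFF": 5.11,
                   "SNI SCS-OFF": 3.48, "sham SCS-ON": 5.23, "SNI SCS-ON": 3.76}
        for group, mean in printed.items():
            assert cfg.vf_mean[group]["BS2"] == pytest.approx(mean)
        # sample means track the configuration at large n
        tab = synth.synth_behavior(cfg, n_per_group=200, seed=0)
        bs2 = tab[tab.timepoint == "BS2"].groupby("group").vf_log_threshold.mean()
        for group, mean in printed.items():
            assert bs2[group] == pytest.approx(mean, abs=4 * 0.2 / np.sqrt(200))

    def test_domains(self):
        tab = synth.synth_behavior(seed=3)
        assert (tab.acetone_latency >= 0).all()
        cutoff = np.log10(synth.VON_FREY_CUTOFF_G * 10_000.0)
        assert (tab.vf_log_threshold <= cutoff + 1e-12).all()

    def test_too_few_animals_raises(self):
        with pytest.raises(DesignError):
            synth.synth_behavior(n_per_group=1, seed=0)

    def test_deterministic(self):
        a = synth.synth_behavior(seed=9)
        b = synth.synth_behavior(seed=9)
        assert a.equals(b)


class TestGeometryValidation:
    def test_defaults(self, geometry):
        assert geometry.n_contacts == 6
        assert geometry.spacing_mm == 4.0
        assert geometry.distance_mm(geometry.measurement_channel) == 4.0

    @pytest.mark.parametrize("kwargs", [
        dict(n_contacts=1), dict(spacing_mm=0.0), dict(stim_index=6),
        dict(stim_index=-1),
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigurationError):
            synth.LeadGeometry(**kwargs)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            synth.GroundTruth(ecapt_ma=0.08, mt_ma=0.05)
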