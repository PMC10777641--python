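import numpy as np
import pytest

from ecaploop import synth


@pytest.fixture(scope="session")
def sham_gt():
    """Sham parameterization at fixture noise (low gain volatility)."""
    return synth.sham_ground_truth(
        gain_process=synth.GainProcess(volatility=0.05), noise_sd_mv=0.01)


@pytest.fixture(scope="session")
def quiet_gt():
    """Noise-free, disturbance-free sham plant."""
    return synth.sham_ground_truth(
        gain_process=synth.GainProcess(volatility=0.0), noise_sd_mv=0.0)


@pytest.fixture(scope="session")
def geometry():
    return synth.LeadGeometry()


@pytest.fixture(scope="session")
def io_geometry():
    """Two-contact lead: just the stimulation contact and the 4-mm
    measurement channel — cheap IO-curve synthesis."""
    return synth.LeadGeometry(n_contacts=2, spacing_mm=4.0, stim_index=1,
                              contact_labels=("L1", "T13"))


def make_io_fit(gt, geometry, seed, frequency_hz=2.0, n_steps=20,
                pulses_per_step=3):
    """Full synthetic IO pipeline: sweep -> per-current features -> fit."""
    from ecaploop import features, iofit

    program = synth.io_sweep_program(gt, frequency_hz, n_steps, pulses_per_step)
    rec = synth.synth_sweep(gt, geometry=geometry, program=program, seed=seed)
    table = features.extract_per_current(rec, rec.geometry.measurement_channel)
    pts = table[table.detected & (table.current_ma <= gt.mt_ma)]
    curve = iofit.IOCurve(pts.current_ma.to_numpy(),
                          pts.amplitude_mv.to_numpy(), mt_ma=gt.mt_ma,
                          frequency_hz=frequency_hz, pulse_width_us=200.0)
    return iofit.fit_io(curve), table
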