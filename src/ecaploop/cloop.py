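"""Open-loop and closed-loop stimulation sessions against the synthetic plant.

The closed-loop controller is an integral law with a per-pulse step cap and
a hard current clamp: exactly one update per pulse ("pulse-on-pulse", 50
updates per second at 50 Hz). The commercial device's update law is
unpublished; this minimal controller reproduces its behavioral contract
(constant dorsal-column activation under slow gain disturbances) and sits
behind :func:`controller_update` so alternatives can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DegenerateSessionError
from .synth import GroundTruth, StimulusProgram, gain_trace, recruitment_amplitude

__all__ = ["ControllerParams", "CLSessionLog", "SessionSummary",
           "controller_update", "run_session", "summarize_session",
           "percent_of_threshold"]


@dataclass(frozen=True)
class ControllerParams:
    """Integral-controller configuration.

    ``gain_i`` is the integral gain in mA per mV of amplitude error; when
    None it is set at run time to ``0.5 / plant slope`` (loop gain 0.5,
    geometrically stable for loop gains in (0, 2)). Currents are clamped to
    ``[0, current_cap]``; the cap defaults to the motor-threshold current,
    the upper bound of the therapeutic window.
    """

    gain_i: float | None = None
    step_cap_ma: float = 0.005
    current_cap_ma: float | None = None
    meas_noise_sd_mv: float = 0.002

    def __post_init__(self) -> None:
        if self.step_cap_ma <= 0:
            raise ConfigurationError("step cap must be positive")
        if self.gain_i is not None and self.gain_i <= 0:
            raise ConfigurationError("integral gain must be positive")
        if self.meas_noise_sd_mv < 0:
            raise ConfigurationError("measurement noise SD must be non-negative")


def controller_update(error_mv: float, current_ma: float, gain_i: float,
                      step_cap_ma: float, current_cap_ma: float) -> float:
    """One integral update: ``I += clip(gain_i * error, +-step_cap)``,
    clamped to ``[0, cap]``. Deterministic."""
    if not np.isfinite(error_mv):
        raise ValueError("amplitude error must be finite")
    step = float(np.clip(gain_i * error_mv, -step_cap_ma, step_cap_ma))
    return float(np.clip(current_ma + step, 0.0, current_cap_ma))


@dataclass
class CLSessionLog:
    """Per-pulse trace of one stimulation session."""

    mode: str  # "OL" | "CL"
    target_amplitude_mv: float
    time_s: np.ndarray = field(repr=False)
    current_ma: np.ndarray = field(repr=False)
    amplitude_mv: np.ndarray = field(repr=False)
    mt_current_ma: float = 0.0
    mt_amplitude_mv: float = 0.0
    ecapt_ma: float = 0.0
    frequency_hz: float = 50.0
    n_updates: int = 0
    saturated: bool = False

    @property
    def n_records(self) -> int:
        return self.current_ma.size


@dataclass
class SessionSummary:
    """Post-hoc dosing-stability summary after 3-SD outlier exclusion."""

    mode: str
    target_amplitude_mv: float
    amplitude_mean_mv: float
    amplitude_sd_mv: float
    current_mean_ma: float
    current_sd_ma: float
    n_included: int
    n_excluded: int
    percent_of_mt: float
    amplitude_error_hist: tuple[np.ndarray, np.ndarray] = field(repr=False)
    current_minus_ecapt_hist: tuple[np.ndarray, np.ndarray] = field(repr=False)


def run_session(mode: str, gt: GroundTruth, program: StimulusProgram,
                target_mv: float, params: ControllerParams | None = None,
                seed: int | np.random.Generator = 0,
                initial_current_ma: float | None = None) -> CLSessionLog:
    """Simulate one stimulation session.

    Per pulse the plant produces a measured amplitude from the commanded
    current, the slow gain trace and measurement noise; in CL mode the
    controller then performs exactly one current update from the amplitude
    error before the next pulse, while OL mode holds the current fixed.
    """
    if mode not in ("OL", "CL"):
        raise ConfigurationError("mode must be 'OL' or 'CL'")
    params = params or ControllerParams()
    mt_amplitude = gt.mt_amplitude_mv
    if not 0 < target_mv < mt_amplitude:
        raise ConfigurationError(
            f"target must lie in (0, {mt_amplitude:.4g}) mV, the plant range up to MT")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = program.n_pulses
    gains = gain_trace(n / program.frequency_hz, program.frequency_hz,
                       gt.gain_process, rng)
    meas_noise = rng.normal(0.0, params.meas_noise_sd_mv, size=n)

    cap = params.current_cap_ma if params.current_cap_ma is not None else gt.mt_ma
    gain_i = params.gain_i if params.gain_i is not None else 0.5 / gt.slope_mv_per_ma
    # amplitude-matched starting point: the noise-free fixed point of the loop
    current = initial_current_ma if initial_current_ma is not None \
        else gt.ecapt_ma + target_mv / gt.slope_mv_per_ma
    current = float(np.clip(current, 0.0, cap))

    currents = np.empty(n)
    amplitudes = np.empty(n)
    n_updates = 0
    saturated = False
    slope, ecapt, step_cap = gt.slope_mv_per_ma, gt.ecapt_ma, params.step_cap_ma
    gains_l, noise_l = gains.tolist(), meas_noise.tolist()
    for p in range(n):
        currents[p] = current
        # inlined plant: recruitment_amplitude(current, gt, gain) + noise
        drive = current - ecapt
        amp = (gains_l[p] * slope * drive if drive > 0.0 else 0.0) + noise_l[p]
        amplitudes[p] = amp
        if mode == "CL":
            # inlined controller_update, one update per pulse
            step = gain_i * (target_mv - amp)
            if step > step_cap:
                step = step_cap
            elif step < -step_cap:
                step = -step_cap
            nxt = current + step
            if nxt <= 0.0:
                nxt = 0.0
            elif nxt >= cap:
                if current == cap and step > 0.0:
                    saturated = True
                nxt = cap
            current = nxt
            n_updates += 1

    return CLSessionLog(
        mode=mode, target_amplitude_mv=target_mv,
        time_s=np.arange(n) / program.frequency_hz,
        current_ma=currents, amplitude_mv=amplitudes,
        mt_current_ma=gt.mt_ma, mt_amplitude_mv=mt_amplitude,
        ecapt_ma=gt.ecapt_ma, frequency_hz=program.frequency_hz,
        n_updates=n_updates, saturated=saturated)


def percent_of_threshold(value: float, threshold: float) -> float:
    """Express a value as a percentage of a threshold (e.g. current as % of
    MT current, or mean amplitude as % of the amplitude at MT)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return 100.0 * value / threshold


def _inlier_mask(x: np.ndarray) -> np.ndarray:
    """Single-pass 3-SD rule: keep records within three SDs of the mean."""
    sd = np.std(x)
    return np.abs(x - np.mean(x)) <= 3.0 * sd


def summarize_session(log: CLSessionLog, bins: int = 60) -> SessionSummary:
    """Summarize a session after outlier exclusion.

    The 3-SD rule is evaluated independently on amplitude and current
    (single pass, not iterated); a record flagged on either axis is excluded
    from all summary statistics and histograms.
    """
    if log.n_records == 0:
        raise DegenerateSessionError("empty session log")
    keep = _inlier_mask(log.amplitude_mv) & _inlier_mask(log.current_ma)
    if not keep.any():
        raise DegenerateSessionError("all records excluded by the 3-SD rule")
    amp = log.amplitude_mv[keep]
    cur = log.current_ma[keep]

    amp_mean = float(np.mean(amp))
    return SessionSummary(
        mode=log.mode,
        target_amplitude_mv=log.target_amplitude_mv,
        amplitude_mean_mv=amp_mean,
        amplitude_sd_mv=float(np.std(amp)),
        current_mean_ma=float(np.mean(cur)),
        current_sd_ma=float(np.std(cur)),
        n_included=int(keep.sum()),
        n_excluded=int((~keep).sum()),
        percent_of_mt=percent_of_threshold(amp_mean, log.mt_amplitude_mv),
        amplitude_error_hist=np.histogram(amp - log.target_amplitude_mv, bins=bins),
        current_minus_ecapt_hist=np.histogram(cur - log.ecapt_ma, bins=bins),
    )
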