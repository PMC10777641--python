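"""Synthetic plant: multi-contact epidural recordings, gain disturbances and
behavioral tables with known ground truth.

Everything downstream of this module (feature extraction, IO fitting,
conduction-velocity estimation, closed-loop control, behavioral statistics)
is exercised against recordings produced here, so each generated quantity is
book-kept in :attr:`MultiChannelRecording.truth`.

Units: currents in mA, voltages in mV, in-sweep time in ms, distances in mm,
conduction velocity in m/s (numerically equal to mm/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import ConfigurationError, DesignError, WindowError

__all__ = [
    "LeadGeometry",
    "StimulusProgram",
    "GainProcess",
    "GroundTruth",
    "MultiChannelRecording",
    "recruitment_amplitude",
    "distance_attenuation",
    "default_decay_length",
    "gain_trace",
    "synth_sweep",
    "synth_behavior",
    "sham_ground_truth",
    "sni_ground_truth",
    "null_effects",
    "default_effects",
    "GROUPS",
    "TIMEPOINTS",
    "TIMEPOINT_MINUTES",
    "VON_FREY_CUTOFF_G",
    "REFERENCE_DISTANCE_MM",
]

# ---------------------------------------------------------------------------
# geometry / program / ground truth
# ---------------------------------------------------------------------------

#: Contact-to-contact distance of the reference recording channel (closest
#: antidromic neighbour of the stimulation contact).
REFERENCE_DISTANCE_MM = 4.0

# Contacts ordered caudal -> rostral; antidromic recording channels are the
# ones caudal to (index below) the stimulation contact.
_DEFAULT_LABELS = ("L3", "L2", "L1", "T13", "T12", "T11")


@dataclass(frozen=True)
class LeadGeometry:
    """Epidural lead layout: evenly spaced contacts along the cord."""

    n_contacts: int = 6
    spacing_mm: float = 4.0
    stim_index: int = 3
    contact_labels: tuple[str, ...] = _DEFAULT_LABELS

    def __post_init__(self) -> None:
        if self.n_contacts < 2:
            raise ConfigurationError("need at least 2 contacts")
        if self.spacing_mm <= 0:
            raise ConfigurationError("contact spacing must be positive")
        if not 0 <= self.stim_index < self.n_contacts:
            raise ConfigurationError("stim_index out of range")
        if len(self.contact_labels) != self.n_contacts:
            object.__setattr__(
                self, "contact_labels",
                tuple(f"C{i}" for i in range(self.n_contacts)),
            )

    def distance_mm(self, channel: int) -> float:
        """Distance from the stimulation contact to ``channel``."""
        return abs(channel - self.stim_index) * self.spacing_mm

    def antidromic_channels(self) -> list[int]:
        """Recording channels caudal to the stimulation contact, nearest first."""
        return list(range(self.stim_index - 1, -1, -1))

    @property
    def measurement_channel(self) -> int:
        """Closest antidromic channel (feedback channel for closed-loop runs)."""
        chans = self.antidromic_channels()
        if not chans:
            raise ConfigurationError("no antidromic channel caudal to stim contact")
        return chans[0]


@dataclass(frozen=True)
class StimulusProgram:
    """Stimulation schedule. ``current_ma`` is a constant or a per-pulse array."""

    frequency_hz: float = 50.0
    pulse_width_us: float = 200.0
    duration_s: float = 1.0
    current_ma: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0 or self.pulse_width_us <= 0:
            raise ConfigurationError("frequency and pulse width must be positive")
        cur = np.atleast_1d(np.asarray(self.current_ma, dtype=float))
        if np.any(cur < 0):
            raise ConfigurationError("currents must be non-negative")

    @property
    def n_pulses(self) -> int:
        cur = np.atleast_1d(np.asarray(self.current_ma, dtype=float))
        if cur.size > 1:
            return cur.size
        return int(round(self.duration_s * self.frequency_hz))

    def pulse_currents(self) -> np.ndarray:
        cur = np.atleast_1d(np.asarray(self.current_ma, dtype=float))
        if cur.size > 1:
            return cur.copy()
        return np.full(self.n_pulses, float(cur[0]))


def program_preset(frequency_hz: float, duration_s: float = 1.0,
                   current_ma: float | np.ndarray = 0.0) -> StimulusProgram:
    """The two supported presets: 2 Hz / 200 us and 50 Hz / 200 us."""
    if frequency_hz not in (2.0, 50.0):
        raise ConfigurationError("supported presets are 2 Hz and 50 Hz at 200 us")
    return StimulusProgram(frequency_hz, 200.0, duration_s, current_ma)


@dataclass(frozen=True)
class GainProcess:
    """Multiplicative slow gain disturbance (posture surrogate).

    Log-gain follows a stationary mean-reverting (Ornstein--Uhlenbeck style)
    process with stationary SD ``volatility`` and correlation time ``tau_s``;
    the exponentiated trace is bias-corrected so its mean is ``mean``.
    """

    mean: float = 1.0
    volatility: float = 0.15
    tau_s: float = 2.0

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.volatility < 0 or self.tau_s <= 0:
            raise ConfigurationError("invalid gain-process parameters")


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters of one synthetic animal."""

    slope_mv_per_ma: float = 20.53
    ecapt_ma: float = 0.038
    mt_ma: float = 0.082
    cv_m_per_s: float = 20.0
    decay_length_mm: float | None = None  # None -> least-squares default
    noise_sd_mv: float = 0.01
    onset_delay_ms: float = 1.2
    gain_process: GainProcess = field(default_factory=GainProcess)

    def __post_init__(self) -> None:
        if self.slope_mv_per_ma <= 0:
            raise ConfigurationError("recruitment slope must be positive")
        if not 0 < self.ecapt_ma < self.mt_ma:
            raise ConfigurationError("need 0 < ECAPT < MT")
        if self.cv_m_per_s <= 0:
            raise ConfigurationError("conduction velocity must be positive")
        if self.decay_length_mm is not None and self.decay_length_mm <= 0:
            raise ConfigurationError("decay length must be positive")
        if self.noise_sd_mv < 0:
            raise ConfigurationError("noise SD must be non-negative")

    @property
    def decay_length(self) -> float:
        return default_decay_length() if self.decay_length_mm is None else self.decay_length_mm

    @property
    def mt_amplitude_mv(self) -> float:
        """Plant ECAP amplitude at MT current, unit gain, reference distance."""
        return self.slope_mv_per_ma * (self.mt_ma - self.ecapt_ma)


def sham_ground_truth(frequency_hz: float = 2.0, **overrides) -> GroundTruth:
    """Sham-cohort parameterization (slope/thresholds from the group means)."""
    slope = 20.53 if frequency_hz == 2.0 else 21.03
    mt = 0.082 if frequency_hz == 2.0 else 0.084
    kw = dict(slope_mv_per_ma=slope, ecapt_ma=0.038, mt_ma=mt, cv_m_per_s=20.0)
    kw.update(overrides)
    return GroundTruth(**kw)


def sni_ground_truth(frequency_hz: float = 2.0, **overrides) -> GroundTruth:
    """Nerve-injured cohort parameterization: lower thresholds, slower CV."""
    slope = 23.56 if frequency_hz == 2.0 else 22.71
    mt = 0.065 if frequency_hz == 2.0 else 0.064
    kw = dict(slope_mv_per_ma=slope, ecapt_ma=0.026, mt_ma=mt, cv_m_per_s=15.0)
    kw.update(overrides)
    return GroundTruth(**kw)


# ---------------------------------------------------------------------------
# recruitment and spatial attenuation
# ---------------------------------------------------------------------------

def recruitment_amplitude(current_ma, gt: GroundTruth, gain: float = 1.0):
    """ECAP amplitude at the reference channel for a given current.

    Zero at or below threshold, then linear: ``gain * slope * (I - ECAPT)``.
    Accepts scalars or arrays.
    """
    current = np.asarray(current_ma, dtype=float)
    if np.any(current < 0):
        raise ValueError("current must be non-negative")
    if np.any(np.asarray(gain) <= 0):
        raise ValueError("gain must be positive")
    amp = gain * gt.slope_mv_per_ma * np.clip(current - gt.ecapt_ma, 0.0, None)
    return float(amp) if np.isscalar(current_ma) and np.isscalar(gain) else amp


# Reference spatial profile: amplitude vs distance at 4/8/12/16 mm from one
# worked propagation example; the default decay length is the least-squares
# calibration of a single exponential to these four points.
_ATTENUATION_DISTANCES_MM = np.array([4.0, 8.0, 12.0, 16.0])
_ATTENUATION_AMPLITUDES_MV = np.array([0.63, 0.20, 0.09, 0.08])


@lru_cache(maxsize=1)
def default_decay_length() -> float:
    """Least-squares single-exponential decay length (mm) for the reference
    four-point spatial profile, anchored at the 4-mm amplitude."""
    d, y = _ATTENUATION_DISTANCES_MM, _ATTENUATION_AMPLITUDES_MV

    def sse(length: float) -> float:
        pred = y[0] * np.exp(-(d - d[0]) / length)
        return float(np.sum((pred - y) ** 2))

    res = minimize_scalar(sse, bounds=(0.5, 100.0), method="bounded")
    return float(res.x)


def distance_attenuation(amplitude_at_ref_mv, distance_mm, gt: GroundTruth):
    """Attenuate a reference-channel amplitude out to ``distance_mm``.

    Single-exponential fall-off with the ground truth's decay length;
    identity at the 4-mm reference distance.
    """
    distance = np.asarray(distance_mm, dtype=float)
    if np.any(distance < REFERENCE_DISTANCE_MM):
        raise ValueError("distance must be at least the 4-mm reference distance")
    length = gt.decay_length
    if length <= 0:
        raise ConfigurationError("decay length must be positive")
    out = amplitude_at_ref_mv * np.exp(-(distance - REFERENCE_DISTANCE_MM) / length)
    return float(out) if np.isscalar(distance_mm) else out


# ---------------------------------------------------------------------------
# gain trace
# ---------------------------------------------------------------------------

def gain_trace(duration_s: float, frequency_hz: float,
               process: GainProcess | None = None,
               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Per-pulse multiplicative gain sequence.

    Exact discretization of a stationary OU log-gain process, exponentiated
    with a half-variance correction so the stationary mean equals
    ``process.mean``. Strictly positive, autocorrelated, seeded.
    """
    if duration_s <= 0 or frequency_hz <= 0:
        raise ConfigurationError("duration and frequency must be positive")
    process = process or GainProcess()
    n = int(round(duration_s * frequency_hz))
    if process.volatility == 0:
        return np.full(n, process.mean)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt = 1.0 / frequency_hz
    a = np.exp(-dt / process.tau_s)
    var = process.volatility ** 2
    x = np.empty(n)
    x[0] = rng.normal(0.0, np.sqrt(var))
    innov = rng.normal(0.0, np.sqrt(var * (1.0 - a * a)), size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + innov[i - 1]
    return process.mean * np.exp(x - var / 2.0)


# ---------------------------------------------------------------------------
# triphasic template and sweep synthesis
# ---------------------------------------------------------------------------

# Three smooth Gaussian lobes: positive P1, negative N1 (unit depth before
# scaling), positive P2. Lobe separation >> lobe SD keeps the N1 minimum at
# the nominal N1 time to sub-microsecond precision.
_LOBE_SD_MS = 0.20
_LOBE_SEP_MS = 0.55
_P1_FRACTION = 0.35
_P2_FRACTION = 0.85
#: half-width of the template support around N1, ms
TEMPLATE_HALF_SUPPORT_MS = _LOBE_SEP_MS + 4.0 * _LOBE_SD_MS


def triphasic_template(t_ms: np.ndarray, n1_time_ms: float) -> np.ndarray:
    """Unit triphasic waveform (P1 +, N1 -, P2 +) with N1 lobe at ``n1_time_ms``."""
    t = np.asarray(t_ms, dtype=float)

    def lobe(center: float) -> np.ndarray:
        return np.exp(-0.5 * ((t - center) / _LOBE_SD_MS) ** 2)

    return (_P1_FRACTION * lobe(n1_time_ms - _LOBE_SEP_MS)
            - lobe(n1_time_ms)
            + _P2_FRACTION * lobe(n1_time_ms + _LOBE_SEP_MS))


@lru_cache(maxsize=1)
def _template_calibration() -> dict:
    """Continuous-time extrema of the unit template (1e-4 ms grid)."""
    t = np.arange(-TEMPLATE_HALF_SUPPORT_MS, TEMPLATE_HALF_SUPPORT_MS, 1e-4)
    u = triphasic_template(t, 0.0)
    i_n1 = int(np.argmin(u))
    i_p2 = i_n1 + int(np.argmax(u[i_n1:]))
    i_p1 = int(np.argmax(u[:i_n1]))
    return {
        "n1_offset_ms": float(t[i_n1]),
        "p1_offset_ms": float(t[i_p1]),
        "p2_offset_ms": float(t[i_p2]),
        "unit_p2p": float(u[i_p2] - u[i_n1]),
    }


@dataclass
class MultiChannelRecording:
    """Stimulus-aligned per-pulse, per-channel voltage sweeps.

    ``sweeps`` has shape ``(n_pulses, n_channels, n_samples)`` in mV with
    sample 0 at stimulus onset. The stimulation channel carries the artifact
    transient and is listed in ``artifact_channels``.
    """

    sample_rate: float
    sweeps: np.ndarray
    geometry: LeadGeometry
    program: StimulusProgram
    currents_ma: np.ndarray
    artifact_channels: tuple[int, ...] = ()
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 3:
            raise ConfigurationError("sweeps must be (n_pulses, n_channels, n_samples)")
        if self.sweeps.shape[1] != self.geometry.n_contacts:
            raise ConfigurationError("channel count must match lead geometry")

    @property
    def n_pulses(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[2]

    @property
    def window_ms(self) -> float:
        return self.n_samples / self.sample_rate * 1000.0

    def time_ms(self) -> np.ndarray:
        """Per-sample time axis in ms relative to stimulus onset."""
        return np.arange(self.n_samples) / self.sample_rate * 1000.0


def _artifact(t_ms: np.ndarray) -> np.ndarray:
    """Large biphasic stimulation-artifact transient on the stim channel."""
    decay = np.exp(-t_ms / 0.15)
    return 60.0 * decay - 25.0 * np.exp(-t_ms / 0.35)


def synth_sweep(gt: GroundTruth, geometry: LeadGeometry | None = None,
                program: StimulusProgram | None = None,
                seed: int | np.random.Generator = 0,
                window_ms: float = 8.0,
                sample_rate: float = 30_000.0) -> MultiChannelRecording:
    """Synthesize a stimulus-aligned multi-channel recording.

    Each non-stimulation channel receives, per pulse, the triphasic template
    scaled by recruitment x spatial attenuation x slow gain, shifted by
    ``onset_delay + distance / CV``, plus white noise. The stimulation channel
    carries the artifact transient. All randomness derives from ``seed``.
    """
    geometry = geometry or LeadGeometry()
    program = program or StimulusProgram()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    currents = program.pulse_currents()
    n_pulses = currents.size
    n_samples = int(round(window_ms / 1000.0 * sample_rate))
    t = np.arange(n_samples) / sample_rate * 1000.0

    gains = gain_trace(n_pulses / program.frequency_hz, program.frequency_hz,
                       gt.gain_process, rng)
    ref_amp = recruitment_amplitude(currents, gt, 1.0) * gains  # per pulse, 4 mm

    cal = _template_calibration()
    sweeps = rng.normal(0.0, gt.noise_sd_mv, size=(n_pulses, geometry.n_contacts, n_samples))

    truth: dict = {
        "gains": gains,
        "currents_ma": currents.copy(),
        "ref_amplitude_mv": ref_amp.copy(),
        "n1_latency_ms": {},
        "amplitude_mv": {},
    }

    for ch in range(geometry.n_contacts):
        if ch == geometry.stim_index:
            sweeps[:, ch, :] += _artifact(t)[None, :]
            continue
        dist = geometry.distance_mm(ch)
        n1_time = gt.onset_delay_ms + dist / gt.cv_m_per_s
        if n1_time + TEMPLATE_HALF_SUPPORT_MS > window_ms:
            raise WindowError(
                f"N1 at {n1_time:.2f} ms on channel {ch} does not fit in a "
                f"{window_ms:.2f} ms sweep window")
        # same law as distance_attenuation, extended below the 4-mm reference
        # for geometries with sub-4-mm spacing
        amp = ref_amp * np.exp(-(dist - REFERENCE_DISTANCE_MM) / gt.decay_length)
        base = triphasic_template(t, n1_time) / cal["unit_p2p"]
        sweeps[:, ch, :] += amp[:, None] * base[None, :]
        truth["n1_latency_ms"][ch] = n1_time + cal["n1_offset_ms"]
        truth["amplitude_mv"][ch] = amp

    return MultiChannelRecording(
        sample_rate=sample_rate, sweeps=sweeps, geometry=geometry,
        program=program, currents_ma=currents,
        artifact_channels=(geometry.stim_index,), truth=truth)


def io_sweep_program(gt: GroundTruth, frequency_hz: float = 2.0,
                     n_steps: int = 20, pulses_per_step: int = 3,
                     start_fraction: float = 0.5,
                     stop_ma: float | None = None) -> StimulusProgram:
    """Stepwise ascending current schedule for IO-function collection:
    from ``start_fraction * ECAPT`` up to MT (or ``stop_ma``)."""
    stop = gt.mt_ma if stop_ma is None else stop_ma
    steps = np.linspace(start_fraction * gt.ecapt_ma, stop, n_steps)
    currents = np.repeat(steps, pulses_per_step)
    return StimulusProgram(frequency_hz, 200.0, currents.size / frequency_hz, currents)


# ---------------------------------------------------------------------------
# behavior tables
# ---------------------------------------------------------------------------

GROUPS = ("sham", "sham SCS-OFF", "sham SCS-ON", "SNI", "SNI SCS-OFF", "SNI SCS-ON")
TIMEPOINTS = ("BS1", "BS2", "0", "15", "30", "45", "60")
TIMEPOINT_MINUTES = {"0": 0.0, "15": 15.0, "30": 30.0, "45": 45.0, "60": 60.0}

VON_FREY_CUTOFF_G = 26.0
_LOG_CUTOFF = float(np.log10(VON_FREY_CUTOFF_G * 10_000.0))


@dataclass(frozen=True)
class EffectConfig:
    """Per group x timepoint generative means/SDs for both endpoints.

    ``vf_mean``/``ac_mean`` map group -> timepoint -> mean of the log10 von
    Frey threshold / acetone latency (s). SDs may be scalars or nested maps.
    """

    vf_mean: Mapping[str, Mapping[str, float]]
    ac_mean: Mapping[str, Mapping[str, float]]
    vf_sd: float | Mapping[str, Mapping[str, float]] = 0.2
    ac_sd: float | Mapping[str, Mapping[str, float]] = 2.5

    def _sd(self, which, group, tp) -> float:
        sd = self.vf_sd if which == "vf" else self.ac_sd
        if isinstance(sd, Mapping):
            return float(sd[group][tp])
        return float(sd)


def _flat(groups, timepoints, value) -> dict:
    return {g: {tp: value for tp in timepoints} for g in groups}


def null_effects(vf_mean: float = 4.0, ac_mean: float = 10.0,
                 vf_sd: float = 0.2, ac_sd: float = 2.5) -> EffectConfig:
    """All groups and timepoints drawn from one distribution (null generator)."""
    return EffectConfig(_flat(GROUPS, TIMEPOINTS, vf_mean),
                        _flat(GROUPS, TIMEPOINTS, ac_mean), vf_sd, ac_sd)


def default_effects() -> EffectConfig:
    """Hypersensitivity-with-rescue configuration.

    BS2 von Frey means match the printed group means (5.01 / 3.13 / 5.11 /
    3.48 / 5.23 / 3.76 log units); injured groups drop after induction and
    the stimulated injured group partially recovers at 15/30 min.
    """
    vf = {
        "sham":        dict(BS1=5.01, BS2=5.01, **{"0": 5.00, "15": 5.00, "30": 5.00, "45": 5.00, "60": 5.00}),
        "sham SCS-OFF": dict(BS1=5.10, BS2=5.11, **{"0": 5.10, "15": 5.10, "30": 5.10, "45": 5.10, "60": 5.10}),
        "sham SCS-ON": dict(BS1=5.20, BS2=5.23, **{"0": 5.20, "15": 5.20, "30": 5.20, "45": 5.20, "60": 5.20}),
        "SNI":         dict(BS1=5.00, BS2=3.13, **{"0": 3.10, "15": 3.10, "30": 3.10, "45": 3.10, "60": 3.10}),
        "SNI SCS-OFF": dict(BS1=5.10, BS2=3.48, **{"0": 3.40, "15": 3.40, "30": 3.40, "45": 3.40, "60": 3.40}),
        "SNI SCS-ON":  dict(BS1=5.20, BS2=3.76, **{"0": 3.70, "15": 4.90, "30": 4.80, "45": 4.10, "60": 3.90}),
    }
    ac = {
        "sham":        dict(BS1=0.20, BS2=0.18, **{"0": 0.20, "15": 0.20, "30": 0.20, "45": 0.20, "60": 0.20}),
        "sham SCS-OFF": dict(BS1=0.05, BS2=0.01, **{"0": 0.05, "15": 0.05, "30": 0.05, "45": 0.05, "60": 0.05}),
        "sham SCS-ON": dict(BS1=0.05, BS2=0.00, **{"0": 0.05, "15": 0.05, "30": 0.05, "45": 0.05, "60": 0.05}),
        "SNI":         dict(BS1=0.20, BS2=26.07, **{"0": 25.0, "15": 25.0, "30": 25.0, "45": 25.0, "60": 25.0}),
        "SNI SCS-OFF": dict(BS1=0.20, BS2=19.66, **{"0": 19.0, "15": 19.0, "30": 19.0, "45": 19.0, "60": 19.0}),
        "SNI SCS-ON":  dict(BS1=0.20, BS2=19.82, **{"0": 19.0, "15": 6.0, "30": 7.0, "45": 15.0, "60": 17.0}),
    }
    return EffectConfig(vf, ac, vf_sd=0.2, ac_sd=2.5)


def synth_behavior(effects: EffectConfig | None = None,
                   n_per_group: int | Mapping[str, int] = 6,
                   seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Generate a behavior table: one row per animal x timepoint.

    Columns: ``animal_id, group, timepoint, vf_log_threshold, acetone_latency``.
    Log von Frey draws are clipped at the 26 g cutoff (log10 scale); acetone
    latencies are clipped at 0 s.
    """
    effects = effects or default_effects()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rows = []
    for group in GROUPS:
        n = n_per_group[group] if isinstance(n_per_group, Mapping) else int(n_per_group)
        if n < 2:
            raise DesignError("need at least 2 animals per group for downstream ANOVA")
        for a in range(n):
            animal = f"{group.replace(' ', '_')}-{a + 1:02d}"
            for tp in TIMEPOINTS:
                vf = rng.normal(effects.vf_mean[group][tp], effects._sd("vf", group, tp))
                ac = rng.normal(effects.ac_mean[group][tp], effects._sd("ac", group, tp))
                rows.append((animal, group, tp,
                             min(vf, _LOG_CUTOFF), max(ac, 0.0)))
    return pd.DataFrame(rows, columns=["animal_id", "group", "timepoint",
                                       "vf_log_threshold", "acetone_latency"])
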