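"""Triphasic ECAP feature extraction from stimulus-aligned sweeps.

The N1 trough is the anchor landmark: it is located first (most negative
sample in the search window on a lightly smoothed trace), then P1 and P2 are
the positive maxima flanking it. Amplitude is the absolute N1-to-P2
difference. The noise floor is the raw-trace SD over the final 20% of the
sweep, which lies beyond the template support for all supported geometries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .exceptions import WindowError
from .synth import MultiChannelRecording

__all__ = ["ECAPFeatures", "extract_features", "extract_per_current",
           "is_detectable", "DEFAULT_BLANKING_MS", "DEFAULT_DETECTION_K"]

DEFAULT_BLANKING_MS = 0.5
DEFAULT_DETECTION_K = 3.0
#: Savitzky-Golay pre-smoothing (quadratic); denoises peak picking (per-pulse
#: false-detection rate < 1% at k = 3 on white noise) while attenuating the
#: template extrema by ~1%
_SMOOTH_WINDOW = 13
#: fraction of the sweep tail used to estimate the noise floor
_NOISE_TAIL_FRACTION = 0.2
#: minimum usable search-window length, ms (template support is ~2.7 ms)
_MIN_WINDOW_MS = 1.0


@dataclass
class ECAPFeatures:
    """P1/N1/P2 landmarks and amplitude for one sweep (or averaged sweep)."""

    p1_latency_ms: float
    n1_latency_ms: float
    p2_latency_ms: float
    p1_value_mv: float
    n1_value_mv: float
    p2_value_mv: float
    amplitude_mv: float
    noise_sd_mv: float
    detected: bool

    def latency_order_ok(self) -> bool:
        lats = (self.p1_latency_ms, self.n1_latency_ms, self.p2_latency_ms)
        if any(math.isnan(v) for v in lats):
            return False
        return lats[0] < lats[1] < lats[2]


def _undetected(noise_sd: float) -> ECAPFeatures:
    nan = float("nan")
    return ECAPFeatures(nan, nan, nan, nan, nan, nan, 0.0, noise_sd, False)


def is_detectable(f: ECAPFeatures, k: float = DEFAULT_DETECTION_K) -> bool:
    """True iff the amplitude clears ``k`` noise SDs and P1 < N1 < P2 holds."""
    if f.noise_sd_mv < 0:
        raise ValueError("noise SD must be non-negative")
    return bool(f.amplitude_mv > k * f.noise_sd_mv and f.latency_order_ok())


def _features_from_trace(trace: np.ndarray, sample_rate: float,
                         blanking_ms: float, window_ms: tuple[float, float],
                         k: float) -> ECAPFeatures:
    n = trace.size
    dt_ms = 1000.0 / sample_rate
    sweep_ms = n * dt_ms

    lo = max(window_ms[0], blanking_ms)
    hi = min(window_ms[1], sweep_ms)
    if hi - lo < _MIN_WINDOW_MS:
        raise WindowError(
            f"search window [{lo:.2f}, {hi:.2f}] ms is shorter than the "
            f"{_MIN_WINDOW_MS} ms minimum")
    i0 = int(np.ceil(lo / dt_ms))
    i1 = int(np.floor(hi / dt_ms))

    tail = trace[int(n * (1.0 - _NOISE_TAIL_FRACTION)):]
    noise_sd = float(np.std(tail))

    if np.ptp(trace) == 0.0:  # all-flat trace
        return _undetected(noise_sd)

    smooth = savgol_filter(trace, _SMOOTH_WINDOW, 2) if n >= _SMOOTH_WINDOW else trace
    seg = smooth[i0:i1]
    i_n1 = int(np.argmin(seg))  # argmin: earliest sample on plateaus
    if i_n1 == 0 or i_n1 == seg.size - 1:
        return _undetected(noise_sd)  # trough on window edge: no flanking peaks
    i_p1 = int(np.argmax(seg[:i_n1]))
    i_p2 = i_n1 + int(np.argmax(seg[i_n1:]))

    p1_v, n1_v, p2_v = float(seg[i_p1]), float(seg[i_n1]), float(seg[i_p2])
    amplitude = abs(p2_v - n1_v)
    f = ECAPFeatures(
        p1_latency_ms=(i0 + i_p1) * dt_ms,
        n1_latency_ms=(i0 + i_n1) * dt_ms,
        p2_latency_ms=(i0 + i_p2) * dt_ms,
        p1_value_mv=p1_v, n1_value_mv=n1_v, p2_value_mv=p2_v,
        amplitude_mv=amplitude, noise_sd_mv=noise_sd, detected=False)
    f.detected = is_detectable(f, k)
    return f


def extract_features(recording: MultiChannelRecording, channel: int,
                     blanking_ms: float = DEFAULT_BLANKING_MS,
                     search_window_ms: tuple[float, float] | None = None,
                     k: float = DEFAULT_DETECTION_K) -> list[ECAPFeatures]:
    """Extract one :class:`ECAPFeatures` per pulse for ``channel``.

    ``channel`` must not be the stimulation channel. The search window
    defaults to blanking-to-5-ms (clipped to the sweep).
    """
    if channel in recording.artifact_channels or channel == recording.geometry.stim_index:
        raise ValueError("cannot extract ECAP features from the stimulation channel")
    if not 0 <= channel < recording.geometry.n_contacts:
        raise ValueError("channel index out of range")
    window = search_window_ms or (blanking_ms, min(5.0, recording.window_ms))
    return [
        _features_from_trace(recording.sweeps[p, channel], recording.sample_rate,
                             blanking_ms, window, k)
        for p in range(recording.n_pulses)
    ]


def extract_per_current(recording: MultiChannelRecording, channel: int,
                        blanking_ms: float = DEFAULT_BLANKING_MS,
                        search_window_ms: tuple[float, float] | None = None,
                        k: float = DEFAULT_DETECTION_K) -> pd.DataFrame:
    """Average sweeps within each distinct current step, then extract features.

    Mirrors offline IO-function analysis where repeated pulses at one current
    are averaged before reading off the ECAP. Returns one row per current,
    ascending, with the feature fields as columns.
    """
    if channel in recording.artifact_channels or channel == recording.geometry.stim_index:
        raise ValueError("cannot extract ECAP features from the stimulation channel")
    window = search_window_ms or (blanking_ms, min(5.0, recording.window_ms))
    rows = []
    for current in np.unique(recording.currents_ma):
        mask = recording.currents_ma == current
        mean_trace = recording.sweeps[mask, channel, :].mean(axis=0)
        f = _features_from_trace(mean_trace, recording.sample_rate,
                                 blanking_ms, window, k)
        rows.append({"current_ma": float(current), "n_pulses": int(mask.sum()),
                     **f.__dict__})
    return pd.DataFrame(rows).sort_values("current_ma", ignore_index=True)
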