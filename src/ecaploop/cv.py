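"""Conduction-velocity estimation from N1 latencies across contacts.

Latency grows linearly with distance from the stimulation contact; the
velocity is the reciprocal of the slope of an ordinary least-squares fit of
N1 latency (ms) on distance (mm), so any fixed activation/utilization delay
enters only the intercept and cancels. mm/ms is numerically equal to m/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, PropagationDirectionError
from .features import ECAPFeatures
from .synth import LeadGeometry

__all__ = ["CVEstimate", "estimate_cv"]


@dataclass
class CVEstimate:
    velocity_m_per_s: float
    latency_points: list[tuple[float, float]]  # (distance mm, N1 latency ms)
    residual_rms_ms: float


def _mean_latency(value) -> float | None:
    """Per-channel N1 latency: a float, one ECAPFeatures, or an iterable of
    per-pulse ECAPFeatures (detected ones are averaged)."""
    if isinstance(value, ECAPFeatures):
        return value.n1_latency_ms if value.detected else None
    if isinstance(value, (int, float, np.floating)):
        return float(value)
    lats = [f.n1_latency_ms for f in value if f.detected]
    return float(np.mean(lats)) if lats else None


def estimate_cv(features_by_channel: Mapping[int, ECAPFeatures | float | Iterable[ECAPFeatures]],
                geometry: LeadGeometry) -> CVEstimate:
    """Estimate conduction velocity from per-channel N1 latencies.

    ``features_by_channel`` maps recording-channel index to per-pulse
    features (averaged per channel before the fit), a single feature set, or
    a latency in ms. At least two channels with detected ECAPs are required.
    """
    points = []
    for channel, value in features_by_channel.items():
        lat = _mean_latency(value)
        if lat is not None:
            points.append((geometry.distance_mm(channel), lat))
    if len(points) < 2:
        raise InsufficientDataError("need detected ECAPs on at least 2 channels")
    points.sort()
    dist = np.array([p[0] for p in points])
    lat = np.array([p[1] for p in points])

    reg = stats.linregress(dist, lat)
    if reg.slope <= 0:
        raise PropagationDirectionError(
            "N1 latency does not increase with distance from the stimulation contact")
    resid = lat - (reg.intercept + reg.slope * dist)
    return CVEstimate(
        velocity_m_per_s=float(1.0 / reg.slope),
        latency_points=points,
        residual_rms_ms=float(np.sqrt(np.mean(resid ** 2))),
    )
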