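"""Input-output (recruitment) function fitting and threshold estimation.

The fitting pipeline mirrors the offline analysis it emulates: raw
(current, amplitude) points from the first detectable ECAP up to motor
threshold are interpolated with a cubic smoothing spline (normalized
smoothing parameter, default 0.95), an ordinary least-squares line is fit to
the densely interpolated points, and the x-intercept of that line is the
extrapolated ECAP threshold. Currents are then rescaled so 0 maps to the
extrapolated threshold and 1 to motor threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .exceptions import (DegenerateRecruitmentError, InconsistentThresholdWarning,
                         InsufficientDataError, NotDetectedError,
                         UndefinedRatioError)
from .features import DEFAULT_DETECTION_K, ECAPFeatures, is_detectable

__all__ = ["IOCurve", "IOFit", "fit_io", "observed_ecapt", "mt_ecapt_ratio",
           "DEFAULT_SMOOTHING", "DEFAULT_INTERP_POINTS"]

DEFAULT_SMOOTHING = 0.95
DEFAULT_INTERP_POINTS = 200
# smoothing-spline points minimum imposed by the spline routine; smaller
# curves fall back to piecewise-linear interpolation for the dense stage
_MIN_SPLINE_POINTS = 5


@dataclass(frozen=True)
class IOCurve:
    """Ordered (current, amplitude) observations up to motor threshold."""

    currents_ma: np.ndarray
    amplitudes_mv: np.ndarray
    mt_ma: float
    frequency_hz: float | None = None
    pulse_width_us: float | None = None

    def __post_init__(self) -> None:
        cur = np.asarray(self.currents_ma, dtype=float)
        amp = np.asarray(self.amplitudes_mv, dtype=float)
        object.__setattr__(self, "currents_ma", cur)
        object.__setattr__(self, "amplitudes_mv", amp)
        if cur.shape != amp.shape or cur.ndim != 1:
            raise InsufficientDataError("currents and amplitudes must be 1-D and equal length")
        if cur.size < 3:
            raise InsufficientDataError("need at least 3 IO points for fitting")
        if np.any(np.diff(cur) <= 0):
            raise InsufficientDataError("currents must be strictly increasing")
        if np.any(cur > self.mt_ma + 1e-12):
            raise InsufficientDataError("IO points must not exceed motor threshold")


@dataclass
class IOFit:
    """Result of the spline + linear-regression IO fit."""

    slope_mv_per_ma: float
    ecapt_extrapolated_ma: float
    r_squared: float
    mt_ma: float
    smoothing: float
    interp_currents_ma: np.ndarray = field(repr=False)
    interp_amplitudes_mv: np.ndarray = field(repr=False)
    normalized_currents: np.ndarray = field(repr=False)

    def scale_current(self, current_ma):
        """Map current to the [0, 1] therapeutic-window scale
        (0 = extrapolated ECAPT, 1 = MT)."""
        span = self.mt_ma - self.ecapt_extrapolated_ma
        return (np.asarray(current_ma, dtype=float) - self.ecapt_extrapolated_ma) / span


def _smoothing_to_lam(smoothing: float, currents: np.ndarray) -> float:
    """Map a csaps-style p in (0, 1] to the roughness weight of the
    penalized least-squares spline: lam = (1 - p) / p scaled by the cube of
    the mean current spacing, making the trade-off grid-scale invariant.
    p = 0.95 therefore means strong fidelity with mild smoothing."""
    if not 0 < smoothing <= 1:
        raise ValueError("smoothing parameter must be in (0, 1]")
    h = float(np.mean(np.diff(currents)))
    return (1.0 - smoothing) / smoothing * h ** 3


def fit_io(curve: IOCurve, smoothing: float = DEFAULT_SMOOTHING,
           n_interp: int = DEFAULT_INTERP_POINTS) -> IOFit:
    """Fit the IO function and extrapolate the ECAP threshold.

    Raises :class:`DegenerateRecruitmentError` for non-positive slopes and
    warns (:class:`InconsistentThresholdWarning`) when the x-intercept lands
    at or above motor threshold.
    """
    x, y = curve.currents_ma, curve.amplitudes_mv
    dense_x = np.linspace(x[0], x[-1], n_interp)
    if x.size >= _MIN_SPLINE_POINTS:
        spline = make_smoothing_spline(x, y, lam=_smoothing_to_lam(smoothing, x))
        dense_y = spline(dense_x)
    else:
        dense_y = np.interp(dense_x, x, y)

    reg = stats.linregress(dense_x, dense_y)
    slope = float(reg.slope)
    if slope <= 0:
        raise DegenerateRecruitmentError(f"non-positive IO slope ({slope:.4g} mV/mA)")
    ecapt = float(-reg.intercept / slope)
    if ecapt >= curve.mt_ma:
        warnings.warn("extrapolated ECAPT is not below motor threshold",
                      InconsistentThresholdWarning, stacklevel=2)

    fit = IOFit(
        slope_mv_per_ma=slope,
        ecapt_extrapolated_ma=ecapt,
        r_squared=float(reg.rvalue ** 2),
        mt_ma=float(curve.mt_ma),
        smoothing=smoothing,
        interp_currents_ma=dense_x,
        interp_amplitudes_mv=np.asarray(dense_y, dtype=float),
        normalized_currents=np.empty(0),
    )
    fit.normalized_currents = fit.scale_current(dense_x)
    return fit


def observed_ecapt(currents_ma: Sequence[float],
                   features: Sequence[ECAPFeatures],
                   k: float = DEFAULT_DETECTION_K) -> float:
    """Smallest current in an ascending sweep with a detectable ECAP.

    This is the online ("visually observed") threshold surrogate used to set
    closed-loop stimulation intensity.
    """
    currents = np.asarray(currents_ma, dtype=float)
    if len(features) != currents.size:
        raise InsufficientDataError("one feature set per current required")
    if np.any(np.diff(currents) <= 0):
        raise InsufficientDataError("currents must be strictly ascending")
    for current, f in zip(currents, features):
        if is_detectable(f, k):
            return float(current)
    raise NotDetectedError("no detectable ECAP in the current sweep")


def mt_ecapt_ratio(mt_ma: float, ecapt_ma: float) -> float:
    """Relative current needed for a motor response: MT / ECAPT."""
    if ecapt_ma <= 0:
        raise UndefinedRatioError("ECAP threshold must be positive")
    return mt_ma / ecapt_ma
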