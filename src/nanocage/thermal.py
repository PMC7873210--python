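"""Empirical melting / aggregation temperature callers and initial rates.

Two callers mirror how thermal-ramp data of assembled nanomaterials and
their free components are reduced in practice:

* ``tm_by_derivative`` — quadratic interpolation of the trace onto a fine
  temperature grid, then the temperature of the derivative extremum in the
  transition direction (used for CD melts and activity data with a clear
  sigmoidal transition).
* ``t_by_threshold`` — intersection of a cubic interpolation of the trace
  with a threshold line whose slope equals the average baseline drift and
  whose intercept is a fixed fraction of a typical endpoint magnitude (used
  for SLS aggregation onsets and nanoDSF barycentric-mean shifts).

Assay presets carry the conventional endpoint constants: an SLS endpoint of
60,000 counts over background with a 20% intercept, nanoDSF endpoint shifts
of -4.5 nm at 50% or -14.2 nm at 20%.

``initial_rate`` computes relative initial enzyme velocities from
absorbance time traces by ordinary least squares over a fixed window
(100-200 s by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import interp1d
from scipy.stats import linregress

__all__ = [
    "MeltCurve",
    "ThresholdSpec",
    "THRESHOLD_PRESETS",
    "NoTransitionError",
    "tm_by_derivative",
    "t_by_threshold",
    "initial_rate",
]


class NoTransitionError(ValueError):
    """Raised when a trace shows no usable transition or threshold crossing."""


@dataclass(frozen=True)
class MeltCurve:
    """A temperature-indexed signal trace.

    ``assay`` is one of ``cd_mre`` (mean residue ellipticity),
    ``nanodsf_bcm`` (fluorescence barycentric mean, nm), ``sls_counts``
    (static light scattering) or ``activity``.
    """

    temperature: tuple[float, ...]
    signal: tuple[float, ...]
    assay: str = "cd_mre"
    sample: str = ""
    ratio: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.size != s.size or t.size < 4:
            raise ValueError("need equal-length temperature/signal arrays of >= 4 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ValueError("missing or non-finite values in melt curve")

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.temperature, dtype=float)

    @property
    def s(self) -> np.ndarray:
        return np.asarray(self.signal, dtype=float)


@dataclass(frozen=True)
class ThresholdSpec:
    """Threshold-line rule: drift slope plus a fractional-endpoint intercept.

    The threshold line starts at the trace's initial signal plus
    ``intercept_rule * endpoint_magnitude`` and rises with ``drift_slope``
    (signal units per deg C); the caller reports where the interpolated trace
    first crosses it.
    """

    drift_slope: float
    intercept_rule: float
    endpoint_magnitude: float

    def __post_init__(self) -> None:
        if not (0 < self.intercept_rule <= 1):
            raise ValueError("intercept_rule must be in (0, 1]")


#: Conventional assay presets (drift slope defaults to 0; override per dataset)
THRESHOLD_PRESETS: dict[str, ThresholdSpec] = {
    # SLS aggregation onset: 20% of a typical 60,000-count endpoint
    "sls": ThresholdSpec(drift_slope=0.0, intercept_rule=0.20, endpoint_magnitude=60_000.0),
    # nanoDSF BCM shift at 95C: 50% of -4.5 nm (I53-40 style)
    "nanodsf_i53_40": ThresholdSpec(drift_slope=0.0, intercept_rule=0.50, endpoint_magnitude=-4.5),
    # nanoDSF BCM shift at 95C: 20% of -14.2 nm (I53-50 pentamer style)
    "nanodsf_i53_50": ThresholdSpec(drift_slope=0.0, intercept_rule=0.20, endpoint_magnitude=-14.2),
}


_FINE_STEP = 0.1  # deg C interpolation grid


def tm_by_derivative(curve: MeltCurve, min_peak_ratio: float = 2.5) -> float:
    """Melting temperature from the derivative extremum of the smoothed trace.

    The trace is spline-interpolated onto a 0.1 deg C grid; the
    central-difference derivative's extremum (largest magnitude after
    removing the median baseline drift) locates Tm.  A cubic spline is used:
    a quadratic spline's derivative is piecewise linear with its extrema
    pinned to the knots, which quantizes Tm to about half the sampling
    interval, while the cubic preserves the sampling-symmetric extremum.

    Traces whose peak baseline-corrected derivative does not exceed the
    trace's mean slope (signal range over temperature range) by at least
    ``min_peak_ratio`` are rejected as transition-free.
    """
    t, s = curve.t, curve.s
    if np.ptp(s) == 0:
        raise NoTransitionError("flat trace")
    fine_t = np.arange(t[0], t[-1] + _FINE_STEP / 2, _FINE_STEP)
    fine_s = interp1d(t, s, kind="cubic")(np.clip(fine_t, t[0], t[-1]))
    deriv = np.gradient(fine_s, fine_t)
    drift = np.median(deriv)
    excess = np.abs(deriv - drift)
    peak = excess.max()
    # a genuine sigmoidal step concentrates its slope: the peak derivative
    # far exceeds the average slope of the whole trace
    scale = np.ptp(s) / np.ptp(t) + 1e-300
    if peak / scale < min_peak_ratio:
        raise NoTransitionError(
            f"no transition detected (derivative peak/mean-slope ratio {peak / scale:.2f})"
        )
    return float(fine_t[int(np.argmax(excess))])


def t_by_threshold(curve: MeltCurve, spec: ThresholdSpec) -> float:
    """First temperature where the interpolated trace crosses the threshold line.

    The line is anchored at the starting temperature:
    line(T) = signal(T0) + intercept_rule * endpoint_magnitude
              + drift_slope * (T - T0).
    The trace is cubically interpolated on a 0.1 deg C grid and the first
    sign change of (signal - line) is refined linearly within its bracket.
    Signed endpoint magnitudes handle downward transitions symmetrically.
    """
    t, s = curve.t, curve.s
    fine_t = np.arange(t[0], t[-1] + _FINE_STEP / 2, _FINE_STEP)
    fine_s = interp1d(t, s, kind="cubic")(np.clip(fine_t, t[0], t[-1]))
    line = s[0] + spec.intercept_rule * spec.endpoint_magnitude + spec.drift_slope * (fine_t - t[0])
    resid = fine_s - line
    crossings = np.where(np.diff(np.signbit(resid)))[0]
    if resid[0] == 0 and crossings.size and crossings[0] == 0:
        crossings = crossings[1:]
    if crossings.size == 0:
        raise NoTransitionError("trace never crosses the threshold line")
    i = int(crossings[0])
    # linear refinement inside the bracketing fine-grid cell
    f0, f1 = resid[i], resid[i + 1]
    frac = 0.0 if f1 == f0 else f0 / (f0 - f1)
    return float(fine_t[i] + frac * _FINE_STEP)


def initial_rate(
    time_s: Sequence[float],
    absorbance: Sequence[float],
    window: tuple[float, float] = (100.0, 200.0),
    control_slope: float | None = None,
) -> tuple[float, float | None]:
    """Initial reaction velocity by OLS over a time window of an A339 trace.

    Returns (slope, relative) where ``relative`` is slope/control_slope when
    a 25 C control slope is supplied (the convention for reporting residual
    activity after thermal challenge), else None.
    """
    t = np.asarray(time_s, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 points in the {window} s window")
    slope = float(linregress(t[mask], a[mask]).slope)
    if control_slope is None:
        return slope, None
    if control_slope == 0:
        raise ValueError("zero control slope")
    return slope, slope / control_slope
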