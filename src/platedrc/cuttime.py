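"""Doubling-normalised cut-time calculation from the vehicle-control curve.

The cut time is the elapsed time at which growth values are read off every
well's curve to build the dose-response table.  To make EC50s comparable
between fast- and slow-growing lines, it is chosen as the time at which the
*control* curve has achieved a requested number of doublings from a baseline
time — restricted to the exponential phase and to a maximum growth value.

The exponential-phase end is detected as the minimum of a moving average of
the second differences of the control predictions on a uniform time grid:
the point where growth is decelerating most rapidly.  The curve is truncated
there (and wherever it exceeds ``max_val``); if the doubling target is not
reached on the truncated curve, the truncation point is returned instead
("capped") together with the number of doublings actually achieved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .drcset import DRCSet
from .errors import CutTimeError
from .growth import GrowthCurveModel, control_model

#: Bisection resolution for crossing times, in hours.
TIME_RESOLUTION_H = 0.01


@dataclass(frozen=True)
class CutTimeParams:
    """Parameters of the cut-time algorithm.

    baseline_time_h
        Time taken as the doubling baseline (hours).
    no_doublings
        Number of control doublings the cut time should allow.
    max_val
        Maximum allowable growth value, in metric units (80 by convention
        when the metric is percent confluence).
    window_n
        Moving-average window (grid points) for the second-difference
        profile.
    grid_step_h
        Uniform grid step for differencing; defaults to the median sampling
        interval of the control data.
    """

    baseline_time_h: float = 0.0
    no_doublings: float = 2.0
    max_val: float = 80.0
    window_n: int = 30
    grid_step_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.baseline_time_h < 0:
            raise CutTimeError("baseline_time_h must be nonnegative")
        if self.no_doublings < 0:
            raise CutTimeError("no_doublings must be nonnegative")
        if self.max_val <= 0:
            raise CutTimeError("max_val must be positive")
        if self.window_n < 1:
            raise CutTimeError("window_n must be a positive integer")
        if self.grid_step_h is not None and self.grid_step_h <= 0:
            raise CutTimeError("grid_step_h must be positive")


@dataclass(frozen=True)
class CutTimeResult:
    """Computed cut time with truncation diagnostics."""

    cut_time_h: float
    baseline_value: float
    target_value: float
    achieved_doublings: float
    truncation_time_h: float
    capped: bool
    params: CutTimeParams = field(repr=False, default=CutTimeParams())

    def to_dict(self) -> dict:
        return {
            "cut_time_h": self.cut_time_h,
            "baseline_value": self.baseline_value,
            "target_value": self.target_value,
            "achieved_doublings": self.achieved_doublings,
            "truncation_time_h": self.truncation_time_h,
            "capped": self.capped,
        }


def _grid(model: GrowthCurveModel, step: float) -> np.ndarray:
    lo, hi = model.time_domain
    n = int(np.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(n + 1)


def default_grid_step(drcset: DRCSet) -> float:
    """Median sampling interval of the observed timepoints."""
    t = drcset.platedata.timepoints
    if t.size < 2:
        raise CutTimeError("need at least 2 timepoints for a grid step")
    return float(np.median(np.diff(t)))


def second_difference_profile(
    model: GrowthCurveModel, grid_step_h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Second differences of predicted growth on a uniform grid.

    Returns ``(times, d2)`` at the interior grid points:
    ``d2[i] = y[i+1] - 2 y[i] + y[i-1]``, a discrete curvature proportional
    to the second derivative times ``grid_step_h**2``.
    """
    times = _grid(model, grid_step_h)
    if times.size < 4:
        raise CutTimeError(
            f"grid of {times.size} points too short for second differences; "
            "use a smaller grid_step_h"
        )
    y = model.predict(times)
    d2 = y[2:] - 2.0 * y[1:-1] + y[:-2]
    return times[1:-1], d2


def moving_average(values: np.ndarray, window_n: int) -> np.ndarray:
    """Centered moving average with windows truncated at the ends.

    Half-width is ``window_n // 2`` (effective full window
    ``2*(window_n//2) + 1`` points); ``window_n = 1`` returns the input.
    """
    half = window_n // 2
    if half == 0:
        return np.asarray(values, dtype=float).copy()
    v = np.asarray(values, dtype=float)
    c = np.concatenate([[0.0], np.cumsum(v)])
    n = v.size
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half, n - 1)
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def exponential_phase_end(
    model: GrowthCurveModel, window_n: int = 30, grid_step_h: float = 1.0
) -> float:
    """Time at which growth decelerates most rapidly (end of exponential
    phase): the minimum of the smoothed second-difference profile.

    An argmin falling in the left-truncated part of the moving average (or a
    flat profile) means no deceleration was detected; the end of the data is
    returned with a warning — early minima reflect initial lag/settling, not
    saturation.
    """
    times, d2 = second_difference_profile(model, grid_step_h)
    if times.size < max(window_n, 1):
        raise CutTimeError(
            f"second-difference profile has {times.size} points, fewer than "
            f"window_n={window_n}; use a smaller grid_step_h"
        )
    ma = moving_average(d2, window_n)
    t_max = model.time_domain[1]
    scale = max(np.abs(ma).max(), 1.0)
    if np.ptp(ma) <= 1e-12 * scale:
        warnings.warn(
            "second-difference profile is flat; no deceleration detected, "
            "using end of data as exponential-phase end"
        )
        return float(t_max)
    imin = int(np.argmin(ma))  # earliest minimum on ties
    if imin < window_n // 2:
        warnings.warn(
            "second-difference minimum at the start of the curve; no "
            "deceleration detected, using end of data as exponential-phase end"
        )
        return float(t_max)
    return float(times[imin])


def _bisect_crossing(model, t_lo, t_hi, level) -> float:
    """Earliest time in [t_lo, t_hi] where the prediction reaches ``level``,
    to TIME_RESOLUTION_H, assuming pred(t_lo) < level <= pred(t_hi)."""
    while t_hi - t_lo > TIME_RESOLUTION_H:
        mid = 0.5 * (t_lo + t_hi)
        if model.predict([mid])[0] >= level:
            t_hi = mid
        else:
            t_lo = mid
    return float(t_hi)


def calculate_cut_time(drcset: DRCSet, params: CutTimeParams) -> CutTimeResult:
    """Run the full cut-time algorithm on a set's pooled control curve.

    The control curve is truncated at the earliest of (a) the detected end
    of the exponential phase, (b) the time it crosses ``max_val`` and (c)
    the end of the data.  The cut time is the earliest time at or after the
    baseline where the control reaches ``baseline_value * 2**no_doublings``;
    if the truncated curve never reaches it, the truncation time is returned
    with ``capped=True`` and the doublings actually achieved.

    The result is stored on the set (as its cut time), clearing any
    previously attached dose-response results.
    """
    model = control_model(drcset)
    lo, hi = model.time_domain
    if not lo <= params.baseline_time_h <= hi:
        raise CutTimeError(
            f"baseline_time_h={params.baseline_time_h} outside control time "
            f"domain [{lo:g}, {hi:g}]"
        )
    step = params.grid_step_h if params.grid_step_h is not None else default_grid_step(drcset)
    baseline_value = float(model.predict([params.baseline_time_h])[0])
    if baseline_value <= 0:
        raise CutTimeError(
            f"control value at baseline is {baseline_value:g} <= 0; doublings undefined"
        )
    if params.max_val <= baseline_value:
        raise CutTimeError(
            f"max_val={params.max_val:g} must exceed the baseline control "
            f"value {baseline_value:g}"
        )

    phase_end = exponential_phase_end(model, params.window_n, step)

    times = _grid(model, step)
    y = model.predict(times)
    above = np.nonzero(y > params.max_val)[0]
    if above.size and above[0] > 0:
        i = above[0]
        max_cross = _bisect_crossing(model, times[i - 1], times[i], params.max_val)
    elif above.size:
        max_cross = float(times[0])
    else:
        max_cross = np.inf

    truncation_time = float(min(phase_end, max_cross, hi))
    target_value = baseline_value * 2.0 ** params.no_doublings

    # search grid times in [baseline, truncation] for the first target crossing
    cand = times[(times >= params.baseline_time_h - 1e-9) & (times <= truncation_time)]
    cand = np.concatenate([[params.baseline_time_h], cand, [truncation_time]])
    cand = np.unique(np.clip(cand, params.baseline_time_h, truncation_time))
    yc = model.predict(cand)
    reached = np.nonzero(yc >= target_value)[0]
    if reached.size:
        i = reached[0]
        if i == 0:
            cut = float(cand[0])
        else:
            cut = _bisect_crossing(model, cand[i - 1], cand[i], target_value)
        result = CutTimeResult(
            cut_time_h=cut,
            baseline_value=baseline_value,
            target_value=target_value,
            achieved_doublings=params.no_doublings,
            truncation_time_h=truncation_time,
            capped=False,
            params=params,
        )
    else:
        end_value = float(model.predict([truncation_time])[0])
        result = CutTimeResult(
            cut_time_h=truncation_time,
            baseline_value=baseline_value,
            target_value=target_value,
            achieved_doublings=float(np.log2(end_value / baseline_value)),
            truncation_time_h=truncation_time,
            capped=True,
            params=params,
        )
    drcset.set_cut_time(result.cut_time_h)
    drcset.cut_time_result = result
    return result


def cut_time_diagnostics(drcset: DRCSet, params: CutTimeParams) -> dict:
    """Diagnostic record behind the two-panel cut-time plot.

    Contains the control curve and moving-average second-difference profile
    plus the user-defined (baseline time, max_val) and computed
    (truncation time, cut time, target value) markers.
    """
    if drcset.cut_time_result is None:
        raise CutTimeError("run calculate_cut_time before requesting diagnostics")
    res: CutTimeResult = drcset.cut_time_result
    model = control_model(drcset)
    step = params.grid_step_h if params.grid_step_h is not None else default_grid_step(drcset)
    times = _grid(model, step)
    d2_times, d2 = second_difference_profile(model, step)
    return {
        "curve_times": times,
        "curve_values": model.predict(times),
        "profile_times": d2_times,
        "profile_values": moving_average(d2, params.window_n),
        "markers": {
            "baseline_time_h": params.baseline_time_h,
            "max_val": params.max_val,
            "truncation_time_h": res.truncation_time_h,
            "cut_time_h": res.cut_time_h,
            "target_value": res.target_value,
        },
        "capped": res.capped,
    }
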