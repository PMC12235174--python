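"""Preprocessing of raw luminescence traces.

The chain applied to every well, in order: subtract the plate background,
drop the initial luciferase-accumulation transient (first 12-24 h), detrend
by removing a 24 h centered moving average, smooth with a 2 h centered moving
average, and normalize to the maximum over the first day after trimming.

All moving averages are defined over *time* windows (not fixed sample
counts), so gaps in a recording - e.g. while the plate sat outside the
luminometer for zeitgeber exposure - are tolerated: each output sample
averages whatever samples fall inside its window. Samples lying exactly on a
window edge contribute with half weight, which makes the average symmetric
and exact for a linear trend even when the window spans an even number of
sampling intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import TraceSeries

_EDGE_EPS = 1e-9


class DeadWellError(ValueError):
    """Normalization window holds no positive signal: the well is dead."""


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessParams:
    """Knobs of the preprocessing chain, all in hours except ``background``
    (luminometer counts)."""

    background: float = 0.0
    trim_hours: float = 24.0
    detrend_window: float = 24.0
    smooth_window: float = 2.0
    norm_window: float = 24.0

    def __post_init__(self) -> None:
        if not 12.0 <= self.trim_hours <= 24.0:
            raise ValueError("trim_hours must lie in [12, 24]")
        if min(self.detrend_window, self.smooth_window, self.norm_window) <= 0:
            raise ValueError("windows must be positive")
        if self.background < 0:
            raise ValueError("background must be >= 0")


def moving_average(times: np.ndarray, values: np.ndarray, window: float) -> np.ndarray:
    """Centered moving average over a time window of ``window`` hours.

    Samples strictly inside (t - w/2, t + w/2) get weight 1; samples exactly
    at t +- w/2 get weight 1/2. Edges average over the available part of the
    window.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    half = window / 2.0
    csum = np.concatenate(([0.0], np.cumsum(values)))
    cnt = np.arange(times.size + 1, dtype=float)

    def _range_sum(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i0 = np.searchsorted(times, lo, side="left")
        i1 = np.searchsorted(times, hi, side="right")
        return csum[i1] - csum[i0], cnt[i1] - cnt[i0]

    # strictly interior samples
    s_in, n_in = _range_sum(times - half + _EDGE_EPS, times + half - _EDGE_EPS)
    # samples sitting exactly on either window edge
    s_lo, n_lo = _range_sum(times - half - _EDGE_EPS, times - half + _EDGE_EPS)
    s_hi, n_hi = _range_sum(times + half - _EDGE_EPS, times + half + _EDGE_EPS)
    wsum = s_in + 0.5 * (s_lo + s_hi)
    wcnt = n_in + 0.5 * (n_lo + n_hi)
    return wsum / wcnt


def subtract_background(trace: TraceSeries, background: float) -> TraceSeries:
    """Remove the luminometer dark-count level; negative results are allowed
    (normalization handles them downstream)."""
    if background < 0:
        raise ValueError("background must be >= 0")
    return trace.with_values(trace.values - background)


def trim_transient(trace: TraceSeries, trim_hours: float) -> TraceSeries:
    """Drop the first ``trim_hours`` of recording (luciferase accumulation).

    Absolute times are kept so the ZT mapping survives. Errors out if fewer
    than two full days would remain - period estimation needs them.
    """
    if trim_hours >= trace.duration:
        raise PreprocessError("trim would remove the whole trace")
    trimmed = trace.slice_time(trace.times[0] + trim_hours, np.inf)
    if trimmed.duration < 48.0 - _EDGE_EPS:
        raise PreprocessError(
            f"trimming {trim_hours} h leaves {trimmed.duration:.1f} h < 2 days of data"
        )
    return trimmed


def detrend(trace: TraceSeries, window: float) -> TraceSeries:
    """Subtract a centered moving average (default window: one day)."""
    if trace.n_samples >= 2 and window < 2 * trace.sampling_interval:
        raise PreprocessError("detrend window must span >= 2 sampling intervals")
    if window > trace.duration:
        raise PreprocessError("detrend window longer than trace")
    return trace.with_values(trace.values - moving_average(trace.times, trace.values, window))


def smooth(trace: TraceSeries, window: float) -> TraceSeries:
    """Centered moving-average smoothing; output length equals input length."""
    if trace.n_samples >= 2 and window < trace.sampling_interval:
        raise PreprocessError("smooth window must span >= 1 sampling interval")
    if window > trace.duration:
        raise PreprocessError("smooth window longer than trace")
    return trace.with_values(moving_average(trace.times, trace.values, window))


def normalize_initial_max(trace: TraceSeries, norm_window: float) -> TraceSeries:
    """Divide by the maximum over the first ``norm_window`` hours.

    After this step the max over that window is exactly 1. An all-zero or
    all-negative window signals a dead well.
    """
    t0 = trace.times[0]
    sel = trace.times <= t0 + norm_window + _EDGE_EPS
    if not np.any(sel):
        raise PreprocessError("normalization window holds no samples")
    peak = float(np.max(trace.values[sel]))
    if peak <= 0:
        raise DeadWellError(
            f"well {trace.well_id}: no positive signal in the first {norm_window} h"
        )
    return trace.with_values(trace.values / peak)


def run_preprocess(trace: TraceSeries, params: PreprocessParams | None = None) -> TraceSeries:
    """Full chain: background -> trim -> detrend -> smooth -> normalize."""
    params = params or PreprocessParams()
    out = subtract_background(trace, params.background)
    out = trim_transient(out, params.trim_hours)
    out = detrend(out, params.detrend_window)
    out = smooth(out, params.smooth_window)
    return normalize_initial_max(out, params.norm_window)
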