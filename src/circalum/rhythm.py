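"""Period, acrophase and rhythmicity per trace.

The period of each (preprocessed) trace is located with a Lomb-Scargle
periodogram over 18-37 h at 30x oversampling; MESOR, amplitude, period and
acrophase are then estimated by cosinor regression

    y(t) = M + A * cos(2*pi*(t - phi_abs) / tau) + e(t),

solved in closed form for fixed tau (the model is linear in A*cos, A*sin) and
by a profile search over tau otherwise. A trace is called "Synchronized"
(entrained recording: tau ~ 24 h and R^2 >= 0.5) or "Circadian" (free run:
18 h <= tau <= 37 h and R^2 >= 0.5), else "Arrhythmic".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import lombscargle as _scipy_lombscargle

from .traces import Condition, TraceSeries

TWO_PI = 2.0 * np.pi


class RhythmError(ValueError):
    pass


class ConstantTraceError(RhythmError):
    """Zero-variance input: no rhythm statistics are defined."""


@dataclass(frozen=True)
class PeriodogramSpec:
    """Search window and resolution of the periodogram (hours)."""

    period_min: float = 18.0
    period_max: float = 37.0
    oversampling: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.period_min < self.period_max:
            raise ValueError("need 0 < period_min < period_max")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")

    def frequency_grid(self, duration: float) -> np.ndarray:
        """Frequencies (1/h) from 1/period_max to 1/period_min, step
        1/(oversampling * duration), inclusive of both period bounds."""
        f_lo, f_hi = 1.0 / self.period_max, 1.0 / self.period_min
        df = 1.0 / (self.oversampling * duration)
        freqs = np.arange(f_lo, f_hi, df)
        if freqs.size == 0 or freqs[-1] < f_hi - 1e-12:
            freqs = np.append(freqs, f_hi)
        return freqs


@dataclass
class Periodogram:
    periods: np.ndarray
    powers: np.ndarray

    @property
    def peak_period(self) -> float:
        return float(self.periods[int(np.argmax(self.powers))])

    @property
    def grid_step(self) -> float:
        """Largest spacing between adjacent period grid points, hours."""
        return float(np.max(np.abs(np.diff(self.periods))))


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    period: float
    acrophase_abs: float  # peak time in hours from recording start, in [0, tau)
    acrophase_zt: float  # peak time mapped to ZT/CT hours, in [0, 24)
    r_squared: float
    sse: float
    n: int


@dataclass
class RhythmCall:
    label: Literal["Synchronized", "Circadian", "Arrhythmic"]
    condition: Condition
    criteria: dict = field(default_factory=dict)


def lomb_scargle(trace: TraceSeries, spec: PeriodogramSpec | None = None) -> Periodogram:
    """Classical variance-normalized Lomb-Scargle periodogram.

    Uses the phase-invariant Scargle form (per-frequency time offset); the
    values are centered first and power is divided by the sample variance, so
    power is invariant under affine transforms of the values and under time
    translation. Peak power locates the dominant period inside the search
    window.
    """
    spec = spec or PeriodogramSpec()
    t, y = trace.times, trace.values
    if t.size < 8:
        raise RhythmError("need >= 8 samples for a periodogram")
    if trace.duration < spec.period_min:
        raise RhythmError("trace shorter than the minimum period searched")
    var = float(np.var(y, ddof=1))
    if var == 0.0:
        raise ConstantTraceError("constant trace has no periodogram")
    freqs = spec.frequency_grid(trace.duration)
    power = _scipy_lombscargle(t, y - y.mean(), TWO_PI * freqs) / var
    periods = 1.0 / freqs
    return Periodogram(periods=periods, powers=power)


def _linear_cosinor(t: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float, float, float]:
    """Closed-form least squares of y on [1, cos(wt), sin(wt)] at fixed tau.

    Returns (mesor, beta_cos, beta_sin, sse).
    """
    w = TWO_PI / tau
    X = np.column_stack((np.ones_like(t), np.cos(w * t), np.sin(w * t)))
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(coef[2]), float(resid @ resid)


def _fit_at_tau(trace: TraceSeries, tau: float) -> CosinorFit:
    t, y = trace.times, trace.values
    m, bc, bs, sse = _linear_cosinor(t, y, tau)
    amplitude = float(np.hypot(bc, bs))
    # bc*cos(wt) + bs*sin(wt) = A*cos(w*(t - t_peak)) with w*t_peak = atan2(bs, bc)
    t_peak = float(np.arctan2(bs, bc) / (TWO_PI / tau)) % tau
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot
    return CosinorFit(
        mesor=m,
        amplitude=amplitude,
        period=float(tau),
        acrophase_abs=t_peak,
        acrophase_zt=float(trace.zt(t_peak)),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        sse=sse,
        n=t.size,
    )


def cosinor_fit(
    trace: TraceSeries,
    period_init: float = 24.0,
    free_period: bool = True,
    spec: PeriodogramSpec | None = None,
) -> CosinorFit:
    """Cosinor regression of a trace.

    With ``free_period`` the period is profiled: the closed-form (M, A, phi)
    solution is evaluated at every period of the Lomb-Scargle grid, and the
    best grid period is refined by bounded 1-D minimization of the SSE
    profile between its neighbors (this sidesteps the initialization
    fragility of a joint nonlinear fit). With ``free_period=False`` the
    period is held at ``period_init`` and the fit is a single closed-form
    solve. Amplitude is reported >= 0 with the acrophase adjusted
    accordingly; acrophase is also mapped to ZT/CT hours mod 24.
    """
    spec = spec or PeriodogramSpec()
    t, y = trace.times, trace.values
    if t.size < 8:
        raise RhythmError("need >= 8 samples for a cosinor fit")
    if float(np.sum((y - y.mean()) ** 2)) == 0.0:
        raise ConstantTraceError("constant trace: SS_tot = 0")
    if not free_period:
        return _fit_at_tau(trace, period_init)
    if not spec.period_min <= period_init <= spec.period_max:
        raise RhythmError("period_init outside the search window")

    taus = np.sort(1.0 / spec.frequency_grid(trace.duration))
    sses = np.array([_linear_cosinor(t, y, tau)[3] for tau in taus])
    k = int(np.argmin(sses))
    lo = taus[max(k - 1, 0)]
    hi = taus[min(k + 1, taus.size - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda tau: _linear_cosinor(t, y, tau)[3],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-7},
        )
        best_tau = float(res.x) if res.fun <= sses[k] else float(taus[k])
    else:
        best_tau = float(taus[k])
    return _fit_at_tau(trace, best_tau)


def classify(
    fit: CosinorFit,
    condition: Condition,
    tol_24: float = 1.0,
    r2_min: float = 0.5,
    period_min: float = 18.0,
    period_max: float = 37.0,
) -> RhythmCall:
    """Rhythmicity call from a cosinor fit.

    Entrained recordings with a ~24 h period (|tau - 24| <= tol_24) and
    R^2 >= 0.5 are "Synchronized"; free-running recordings with
    18 <= tau <= 37 h and R^2 >= 0.5 are "Circadian"; all bounds inclusive;
    anything else is "Arrhythmic".
    """
    criteria = {
        "tau": fit.period,
        "r_squared": fit.r_squared,
        "r2_min": r2_min,
        "condition": condition,
    }
    if condition == "entrained":
        criteria["tol_24"] = tol_24
        ok = abs(fit.period - 24.0) <= tol_24 and fit.r_squared >= r2_min
        label = "Synchronized" if ok else "Arrhythmic"
    elif condition == "freerun":
        criteria["period_range"] = (period_min, period_max)
        ok = period_min <= fit.period <= period_max and fit.r_squared >= r2_min
        label = "Circadian" if ok else "Arrhythmic"
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return RhythmCall(label=label, condition=condition, criteria=criteria)


def find_peak_phases(
    trace: TraceSeries,
    window: tuple[float, float],
    first_only: bool = False,
) -> list[float]:
    """Observed peak time(s) of a trace, in ZT/CT hours mod 24.

    For each full 24 h cycle inside ``window`` (hours from recording start),
    the time of the maximum value is recorded. ``first_only`` returns just
    the first cycle's peak - the definition used for free-run summaries (the
    first bioluminescent peak after release).
    """
    t0, t1 = window
    if t1 - t0 < 24.0 - 1e-9:
        raise RhythmError("peak window must span at least one day")
    phases: list[float] = []
    start = t0
    while start + 24.0 <= t1 + 1e-9:
        seg = trace.slice_time(start, min(start + 24.0, t1 + 1e-9))
        if seg.n_samples == 0:
            raise RhythmError("peak window contains no samples")
        if np.ptp(seg.values) == 0.0:
            raise ConstantTraceError("constant trace has no unique peak")
        t_peak = float(seg.times[int(np.argmax(seg.values))])
        phases.append(float(trace.zt(t_peak)))
        if first_only:
            return phases
        start += 24.0
    if not phases:
        raise RhythmError("peak window contains no full day")
    return phases


def percent_rhythmic(
    calls: Sequence[RhythmCall],
    labels: tuple[str, ...] = ("Synchronized", "Circadian"),
    decimals: int | None = None,
) -> float:
    """Percentage of calls carrying a rhythmic label.

    Returns the exact percentage by default; ``decimals`` rounds to the
    requested printed precision (0 for whole percent, 1 for one decimal).
    """
    if len(calls) == 0:
        raise ValueError("no rhythm calls given")
    hits = sum(1 for c in calls if c.label in labels)
    pct = 100.0 * hits / len(calls)
    if decimals is not None:
        pct = round(pct, decimals)
        if decimals == 0:
            pct = float(int(pct))
    return pct
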