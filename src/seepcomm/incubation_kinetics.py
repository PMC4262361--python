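"""Sulfate-depletion kinetics for anoxic slurry incubations.

Estimates the maximum sulfate consumption rate (sliding-window ordinary
least squares), fits a four-parameter falling logistic to sigmoidal
depletion curves, locates the lag phase, and classifies a series as
active or inactive.

The falling logistic is

    S(t) = S_inf + (S0 - S_inf) / (1 + exp(k (t - t0)))      with k > 0,

whose steepest consumption rate is the analytic (S0 - S_inf) * k / 4 at
t = t0.  Sliding-window OLS is the default rate estimator because sparse,
noisy depletion series do not always support a sigmoid fit; the analytic
logistic rate is reported alongside whenever the fit succeeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core_data_io import IncubationSeries, ValidationError

__all__ = [
    "RateEstimate",
    "LogisticFit",
    "KineticsError",
    "max_consumption_rate",
    "fit_logistic",
    "detect_lag",
    "classify_activity",
    "estimate_rates",
]

DEFAULT_WINDOW_POINTS = 3
DEFAULT_LAG_THRESHOLD = 0.05
DEFAULT_MIN_CONSUMED_FRACTION = 0.2


class KineticsError(ValueError):
    """Raised when a series does not support the requested kinetic analysis."""


@dataclass(frozen=True)
class LogisticFit:
    """Fitted falling-logistic parameters and the residual RMS (µM)."""

    S0_uM: float
    S_inf_uM: float
    k_per_h: float
    t0_h: float
    rms_uM: float

    @property
    def r_max_uM_per_h(self) -> float:
        """Analytic maximum consumption rate (S0 - S_inf) * k / 4."""
        return (self.S0_uM - self.S_inf_uM) * self.k_per_h / 4.0

    def predict(self, t_h: np.ndarray) -> np.ndarray:
        return _logistic(np.asarray(t_h, float), self.S0_uM, self.S_inf_uM,
                         self.k_per_h, self.t0_h)


@dataclass(frozen=True)
class RateEstimate:
    """Maximum consumption rate, its defining window, lag and activity flag."""

    r_max_uM_per_h: float
    window_h: tuple[float, float]
    lag_h: float
    active: bool
    fit: LogisticFit | None = None

    def __post_init__(self) -> None:
        if self.r_max_uM_per_h < 0:
            raise ValidationError("r_max must be >= 0")
        if self.window_h[0] >= self.window_h[1]:
            raise ValidationError("rate window start must precede end")


def _logistic(t, S0, S_inf, k, t0):
    # exp argument clipped: curve_fit explores parameter space freely
    return S_inf + (S0 - S_inf) / (1.0 + np.exp(np.clip(k * (t - t0), -500, 500)))


def classify_activity(series: IncubationSeries,
                      min_consumed_fraction: float = DEFAULT_MIN_CONSUMED_FRACTION) -> bool:
    """True when net consumption reaches ``min_consumed_fraction`` of the start.

    The boundary is inclusive: consuming exactly the threshold fraction counts
    as active.
    """
    s = series.sulfate_uM
    if s[0] == 0:
        raise KineticsError("cannot classify activity: initial sulfate is 0")
    return bool((s[0] - s[-1]) / s[0] >= min_consumed_fraction)


def max_consumption_rate(series: IncubationSeries,
                         window_points: int = DEFAULT_WINDOW_POINTS,
                         min_consumed_fraction: float = DEFAULT_MIN_CONSUMED_FRACTION,
                         lag_threshold: float = DEFAULT_LAG_THRESHOLD,
                         with_fit: bool = False) -> RateEstimate:
    """Maximum consumption rate over all contiguous ``window_points`` windows.

    Each window contributes the negated OLS slope of sulfate on time;
    windows with non-negative slope (no net consumption) contribute zero.
    Returns the argmax window, the lag estimate (NaN for inactive series)
    and, when ``with_fit`` is set and the sigmoid fit converges, the
    logistic parameters.
    """
    if window_points < 2:
        raise KineticsError("window_points must be >= 2")
    n = len(series)
    if n < window_points:
        raise KineticsError(
            f"series has {n} points; needs >= {window_points} "
            f"(reduce window_points to {max(2, n)} or fewer)"
        )
    t, s = series.times_h, series.sulfate_uM
    best_rate, best_win = 0.0, (float(t[0]), float(t[-1]))
    for i in range(n - window_points + 1):
        tw, sw = t[i:i + window_points], s[i:i + window_points]
        # centered OLS slope: exactly zero for constant windows
        dt, ds = tw - tw.mean(), sw - sw.mean()
        slope = float(np.dot(dt, ds) / np.dot(dt, dt))
        rate = max(0.0, -slope)
        if rate > best_rate:
            best_rate, best_win = rate, (float(tw[0]), float(tw[-1]))
    active = classify_activity(series, min_consumed_fraction)
    lag = detect_lag(series, lag_threshold) if active else float("nan")
    fit = None
    if with_fit and active:
        try:
            fit = fit_logistic(series)
        except KineticsError:
            fit = None
    return RateEstimate(r_max_uM_per_h=best_rate, window_h=best_win,
                        lag_h=lag, active=active, fit=fit)


def fit_logistic(series: IncubationSeries) -> LogisticFit:
    """Least-squares fit of the falling logistic to a depletion series.

    Initialisation is deterministic: S0 = max(S), S_inf = min(S), t0 at the
    steepest finite-difference drop, and k from that slope, so repeated fits
    of the same series are identical.
    """
    t, s = series.times_h, series.sulfate_uM
    if len(series) < 4:
        raise KineticsError("logistic fit needs >= 4 points")
    if s[-1] >= s[0]:
        raise KineticsError(
            "no net consumption observed; use max_consumption_rate instead"
        )
    S0_i, Sinf_i = float(s.max()), float(s.min())
    diffs = np.diff(s) / np.diff(t)
    j = int(np.argmin(diffs))  # steepest drop
    t0_i = float(0.5 * (t[j] + t[j + 1]))
    span = max(S0_i - Sinf_i, 1e-9)
    k_i = float(np.clip(-4.0 * diffs[j] / span, 1e-4, 10.0))
    p0 = (S0_i, Sinf_i, k_i, t0_i)
    try:
        popt, _ = curve_fit(
            _logistic, t, s, p0=p0, maxfev=20000,
            ftol=1e-14, xtol=1e-14, gtol=1e-14,
            bounds=([0.0, 0.0, 1e-6, t[0] - (t[-1] - t[0])],
                    [np.inf, np.inf, np.inf, t[-1] + (t[-1] - t[0])]),
        )
    except RuntimeError as exc:
        resid = s - _logistic(t, *p0)
        raise KineticsError(
            f"logistic fit did not converge (initial guess {p0}, "
            f"initial residual RMS {float(np.sqrt(np.mean(resid ** 2))):.3g} µM)"
        ) from exc
    S0, S_inf, k, t0 = (float(v) for v in popt)
    resid = s - _logistic(t, S0, S_inf, k, t0)
    return LogisticFit(S0_uM=S0, S_inf_uM=S_inf, k_per_h=k, t0_h=t0,
                       rms_uM=float(np.sqrt(np.mean(resid ** 2))))


def detect_lag(series: IncubationSeries,
               consumed_fraction_threshold: float = DEFAULT_LAG_THRESHOLD) -> float:
    """Earliest time by which consumption first exceeds a fraction of the total.

    Cumulative consumption is S(0) - S(t); the crossing of
    ``threshold * total_consumption`` is located by linear interpolation
    between the bracketing observations.
    """
    if not 0 < consumed_fraction_threshold < 1:
        raise KineticsError("consumed_fraction_threshold must lie in (0, 1)")
    if not classify_activity(series, min_consumed_fraction=1e-12):
        raise KineticsError("series shows no net consumption; lag undefined")
    t, s = series.times_h, series.sulfate_uM
    consumed = s[0] - s
    target = consumed_fraction_threshold * consumed[-1]
    idx = int(np.argmax(consumed >= target))
    if idx == 0:
        return float(t[0])
    c0, c1 = consumed[idx - 1], consumed[idx]
    frac = (target - c0) / (c1 - c0)
    return float(t[idx - 1] + frac * (t[idx] - t[idx - 1]))


def estimate_rates(series_list: list[IncubationSeries],
                   window_points: int = DEFAULT_WINDOW_POINTS,
                   lag_threshold: float = DEFAULT_LAG_THRESHOLD,
                   with_fit: bool = True) -> dict[float, RateEstimate]:
    """Per-temperature rate estimates for a suite of incubation series."""
    return {
        s.temperature_C: max_consumption_rate(
            s, window_points=window_points, lag_threshold=lag_threshold,
            with_fit=with_fit)
        for s in series_list
    }
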