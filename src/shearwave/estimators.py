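"""Shear-wave speed estimators.

Four estimators of the lateral shear-wave group speed from a space-time
displacement field, presented as scikit-learn style estimator classes (a
``fit`` method, fitted attributes with trailing underscores, parameters in
the constructor) so they compose with sklearn model-selection tooling:

* :class:`SPMEstimator` — time-to-peak at sample resolution: per channel,
  the arrival time is the time sample of the displacement maximum; the
  speed is the slope of an ordinary least-squares regression of channel
  position (m) on arrival time (s).
* :class:`TDPMEstimator` — time-to-peak with sub-sample resolution: each
  trace is upsampled with a cubic spline and the peak is refined by
  three-point parabolic interpolation, which removes the time-quantization
  floor of the sample-resolution method.
* :class:`TSPMEstimator` — time-shift estimation: the delay between
  adjacent channels is the (parabolically refined) maximum of their
  cross-correlation; cumulative delays against position go through the same
  regression.
* :class:`RadonSumEstimator` — group velocity from the straight trajectory
  t = t0 + (x - x_ref)/c through the space-time image that maximizes the
  integrated absolute displacement, searched over a speed/intercept grid.

The acronym-style names (SPM/TDPM/TSPM) follow the shear-wave-elastography
literature's shorthand for the sample-resolution, sub-sample and time-shift
variants of the time-to-peak family; the constructions here are this
package's conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import correlate, correlation_lags
from sklearn.base import BaseEstimator

from .errors import NumericalError, SchemaError
from .field import DisplacementField

__all__ = [
    "ArrivalTimes",
    "SWSEstimate",
    "SPMEstimator",
    "TDPMEstimator",
    "TSPMEstimator",
    "RadonSumEstimator",
    "detect_arrivals_spm",
    "detect_arrivals_tdpm",
    "fit_speed_regression",
    "estimate_tspm",
    "estimate_radon",
    "ESTIMATORS",
]


@dataclass
class ArrivalTimes:
    """Per-channel feature-point (peak) times with validity flags."""

    channel_positions: np.ndarray  # m, strictly increasing
    arrival_times: np.ndarray  # s (nan where invalid)
    peak_amplitudes: np.ndarray  # micrometres
    quality_flags: np.ndarray  # bool, True = valid peak found

    def __post_init__(self) -> None:
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        self.arrival_times = np.asarray(self.arrival_times, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        self.quality_flags = np.asarray(self.quality_flags, dtype=bool)
        if np.any(np.diff(self.channel_positions) <= 0):
            raise SchemaError("channel positions must be strictly increasing")
        if not np.all(np.isfinite(self.arrival_times[self.quality_flags])):
            raise SchemaError("arrival times must be finite wherever flagged valid")

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.quality_flags))

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table (position_m, arrival_s, amplitude_um, valid)."""
        return pd.DataFrame(
            {
                "position_m": self.channel_positions,
                "arrival_s": self.arrival_times,
                "amplitude_um": self.peak_amplitudes,
                "valid": self.quality_flags,
            }
        )


@dataclass
class SWSEstimate:
    """One shear-wave-speed reading.

    ``speed`` is in m/s; ``r_squared`` is the coefficient of determination
    of the position-vs-time fit (or the normalized peak sharpness for the
    Radon method); ``intercept`` is the fitted arrival time at lateral
    position zero, in seconds.
    """

    speed: float
    r_squared: float
    method: str
    n_channels_used: int
    intercept: float = float("nan")

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise NumericalError(f"non-physical speed {self.speed}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise NumericalError(f"r_squared {self.r_squared} outside [0, 1]")


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------


def _window_slice(time_axis: np.ndarray, window) -> slice:
    if window is None:
        return slice(0, time_axis.size)
    a, b = float(window[0]), float(window[1])
    if not (time_axis[0] <= a < b <= time_axis[-1] + 1e-15):
        raise SchemaError(f"window ({a}, {b}) s must lie inside the time axis")
    i0 = int(np.searchsorted(time_axis, a - 1e-15))
    i1 = int(np.searchsorted(time_axis, b + 1e-15))
    if i1 - i0 < 3:
        raise SchemaError("window must contain at least 3 time samples")
    return slice(i0, i1)


def detect_arrivals_spm(field: DisplacementField, depth_index: int = 0,
                        window=None) -> ArrivalTimes:
    """Sample-resolution peak pick: arrival = time of the maximum sample.

    Ties break toward the earliest sample; a channel whose maximum sits on
    the window boundary (no interior peak) or which carries no signal is
    flagged invalid.
    """
    traces = field.traces(depth_index)
    if traces.shape[0] < 3:
        raise SchemaError("need at least 3 lateral channels")
    sl = _window_slice(field.time_axis, window)
    t = field.time_axis[sl]
    seg = traces[:, sl]
    n = seg.shape[1]
    times = np.full(traces.shape[0], np.nan)
    amps = np.zeros(traces.shape[0])
    valid = np.zeros(traces.shape[0], dtype=bool)
    for i, y in enumerate(seg):
        k = int(np.argmax(y))  # argmax takes the earliest of equal maxima
        amps[i] = y[k]
        if y[k] == y.min() or k == 0 or k == n - 1:
            continue  # flat trace or boundary peak
        times[i] = t[k]
        valid[i] = True
    if not valid.any():
        raise NumericalError("no channel produced a valid peak")
    return ArrivalTimes(field.lateral_axis, times, amps, valid)


def _parabolic_vertex(tm: float, h: float, ym: float, yl: float, yr: float) -> float:
    denom = yl - 2.0 * ym + yr
    if denom >= 0:  # not a local max; keep the grid point
        return tm
    delta = 0.5 * (yl - yr) / denom
    return tm + float(np.clip(delta, -1.0, 1.0)) * h


def detect_arrivals_tdpm(field: DisplacementField, depth_index: int = 0,
                         upsample_factor: int = 8, window=None,
                         refine: bool = True) -> ArrivalTimes:
    """Sub-sample peak pick: spline upsampling + parabolic refinement.

    The trace is upsampled by ``upsample_factor`` with a (not-a-knot) cubic
    spline, the maximum is located on the fine grid within one original
    sample of the discrete peak, and the peak time is refined by a
    three-point parabolic fit (exact for a quadratic peak). With
    ``upsample_factor=1`` and ``refine=False`` this reduces exactly to the
    sample-resolution method.
    """
    if upsample_factor < 1:
        raise SchemaError("upsample_factor must be >= 1")
    traces = field.traces(depth_index)
    if traces.shape[0] < 3:
        raise SchemaError("need at least 3 lateral channels")
    sl = _window_slice(field.time_axis, window)
    t = field.time_axis[sl]
    seg = traces[:, sl]
    n = seg.shape[1]
    dt_fine = (t[1] - t[0]) / upsample_factor
    times = np.full(traces.shape[0], np.nan)
    amps = np.zeros(traces.shape[0])
    valid = np.zeros(traces.shape[0], dtype=bool)
    for i, y in enumerate(seg):
        k = int(np.argmax(y))
        amps[i] = y[k]
        if y[k] == y.min() or k == 0 or k == n - 1:
            continue  # no 3-point neighbourhood around the peak
        if upsample_factor == 1 and not refine:
            times[i] = t[k]
            valid[i] = True
            continue
        if upsample_factor > 1:
            spline = CubicSpline(t, y)
            # search only within +-1 original sample of the discrete peak
            tf = t[k - 1] + np.arange(2 * upsample_factor + 1) * dt_fine
            yf = spline(tf)
            m = int(np.argmax(yf))
            m = min(max(m, 1), yf.size - 2)
            tm, ym, yl, yr = tf[m], yf[m], yf[m - 1], yf[m + 1]
            h = dt_fine
        else:
            tm, ym, yl, yr = t[k], y[k], y[k - 1], y[k + 1]
            h = t[1] - t[0]
        times[i] = _parabolic_vertex(tm, h, ym, yl, yr) if refine else tm
        amps[i] = ym
        valid[i] = True
    if not valid.any():
        raise NumericalError("no channel produced a valid peak")
    return ArrivalTimes(field.lateral_axis, times, amps, valid)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


def fit_speed_regression(arrivals: ArrivalTimes, method: str = "SPM",
                         robust: bool = False) -> SWSEstimate:
    """Speed from the slope of OLS position (m) on arrival time (s).

    Regressing position on time makes the slope the speed directly (the
    reciprocal-slope orientation — time on position — gives 1/speed and is
    not used here). ``robust=True`` adds a single re-fit after discarding
    residuals beyond 3 estimated standard deviations.
    """
    x = arrivals.channel_positions[arrivals.quality_flags]
    t = arrivals.arrival_times[arrivals.quality_flags]
    return _regress(x, t, method, robust)


def _regress(x: np.ndarray, t: np.ndarray, method: str, robust: bool = False) -> SWSEstimate:
    if x.size < 3:
        raise NumericalError(f"only {x.size} valid channels; need at least 3")
    if np.ptp(t) == 0:
        raise NumericalError("all arrival times equal: slope (speed) is infinite")
    tm, xm = t.mean(), x.mean()
    stt = float(np.sum((t - tm) ** 2))
    sxt = float(np.sum((t - tm) * (x - xm)))
    slope = sxt / stt
    if robust:
        resid = x - xm - slope * (t - tm)
        s = resid.std()
        if s > 0:
            keep = np.abs(resid) <= 3.0 * s
            if keep.sum() >= 3 and keep.sum() < x.size:
                return _regress(x[keep], t[keep], method, robust=False)
    if slope <= 0:
        raise NumericalError(
            f"fitted slope {slope:.4g} m/s is non-positive: non-physical propagation"
        )
    fitted = xm + slope * (t - tm)
    sse = float(np.sum((x - fitted) ** 2))
    sst = float(np.sum((x - xm) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, min(1.0, 1.0 - sse / sst))
    # time at lateral position zero from x = a + slope * t
    a = xm - slope * tm
    return SWSEstimate(speed=slope, r_squared=r2, method=method,
                       n_channels_used=int(x.size), intercept=-a / slope)


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------


class _BaseSWS(BaseEstimator):
    """Shared fit plumbing: fit(X) on a DisplacementField, fitted attrs."""

    method: str = ""

    def fit(self, X: DisplacementField, y=None):
        if not isinstance(X, DisplacementField):
            raise SchemaError("X must be a DisplacementField")
        est = self._estimate(X)
        self.result_ = est
        self.speed_ = est.speed
        self.r_squared_ = est.r_squared
        self.n_channels_used_ = est.n_channels_used
        self.intercept_ = est.intercept
        return self

    def estimate(self, X: DisplacementField) -> SWSEstimate:
        """Fit and return the :class:`SWSEstimate` in one call."""
        return self.fit(X).result_

    def _estimate(self, X: DisplacementField) -> SWSEstimate:  # pragma: no cover
        raise NotImplementedError


class SPMEstimator(_BaseSWS):
    """Sample-resolution time-to-peak speed estimator.

    Accuracy is floored by time quantization: arrival times are multiples of
    1/PRF, so the worst-case speed bias over an aperture L is of order
    c^2 * dt / L.
    """

    method = "SPM"

    def __init__(self, depth_index: int = 0, window=None, robust: bool = False):
        self.depth_index = depth_index
        self.window = window
        self.robust = robust

    def _estimate(self, X: DisplacementField) -> SWSEstimate:
        arr = detect_arrivals_spm(X, self.depth_index, self.window)
        self.arrival_times_ = arr
        return fit_speed_regression(arr, self.method, self.robust)


class TDPMEstimator(_BaseSWS):
    """Sub-sample time-to-peak speed estimator (spline + parabolic refine)."""

    method = "TDPM"

    def __init__(self, depth_index: int = 0, window=None, upsample_factor: int = 8,
                 refine: bool = True, robust: bool = False):
        self.depth_index = depth_index
        self.window = window
        self.upsample_factor = upsample_factor
        self.refine = refine
        self.robust = robust

    def _estimate(self, X: DisplacementField) -> SWSEstimate:
        arr = detect_arrivals_tdpm(X, self.depth_index, self.upsample_factor,
                                   self.window, self.refine)
        self.arrival_times_ = arr
        return fit_speed_regression(arr, self.method, self.robust)


class TSPMEstimator(_BaseSWS):
    """Time-shift speed estimator via adjacent-channel cross-correlation.

    For each adjacent channel pair the inter-channel delay is the location
    of the cross-correlation maximum within ``+-max_lag_s``, refined to
    sub-sample precision by parabolic interpolation; cumulative delays
    against position go through the position-on-time regression. A pair
    whose correlation peak lands on the lag boundary is dropped, and since a
    dropped pair breaks the cumulative chain, only channels up to the first
    dropped pair contribute.
    """

    method = "TSPM"

    def __init__(self, depth_index: int = 0, max_lag_s: float | None = None,
                 window=None, robust: bool = False):
        self.depth_index = depth_index
        self.max_lag_s = max_lag_s
        self.window = window
        self.robust = robust

    def _estimate(self, X: DisplacementField) -> SWSEstimate:
        traces = X.traces(self.depth_index)
        if traces.shape[0] < 3:
            raise NumericalError("need at least 3 channels for time-shift estimation")
        sl = _window_slice(X.time_axis, self.window)
        seg = traces[:, sl]
        dt = X.dt
        n = seg.shape[1]
        max_lag = (n - 1) * dt if self.max_lag_s is None else float(self.max_lag_s)
        if max_lag <= 0:
            raise SchemaError("max_lag_s must be positive")
        lags = correlation_lags(n, n, mode="full")
        allowed = np.abs(lags * dt) <= max_lag + 1e-15
        if allowed.sum() < 3:
            raise SchemaError("max_lag_s admits fewer than 3 correlation lags")
        idx_allowed = np.flatnonzero(allowed)
        cum = [0.0]
        pos = [X.lateral_axis[0]]
        for i in range(seg.shape[0] - 1):
            c = correlate(seg[i + 1], seg[i], mode="full")
            sub = c[idx_allowed]
            m = int(np.argmax(sub))
            if m == 0 or m == sub.size - 1:
                break  # peak on the lag boundary: drop pair, chain ends
            j = idx_allowed[m]
            lag = _parabolic_vertex(lags[j] * dt, dt, c[j], c[j - 1], c[j + 1])
            cum.append(cum[-1] + lag)
            pos.append(X.lateral_axis[i + 1])
        if len(pos) < 3:
            raise NumericalError(
                f"only {len(pos)} cumulative time-shift points survive; need >= 3"
            )
        self.cumulative_lags_ = np.asarray(cum)
        return _regress(np.asarray(pos), np.asarray(cum), self.method, self.robust)


class RadonSumEstimator(_BaseSWS):
    """Group velocity by maximizing the integrated absolute displacement
    along straight space-time trajectories t = t0 + (x - x_ref)/c.

    Candidate speeds are log-spaced over ``speed_range``; intercepts span
    the time axis (every sample by default). The reported ``r_squared`` is
    the normalized peak sharpness (peak sum minus median sum over the grid,
    divided by the peak sum) — a contrast measure in [0, 1], not a
    regression R². Resolution is limited by the speed grid; equal maxima
    resolve to the lowest speed / earliest intercept.
    """

    method = "RADON"

    def __init__(self, depth_index: int = 0, speed_range=(0.5, 8.0),
                 n_speeds: int = 201, n_intercepts: int | None = None):
        self.depth_index = depth_index
        self.speed_range = speed_range
        self.n_speeds = n_speeds
        self.n_intercepts = n_intercepts

    def candidate_speeds(self) -> np.ndarray:
        lo, hi = float(self.speed_range[0]), float(self.speed_range[1])
        if not 0 < lo < hi:
            raise SchemaError("speed_range must be positive and ordered")
        return np.geomspace(lo, hi, int(self.n_speeds))

    def _estimate(self, X: DisplacementField) -> SWSEstimate:
        traces = X.traces(self.depth_index)
        if traces.shape[0] < 3:
            raise NumericalError("need at least 3 channels")
        speeds = self.candidate_speeds()
        t = X.time_axis
        if self.n_intercepts is None:
            intercepts = t
        else:
            intercepts = np.linspace(t[0], t[-1], int(self.n_intercepts))
        dx = X.lateral_axis - X.lateral_axis[0]
        absu = np.abs(traces)
        sums = np.zeros((speeds.size, intercepts.size))
        for si, c in enumerate(speeds):
            acc = np.zeros(intercepts.size)
            for ch in range(dx.size):
                acc += np.interp(intercepts + dx[ch] / c, t, absu[ch],
                                 left=0.0, right=0.0)
            sums[si] = acc
        flat = int(np.argmax(sums))  # first max: lowest speed, earliest t0
        si, ti = np.unravel_index(flat, sums.shape)
        if si == 0 or si == speeds.size - 1:
            raise NumericalError(
                f"trajectory-sum maximum at the speed_range boundary "
                f"({speeds[si]:.3g} m/s); widen speed_range beyond "
                f"({speeds[0]:.3g}, {speeds[-1]:.3g}) m/s"
            )
        peak = sums[si, ti]
        sharp = 0.0 if peak <= 0 else float((peak - np.median(sums)) / peak)
        self.trajectory_sums_ = sums
        self.speeds_grid_ = speeds
        self.intercepts_grid_ = intercepts
        return SWSEstimate(speed=float(speeds[si]), r_squared=max(0.0, min(1.0, sharp)),
                           method=self.method, n_channels_used=int(dx.size),
                           intercept=float(intercepts[ti]))


ESTIMATORS = {
    "spm": SPMEstimator,
    "tdpm": TDPMEstimator,
    "tspm": TSPMEstimator,
    "radon": RadonSumEstimator,
}


def estimate_tspm(field: DisplacementField, depth_index: int = 0,
                  max_lag_s: float | None = None) -> SWSEstimate:
    """Functional wrapper over :class:`TSPMEstimator`."""
    return TSPMEstimator(depth_index=depth_index, max_lag_s=max_lag_s).estimate(field)


def estimate_radon(field: DisplacementField, depth_index: int = 0,
                   speed_range=(0.5, 8.0), n_speeds: int = 201,
                   n_intercepts: int | None = None) -> SWSEstimate:
    """Functional wrapper over :class:`RadonSumEstimator`."""
    return RadonSumEstimator(depth_index=depth_index, speed_range=speed_range,
                             n_speeds=n_speeds, n_intercepts=n_intercepts).estimate(field)
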