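"""Developmental time courses: smoothing, thermal time and phase calling.

Per-carpel measurements sampled on days after W9.5 (ear emergence on the
Waddington scale) are turned into cultivar-level developmental curves and a
three-phase classification of unpollinated carpel development:

* **growth** -- from W9.5 until the smoothed stigma area first reaches 85%
  of its maximum (a proxy for anthesis-equivalent receptivity);
* **peak** -- until the smoothed area falls 15% below the maximum;
* **deterioration** -- until the last sampling point, with the time of a
  40% drop reported as an additional senescence marker.

All thresholds are applied to a Loess-smoothed curve (local quadratic
regression, tricube weights, default span 0.9) evaluated on a dense grid,
with boundary times refined by linear interpolation between grid points.
Phase durations are reported both in days and in cumulative degree days
(base 0 degrees C).  Outliers are removed beforehand with the 1.5 x IQR
fence per cultivar x timepoint group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

from .synthetic import TemperatureSeries

__all__ = [
    "iqr_filter",
    "LoessSmoother",
    "loess_smooth",
    "SmoothedCurve",
    "cumulative_degree_days",
    "thermal_time_at",
    "PhaseReport",
    "classify_phases",
    "rank_cultivars",
]


# ---------------------------------------------------------------------------
# outlier filtering
# ---------------------------------------------------------------------------

def iqr_filter(data: pd.DataFrame, value_col: str,
               group_cols=("cultivar", "timepoint_days"),
               k: float = 1.5, min_group: int = 4):
    """Remove values outside [Q1 - k*IQR, Q3 + k*IQR] within each group.

    Quartiles use linear interpolation between order statistics.  Groups
    smaller than ``min_group`` pass through unfiltered.  Returns
    ``(kept, removed)`` DataFrames preserving the input row order.
    """
    keep = np.ones(len(data), dtype=bool)
    for _, idx in data.groupby(list(group_cols)).groups.items():
        vals = data.loc[idx, value_col].to_numpy(dtype=float)
        if len(vals) < min_group:
            continue
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        bad = (vals < lo) | (vals > hi)
        keep[data.index.get_indexer(idx)] &= ~bad
    return data[keep], data[~keep]


# ---------------------------------------------------------------------------
# Loess
# ---------------------------------------------------------------------------

@dataclass
class SmoothedCurve:
    """A fitted curve with pointwise 95% confidence bounds."""

    grid: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    span: float


class LoessSmoother(BaseEstimator, RegressorMixin):
    """Locally weighted quadratic regression (Loess).

    At each evaluation point the span-fraction nearest neighbours are fit
    with a degree-``degree`` polynomial under tricube weights; the pointwise
    confidence interval comes from the variance of the local fit's intercept
    under a normal approximation, with the residual variance estimated from
    the fit at the observed points.

    Parameters
    ----------
    span : fraction of points in each local window (default 0.9).
    degree : local polynomial degree (default 2).
    ci_level : coverage of the pointwise interval (default 0.95).
    """

    def __init__(self, span: float = 0.9, degree: int = 2,
                 ci_level: float = 0.95):
        self.span = span
        self.degree = degree
        self.ci_level = ci_level

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        v = np.asarray(y, dtype=float).ravel()
        if t.shape != v.shape:
            raise ValueError("times and values differ in length")
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must lie in (0, 1]")
        if np.unique(t).size < 5:
            raise ValueError("need at least 5 distinct time values")
        order = np.argsort(t, kind="stable")
        self.t_ = t[order]
        self.y_ = v[order]
        n = len(self.t_)
        self.k_ = max(int(np.ceil(self.span * n)), self.degree + 1)
        if self.k_ > n:
            raise ValueError("window larger than the data: fewer points than "
                             "the local fit's degrees of freedom")
        # residual variance from the smoother evaluated at the data points
        fits = np.array([self._local_fit(x0)[0] for x0 in self.t_])
        dof = max(n - (self.degree + 1), 1)
        self.sigma2_ = float(np.sum((self.y_ - fits) ** 2) / dof)
        return self

    def _local_fit(self, x0: float):
        """Fitted value and squared norm of the equivalent kernel at x0."""
        d = np.abs(self.t_ - x0)
        dmax = np.partition(d, self.k_ - 1)[self.k_ - 1]
        if dmax == 0:
            # all window points at x0: weighted mean of the exact ties
            sel = d == 0
            return float(self.y_[sel].mean()), 1.0 / sel.sum()
        w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
        sel = w > 0
        ts, ys, ws = self.t_[sel] - x0, self.y_[sel], w[sel]
        if sel.sum() < self.degree + 1:
            raise ValueError("fewer points than local-fit degrees of freedom")
        X = np.vander(ts, self.degree + 1, increasing=True)
        sw = np.sqrt(ws)
        A = X * sw[:, None]
        beta, *_ = np.linalg.lstsq(A, ys * sw, rcond=None)
        # equivalent-kernel row for the intercept: l = e0^T (X'WX)^-1 X'W
        XtWX = X.T @ (ws[:, None] * X)
        try:
            li = np.linalg.solve(XtWX, (ws[:, None] * X).T)[0]
        except np.linalg.LinAlgError:
            li = ws / ws.sum()
        return float(beta[0]), float(np.sum(li ** 2))

    def predict(self, X):
        grid = np.asarray(X, dtype=float).ravel()
        return np.array([self._local_fit(x0)[0] for x0 in grid])

    def predict_interval(self, X):
        """Returns (mean, ci_low, ci_high) on the evaluation grid."""
        grid = np.asarray(X, dtype=float).ravel()
        fit = np.empty(grid.size)
        se = np.empty(grid.size)
        for i, x0 in enumerate(grid):
            fit[i], lnorm2 = self._local_fit(x0)
            se[i] = np.sqrt(self.sigma2_ * lnorm2)
        z = norm.ppf(0.5 + self.ci_level / 2.0)
        return fit, fit - z * se, fit + z * se


def loess_smooth(times, values, span: float = 0.9,
                 grid=None) -> SmoothedCurve:
    """Functional wrapper over :class:`LoessSmoother`."""
    sm = LoessSmoother(span=span).fit(times, values)
    if grid is None:
        grid = np.arange(sm.t_.min(), sm.t_.max() + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    mean, lo, hi = sm.predict_interval(grid)
    return SmoothedCurve(grid=grid, mean=mean, ci_low=lo, ci_high=hi, span=span)


# ---------------------------------------------------------------------------
# degree days
# ---------------------------------------------------------------------------

def cumulative_degree_days(series: TemperatureSeries, start_index: int,
                           end_index: int) -> float:
    """Sum of daily means clamped at the 0 degC base, inclusive of both ends."""
    n = len(series)
    if not (0 <= start_index <= end_index < n):
        raise IndexError(f"window [{start_index}, {end_index}] outside the "
                         f"{n}-day series")
    vals = np.maximum(series.daily_mean[start_index:end_index + 1], 0.0)
    return float(vals.sum())


def thermal_time_at(series: TemperatureSeries, t_days: float,
                    start_index: int = 0) -> float:
    """Cumulative degree days accrued from day 0 up to fractional day t.

    Linear interpolation within the day: whole days contribute their full
    clamped mean, the final fractional day contributes proportionally.
    """
    if t_days < 0:
        raise ValueError("t_days must be non-negative")
    clamped = np.maximum(series.daily_mean[start_index:], 0.0)
    if t_days > len(clamped):
        raise IndexError("t_days extends past the end of the temperature series")
    whole = int(np.floor(t_days))
    out = float(clamped[:whole].sum())
    frac = t_days - whole
    if frac > 0:
        out += frac * float(clamped[whole])
    return out


# ---------------------------------------------------------------------------
# phase classification
# ---------------------------------------------------------------------------

@dataclass
class PhaseReport:
    """Phase boundaries and durations for one cultivar x season."""

    cultivar: str
    growth_end: float | None
    peak_onset: float
    peak_end: float | None
    deterioration_marker_40pct: float | None
    last_sampling: float
    durations_days: dict = field(default_factory=dict)
    durations_degree_days: dict = field(default_factory=dict)
    censored: set = field(default_factory=set)
    season: str = ""


def _first_crossing(grid, vals, level, start_idx, direction):
    """Earliest grid time >= grid[start_idx] where vals crosses `level`.

    direction +1: first time vals >= level; -1: first time vals <= level.
    Linear interpolation between the bracketing grid points.  None if the
    level is never reached.
    """
    g, v = grid[start_idx:], vals[start_idx:]
    ok = v >= level if direction > 0 else v <= level
    if not ok.any():
        return None
    i = int(np.argmax(ok))
    if i == 0:
        return float(g[0])
    t0, t1, v0, v1 = g[i - 1], g[i], v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def classify_phases(stigma_curve: SmoothedCurve,
                    ovary_curve: SmoothedCurve | None = None,
                    temperature: TemperatureSeries | None = None,
                    last_sampling: float | None = None,
                    cultivar: str = "", season: str = "",
                    growth_threshold: float = 0.85,
                    peak_drop: float = 0.15,
                    deterioration_drop: float = 0.40) -> PhaseReport:
    """Partition a smoothed stigma-area curve into growth/peak/deterioration.

    The ovary curve is accepted for completeness of the report but does not
    enter any boundary rule -- all three boundaries are defined on stigma
    area relative to its smoothed maximum.
    """
    grid = np.asarray(stigma_curve.grid, dtype=float)
    vals = np.asarray(stigma_curve.mean, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values in the smoothed stigma curve")
    if last_sampling is None:
        last_sampling = float(grid[-1])
    if grid[0] > 0 or grid[-1] < last_sampling - 1e-9:
        raise ValueError("stigma curve must cover [0, last_sampling]")
    sel = grid <= last_sampling + 1e-9
    grid, vals = grid[sel], vals[sel]

    s_max = float(vals.max())
    i_peak = int(np.argmax(vals))
    peak_onset = float(grid[i_peak])

    growth_end = _first_crossing(grid[:i_peak + 1], vals[:i_peak + 1],
                                 growth_threshold * s_max, 0, +1)
    peak_end = _first_crossing(grid, vals, (1.0 - peak_drop) * s_max,
                               i_peak, -1)
    marker = _first_crossing(grid, vals, (1.0 - deterioration_drop) * s_max,
                             i_peak, -1)
    censored = set()
    if peak_end is None:
        censored.add("peak_end")
    if marker is None:
        censored.add("deterioration_marker_40pct")

    durations_days = {
        "growth": growth_end if growth_end is not None else None,
        "peak": (peak_end - growth_end
                 if peak_end is not None and growth_end is not None else None),
        "deterioration": (last_sampling - peak_end
                          if peak_end is not None else None),
    }
    durations_dd: dict = {}
    if temperature is not None:
        tt = lambda t: thermal_time_at(temperature, t)
        bounds = {"growth": (0.0, growth_end),
                  "peak": (growth_end, peak_end),
                  "deterioration": (peak_end, last_sampling)}
        for name, (a, b) in bounds.items():
            durations_dd[name] = (tt(b) - tt(a)
                                  if a is not None and b is not None else None)

    return PhaseReport(
        cultivar=cultivar, season=season,
        growth_end=growth_end, peak_onset=peak_onset, peak_end=peak_end,
        deterioration_marker_40pct=marker, last_sampling=last_sampling,
        durations_days=durations_days, durations_degree_days=durations_dd,
        censored=censored,
    )


def rank_cultivars(reports) -> pd.DataFrame:
    """Order cultivars from slow- to fast-developing carpels.

    Sorted by the onset of the deterioration phase (peak_end) descending:
    the latest onset is the slowest developer.  Censored boundaries rank as
    slower than any observed value; ties break on the 40%-drop marker, then
    on the cultivar label.  With exactly three cultivars the conventional
    slow / moderate / fast labels are attached.
    """
    reports = list(reports)
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to rank")
    seasons = {r.season for r in reports}
    if len(seasons) > 1:
        raise ValueError(f"reports span multiple seasons: {sorted(seasons)}")

    inf = float("inf")
    def key(r: PhaseReport):
        pe = inf if r.peak_end is None else r.peak_end
        mk = inf if r.deterioration_marker_40pct is None \
            else r.deterioration_marker_40pct
        return (-pe, -mk, r.cultivar)

    ordered = sorted(reports, key=key)
    labels = (["slow", "moderate", "fast"] if len(ordered) == 3
              else [f"rank_{i + 1}" for i in range(len(ordered))])
    return pd.DataFrame({
        "rank": np.arange(1, len(ordered) + 1),
        "cultivar": [r.cultivar for r in ordered],
        "peak_end": [r.peak_end for r in ordered],
        "deterioration_marker_40pct": [r.deterioration_marker_40pct
                                       for r in ordered],
        "tempo": labels,
    })
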