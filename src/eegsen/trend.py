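"""Linear trend and moving average of an entropy series.

The preictal trend is quantified by an ordinary least-squares line of SEN
on time (minutes relative to onset) over the half-open fit interval
[-32, -4) min, together with the Pearson correlation r of the same points.
The final 4 minutes before onset are excluded from the fit because entropy
can rise steeply there.  For visualization a centered moving mean with a
4-minute span (up to 15 windows at 16 s spacing) is computed over the whole
series.

Missing (NaN) entropy windows are excluded from both computations rather
than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .entropy import EntropySeries
from .errors import InsufficientDataError

__all__ = [
    "TrendSummary",
    "MovingAverageSeries",
    "DEFAULT_FIT_INTERVAL_MIN",
    "fit_trend",
    "moving_average",
]

DEFAULT_FIT_INTERVAL_MIN: tuple[float, float] = (-32.0, -4.0)


@dataclass(frozen=True)
class TrendSummary:
    """OLS slope/intercept and Pearson correlation of SEN against time.

    ``slope_per_min`` is in entropy units per minute.  A degenerate fit
    (zero SEN variance) reports slope 0 with ``degenerate=True`` and r = 0.
    """

    band: str
    slope_per_min: float
    intercept: float
    r: float
    stderr: float
    n_points: int
    fit_interval_min: tuple[float, float] = DEFAULT_FIT_INTERVAL_MIN
    degenerate: bool = False
    record_id: str = "record"

    @property
    def abs_r(self) -> float:
        return abs(self.r)


@dataclass
class MovingAverageSeries:
    """Centered moving mean of an entropy series."""

    band: str
    times_min_rel_onset: np.ndarray
    value: np.ndarray
    window_min: float

    def __post_init__(self) -> None:
        if len(self.times_min_rel_onset) != len(self.value):
            raise ValueError("times and values must have the same length")


def fit_trend(
    series: EntropySeries,
    interval_min: tuple[float, float] = DEFAULT_FIT_INTERVAL_MIN,
) -> TrendSummary:
    """Fit the regression line over the half-open interval [lo, hi) minutes.

    Points outside the interval and NaN windows are excluded.  Requires at
    least 3 usable points.
    """
    lo, hi = interval_min
    t = series.times_min_rel_onset
    y = series.sen
    mask = (t >= lo) & (t < hi) & np.isfinite(y)
    t, y = t[mask], y[mask]
    if t.size < 3:
        raise InsufficientDataError(
            f"{t.size} usable points in [{lo}, {hi}) min; need >= 3"
        )
    if np.ptp(y) == 0.0:
        return TrendSummary(
            band=series.band,
            slope_per_min=0.0,
            intercept=float(y[0]),
            r=0.0,
            stderr=0.0,
            n_points=int(t.size),
            fit_interval_min=(lo, hi),
            degenerate=True,
            record_id=series.record_id,
        )
    res = stats.linregress(t, y)
    return TrendSummary(
        band=series.band,
        slope_per_min=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        stderr=float(res.stderr),
        n_points=int(t.size),
        fit_interval_min=(lo, hi),
        record_id=series.record_id,
    )


def moving_average(series: EntropySeries, window_min: float = 4.0) -> MovingAverageSeries:
    """Centered moving mean over all windows within +/- window_min/2.

    Output times equal the input times; edge points average the available
    one-sided neighborhood.  NaN inputs are skipped; an output point with no
    finite neighbors is NaN.
    """
    t = series.times_min_rel_onset
    y = series.sen
    if t.size == 0:
        return MovingAverageSeries(series.band, t.copy(), y.copy(), window_min)
    if t.size > 1 and window_min <= np.min(np.diff(t)):
        raise ValueError("averaging window must exceed the window spacing")
    half = window_min / 2.0 + 1e-9  # tolerate float jitter at the boundary
    out = np.full(t.size, np.nan)
    for i, ti in enumerate(t):
        sel = np.abs(t - ti) <= half
        vals = y[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[i] = vals.mean()
    return MovingAverageSeries(series.band, t.copy(), out, window_min)
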