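"""Rate estimation from time courses.

All rates are estimated the way the source experiments report them: a
straight line is fitted by ordinary least squares to the natural log of the
measured series against time ("semi-logarithmic plot"), and r² is the
squared Pearson correlation on that log scale.  Specific growth rate is the
same fit applied to OD600 or total-cell series; the adsorption rate
constant divides the decay slope of unadsorbed phage by the cell density;
time to stationary interpolates the first crossing of (1 − ε) × plateau.

Zeros inside a fitting window cannot enter a log fit; they are excluded and
the exclusion count is recorded on the fit (and logged), never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .data_model import (DataError, Entity, EstimationError, FitError,
                         TimeCourse)

logger = logging.getLogger(__name__)

#: default growth-fit window: maximal prefix below this fraction of plateau
GROWTH_WINDOW_FRACTION = 0.40


@dataclass
class RateFit:
    """A fitted exponential rate with its provenance.

    ``slope`` is per hour (per minute for adsorption-assay fits);
    ``window`` is the (t_start, t_end) actually used; ``n_excluded`` counts
    zero-valued points dropped from the log fit.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    window: tuple[float, float]
    stderr: float
    unit: str = "1/h"
    n_excluded: int = 0


def _ols_log(times: np.ndarray, values: np.ndarray, unit: str,
             n_excluded: int) -> RateFit:
    if len(times) < 2:
        raise FitError(f"need >= 2 positive points for a semi-log fit, "
                       f"got {len(times)}")
    logs = np.log(values)
    res = sps.linregress(times, logs)
    # constant series: slope 0 with undefined correlation -> r^2 = 0
    r2 = 0.0 if math.isnan(res.rvalue) else float(res.rvalue ** 2)
    stderr = 0.0 if math.isnan(res.stderr) else float(res.stderr)
    return RateFit(float(res.slope), float(res.intercept), r2, len(times),
                   (float(times[0]), float(times[-1])), stderr, unit,
                   n_excluded)


def semilog_rate(tc: TimeCourse,
                 window: Optional[tuple[float, float]] = None,
                 unit: str = "1/h") -> RateFit:
    """OLS slope of ln(value) vs time, the amplification/infection rate.

    ``window`` restricts the fit to an inclusive time interval.  Points with
    value 0 inside the window are excluded (count recorded and logged).
    """
    t, v = tc.times, tc.values
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, v = t[mask], v[mask]
    positive = v > 0
    n_excluded = int(np.sum(~positive))
    if n_excluded:
        logger.info("semilog_rate: excluded %d zero-valued point(s) from the "
                    "log fit of %s", n_excluded, tc.entity.value)
    t, v = t[positive], v[positive]
    return _ols_log(t, v, unit, n_excluded)


def default_growth_window(tc: TimeCourse,
                          fraction: float = GROWTH_WINDOW_FRACTION
                          ) -> tuple[float, float]:
    """Maximal prefix of the series with values below ``fraction`` × plateau.

    The plateau is the mean of the final three points.  Used when no window
    is supplied for a growth fit, and reported in the resulting RateFit.
    """
    if len(tc) < 2:
        raise FitError("need >= 2 points to choose a growth window")
    plateau = float(np.mean(tc.values[-3:]))
    below = tc.values < fraction * plateau
    if not below[0]:
        return (float(tc.times[0]), float(tc.times[-1]))
    k = int(np.argmin(below)) if not below.all() else len(tc)
    return (float(tc.times[0]), float(tc.times[k - 1]))


def specific_growth_rate(tc: TimeCourse,
                         window: Optional[tuple[float, float]] = None) -> RateFit:
    """Specific growth rate μ (per hour) from an OD600 or total-cell series.

    Identical to :func:`semilog_rate`; when no window is given the maximal
    prefix below 40% of the plateau is used so the fit stays in the
    exponential phase of a saturating (glucose-limited) curve.
    """
    if tc.entity not in (Entity.OD600, Entity.TOTAL_CELLS):
        raise DataError("specific growth rate expects an od600 or total_cells "
                        f"series, got {tc.entity.value}")
    if window is None:
        window = default_growth_window(tc)
    return semilog_rate(tc, window=window)


def time_to_stationary(tc: TimeCourse, epsilon: float = 0.05) -> float:
    """Earliest time (h) the series reaches (1 − ε) × plateau.

    The plateau is the mean of the final three points; the last value must
    itself lie within ε of the series maximum (otherwise the culture never
    saturated and the estimate is undefined).  The crossing is linearly
    interpolated between samples.
    """
    if len(tc) < 3:
        raise EstimationError("need >= 3 points to detect a plateau")
    tail = tc.values[-3:]
    plateau = float(np.mean(tail))
    # the culture must actually have saturated: the final points are flat
    if float(np.ptp(tail)) > epsilon * plateau + 1e-12:
        raise EstimationError("series does not end on a plateau")
    threshold = (1 - epsilon) * plateau
    above = tc.values >= threshold * (1 - 1e-12)
    if not above.any():
        raise EstimationError("series never reaches the plateau threshold")
    k = int(np.argmax(above))
    if k == 0:
        return float(tc.times[0])
    t0, t1 = tc.times[k - 1], tc.times[k]
    v0, v1 = tc.values[k - 1], tc.values[k]
    if v1 == v0:
        return float(t1)
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))


def adsorption_rate_constant(tc: TimeCourse, cell_density: float) -> RateFit:
    """Adsorption rate constant k (ml/cells/min) from unadsorbed-phage decay.

    The series times are in **minutes**; k = −slope(ln P vs t) / cell
    density, so that P(t) = P₀·exp(−k·C·t) under mass action.
    """
    if not cell_density > 0:
        raise DataError(f"cell_density must be > 0, got {cell_density!r}")
    fit = semilog_rate(tc, unit="1/min")
    k = -fit.slope / cell_density
    return RateFit(k, fit.intercept, fit.r_squared, fit.n_points, fit.window,
                   fit.stderr / cell_density, "ml/cells/min", fit.n_excluded)


def infection_ratio(infected: TimeCourse, total: TimeCourse,
                    at_time: float) -> float:
    """Infected / total cell density at a time point (nearest sample)."""
    num = infected.value_at(at_time)
    den = total.value_at(at_time)
    if den == 0:
        raise DataError(f"total cell density is 0 at t={at_time:g} h")
    return num / den
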