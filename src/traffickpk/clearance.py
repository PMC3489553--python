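"""Log-linear blood clearance: half-time and initial volume of distribution.

Blood disappearance of labeled lymphocytes is modeled as a single
mono-exponential phase, fitted by ordinary least squares of
log10(%Inj/ml) on time.  The half-time is log10(2) / (-slope) — the time
for the blood level to halve — and the initial volume of distribution is
Vd = 100 / 10**intercept, the apparent volume the whole dose would occupy
at the blood concentration extrapolated to t = 0 (%Inj/ml at t=0 is
10**intercept, and 100% of the dose divided by that concentration gives ml).

A fit is classified as showing no measurable clearance when the slope is
non-negative or the regression is not significant at the configured alpha,
which mirrors how a flat blood curve (steady state between entry to and
exit from the circulation) presents in practice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ClearanceFit",
    "fit_clearance",
    "half_time_from_slope",
    "vd_from_intercept",
    "circulating_fraction",
    "LOG10_2",
]

#: log10(2); quoted as 0.301 in the user-facing formula half_time = 0.301/(-slope)
LOG10_2 = math.log10(2.0)

CLEARED = "cleared"
NO_CLEARANCE = "no_measurable_clearance"


@dataclass(frozen=True)
class ClearanceFit:
    """A fitted log10-linear blood-clearance model.

    ``half_time_min`` is NaN when the slope is non-negative (no measurable
    clearance).  ``r`` is the signed Pearson correlation of the regression;
    its absolute value is available as ``abs_r``.
    """

    slope: float  # log10(%Inj/ml) per min
    intercept: float  # log10(%Inj/ml) at t = 0
    r: float
    p_value: float
    n_points: int
    half_time_min: float
    vd_ml: float
    window: Tuple[float, float]
    classification: str
    alpha: float = 0.05

    @property
    def abs_r(self) -> float:
        return abs(self.r)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "abs_r": self.abs_r,
            "p_value": self.p_value,
            "n_points": self.n_points,
            "half_time_min": self.half_time_min,
            "vd_ml": self.vd_ml,
            "window": list(self.window),
            "classification": self.classification,
            "alpha": self.alpha,
        }


def half_time_from_slope(slope: float) -> float:
    """Half-time (min) from the log10 slope: log10(2) / (-slope).

    Returns NaN for a non-negative slope (no measurable clearance); in
    batch use the missing value is recorded rather than raising.
    """
    if slope >= 0:
        return math.nan
    return LOG10_2 / (-slope)


def vd_from_intercept(intercept: float) -> float:
    """Initial volume of distribution (ml): 100 / 10**intercept."""
    return 100.0 / (10.0 ** intercept)


def circulating_fraction(vd_ml: float, vascular_volume_ml: float = 2.0) -> Tuple[float, float]:
    """Split the dose between blood and tissue beds at t = 0.

    Returns ``(in_blood_pct, in_tissue_pct)`` where in_blood is
    100 * vascular volume / Vd.  If Vd is smaller than the vascular volume
    the blood share is capped at 100% with a warning.
    """
    if not vascular_volume_ml > 0:
        raise ValueError("vascular_volume_ml must be > 0")
    if vd_ml < vascular_volume_ml:
        logger.warning(
            "Vd %.3g ml smaller than vascular volume %.3g ml; capping blood share at 100%%",
            vd_ml,
            vascular_volume_ml,
        )
        return 100.0, 0.0
    in_blood = 100.0 * vascular_volume_ml / vd_ml
    return in_blood, 100.0 - in_blood


def fit_clearance(
    times_min: Sequence[float],
    pct_inj_per_ml: Sequence[float],
    window: Optional[Tuple[float, float]] = None,
    *,
    drop_first_point: bool = False,
    alpha: float = 0.05,
) -> ClearanceFit:
    """Fit log10(%Inj/ml) against time by ordinary least squares.

    Parameters
    ----------
    times_min, pct_inj_per_ml
        Paired observations; replicates at the same time are fitted as
        individual points, not averaged.
    window
        Optional (t_min, t_max) restricting the fit to the linear portion;
        by default all points are used.
    drop_first_point
        Drop all observations at the earliest time inside the window (used
        when the first time point sits off the linear phase).
    alpha
        Significance level for the no-measurable-clearance classification.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(pct_inj_per_ml, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and levels must have the same length")
    if window is not None:
        lo, hi = window
        keep = (t >= lo) & (t <= hi)
        t, y = t[keep], y[keep]
    else:
        lo, hi = (float(t.min()), float(t.max())) if t.size else (math.nan, math.nan)
    if drop_first_point and t.size:
        keep = t > t.min()
        t, y = t[keep], y[keep]
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need at least 2 points with distinct times inside the window")
    if np.any(y <= 0):
        raise ValueError("all %Inj/ml values must be > 0 to take logarithms")

    logy = np.log10(y)
    if np.ptp(logy) == 0.0:
        # perfectly flat series: slope 0, no correlation with time
        slope, intercept, r, p = 0.0, float(logy[0]), 0.0, 1.0
    else:
        res = stats.linregress(t, logy)
        slope, intercept, r, p = res.slope, res.intercept, res.rvalue, res.pvalue

    half_time = half_time_from_slope(slope)
    vd = vd_from_intercept(intercept)
    classification = CLEARED if (slope < 0 and p < alpha) else NO_CLEARANCE
    return ClearanceFit(
        slope=float(slope),
        intercept=float(intercept),
        r=float(r),
        p_value=float(p),
        n_points=int(t.size),
        half_time_min=float(half_time),
        vd_ml=float(vd),
        window=(float(lo), float(hi)),
        classification=classification,
        alpha=alpha,
    )
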