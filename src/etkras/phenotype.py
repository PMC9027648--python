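"""Deterministic phenotype calculators.

Growth rate and doubling time from cell counts, caspase-activity
normalization, and four-parameter logistic (4PL) dose–response fitting.

Growth uses the two-point formula rate = ln(N(t)/N(0)) / t by default
(doubling_time = ln(2)/rate), with an optional log-linear regression mode
over all time points.  EC50/IC50 denote the same fitted quantity: the
inflection concentration of the 4PL curve.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class GrowthFit:
    rate: float              # per hour
    doubling_time: float     # hours; inf when rate == 0
    n0: float
    r_squared: float


@dataclass
class DoseResponseFit:
    ec50: float
    hill: float
    top: float
    bottom: float
    rss: float


def growth_rate(counts: pd.DataFrame, endpoint_only: bool = True) -> GrowthFit:
    """Growth rate and doubling time from a (time_h, cells) table.

    Endpoint mode: rate = ln(N(t_final)/N(t_0)) / (t_final - t_0).
    Regression mode: least-squares slope of ln(cells) vs time.
    """
    t = counts["time_h"].to_numpy(dtype=float)
    n = counts["cells"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 time points")
    if np.any(n <= 0):
        raise ValueError("cell counts must be positive")
    log_n = np.log(n)
    if endpoint_only:
        span = t[-1] - t[0]
        if span <= 0:
            raise ValueError("final time must exceed the first time point")
        rate = (log_n[-1] - log_n[0]) / span
        n0 = n[0]
    else:
        fit = stats.linregress(t, log_n)
        rate, n0 = float(fit.slope), float(math.exp(fit.intercept))
    pred = np.log(n0) + rate * (t - (0.0 if not endpoint_only else t[0]))
    if endpoint_only:
        pred = log_n[0] + rate * (t - t[0])
    ss_res = float(((log_n - pred) ** 2).sum())
    ss_tot = float(((log_n - log_n.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    doubling = math.inf if rate == 0 else math.log(2) / rate
    return GrowthFit(rate=float(rate), doubling_time=float(doubling),
                     n0=float(n0), r_squared=r2)


def caspase_activity(
    fluorescence_delta: float,
    protein_ug: float,
    hours: float,
    blank: float = 0.0,
) -> float:
    """Caspase activity as delta-FU per microgram protein per hour.

    The substrate-free blank is subtracted first.  A blank above the signal
    yields a negative activity (returned with a warning, not clipped).
    """
    if protein_ug <= 0:
        raise ValueError("protein_ug must be positive")
    if hours <= 0:
        raise ValueError("hours must be positive")
    value = (fluorescence_delta - blank) / protein_ug / hours
    if value < 0:
        logger.warning("blank (%g) exceeds signal (%g): negative activity",
                       blank, fluorescence_delta)
    return value


def four_pl(dose: np.ndarray, ec50: float, hill: float,
            top: float, bottom: float) -> np.ndarray:
    """4PL response: bottom + (top - bottom) / (1 + (dose/ec50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, dose / ec50, 0.0)
        resp = bottom + (top - bottom) / (1.0 + ratio**hill)
    return np.where(dose > 0, resp, top)


def fit_ec50(
    doses: Sequence[float],
    viability: Sequence[float],
    fixed_asymptotes: tuple[float, float] | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start initialization over EC50.

    ``fixed_asymptotes`` pins (top, bottom); otherwise both are free.  The
    EC50 is reported on the original concentration scale.  Data with no
    discernible dose–response transition (flat within noise) raise an
    error carrying the best residual sum of squares.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viability, dtype=float)
    if len(d) != len(v):
        raise ValueError("doses and viability must have equal length")
    if len(np.unique(d)) < 4:
        raise ValueError("need at least 4 distinct dose levels")
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    pos = d[d > 0]
    span = v.max() - v.min()
    if span <= 1e-12 * max(1.0, abs(float(v.max()))):
        raise ValueError(f"no dose-response transition (flat data, rss=0)")

    lo, hi = pos.min(), pos.max()
    starts = np.geomspace(lo, hi, 7)
    best: tuple[float, np.ndarray] | None = None

    if fixed_asymptotes is not None:
        top0, bot0 = fixed_asymptotes
        if bot0 > top0:
            raise ValueError("bottom asymptote exceeds top")

        def resid(theta):
            log_ec50, hill = theta
            return four_pl(d, math.exp(log_ec50), hill, top0, bot0) - v

        for ec0 in starts:
            sol = optimize.least_squares(resid, x0=[math.log(ec0), 1.0])
            rss = float((sol.fun**2).sum())
            if best is None or rss < best[0]:
                best = (rss, sol.x)
        rss, x = best
        ec50, hill = math.exp(x[0]), float(x[1])
        top, bottom = float(top0), float(bot0)
    else:

        def resid(theta):
            log_ec50, hill, top, bottom = theta
            return four_pl(d, math.exp(log_ec50), hill, top, bottom) - v

        for ec0 in starts:
            sol = optimize.least_squares(
                resid, x0=[math.log(ec0), 1.0, float(v.max()), float(v.min())]
            )
            rss = float((sol.fun**2).sum())
            if best is None or rss < best[0]:
                best = (rss, sol.x)
        rss, x = best
        ec50, hill = math.exp(x[0]), float(x[1])
        top, bottom = float(x[2]), float(x[3])
        if bottom > top:  # reflected solution: swap and flip the slope
            top, bottom, hill = bottom, top, -hill

    fitted_span = abs(top - bottom)
    if fitted_span <= 0.02 * max(abs(top), 1.0):
        raise ValueError(f"no dose-response transition (rss of best fit: {rss:.4g})")
    return DoseResponseFit(ec50=float(ec50), hill=hill, top=top,
                           bottom=bottom, rss=rss)
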