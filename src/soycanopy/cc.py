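"""Logistic canopy-coverage model.

Canopy coverage (CC) is the fraction of ground area covered by green
canopy in nadir view, measured repeatedly over days after emergence
(DAE).  Each plot's trajectory is modelled with a three-parameter
logistic

    CC(t) = L / (1 + exp(-k (t - t0)))

where ``L`` is the asymptotic coverage (fraction), ``k`` the growth
steepness (per day) and ``t0`` the inflection day.  Derived summaries:

* ``ACC``   — season-average coverage, the time-average of the fitted
  curve over a window (closed form via the logistic antiderivative).
* ``CC50``  — day at which half the asymptote is reached; identically
  the fitted ``t0``.
* ``CCR2``  — fitted coverage on the plot's R2 (full bloom) date.
* ``MCC_d`` — maximum daily rate of coverage gain, ``100 L k / 4`` %/day.
* ``MCC_w`` — maximum gain over any 7-day sliding window, %/week.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "CCSeries",
    "CCFit",
    "DegenerateSeriesError",
    "logistic",
    "fit_cc",
    "acc",
    "mcc_d",
    "mcc_w",
    "cc_at",
    "rate_profile",
]


class DegenerateSeriesError(ValueError):
    """Raised when a CC series carries no usable growth signal."""


@dataclass(frozen=True)
class CCSeries:
    """One plot's canopy-coverage trajectory.

    ``dae`` must be strictly increasing; ``cc`` values are fractions in
    [0, 1] (out-of-range values are clipped with a warning at
    construction).
    """

    accession: str
    year: int
    block: int
    dae: np.ndarray
    cc: np.ndarray

    def __post_init__(self) -> None:
        dae = np.asarray(self.dae, dtype=float)
        cc = np.asarray(self.cc, dtype=float)
        if dae.size != cc.size:
            raise ValueError("dae and cc must have equal length")
        if dae.size and np.any(np.diff(dae) <= 0):
            raise ValueError("dae must be strictly increasing")
        if np.any((cc < 0) | (cc > 1)):
            logger.warning(
                "CC values outside [0, 1] in %s/%s/%s clipped",
                self.accession, self.year, self.block,
            )
            cc = np.clip(cc, 0.0, 1.0)
        object.__setattr__(self, "dae", dae)
        object.__setattr__(self, "cc", cc)


@dataclass
class CCFit:
    """Fitted logistic parameters and derived coverage summaries."""

    L: float
    k: float
    t0: float
    window: tuple[float, float]
    acc: float = math.nan
    cc50: float = math.nan
    mcc_d: float = math.nan
    mcc_w: float = math.nan
    ccr2: float = math.nan
    adj_r2: float = math.nan
    aic: float = math.nan
    converged: bool = True
    flags: list[str] = field(default_factory=list)


def logistic(t, L: float, k: float, t0: float):
    """Three-parameter logistic curve ``L * sigmoid(k (t - t0))``."""
    return L * expit(k * (np.asarray(t, dtype=float) - t0))


def fit_cc(series: CCSeries, window: tuple[float, float] | None = None) -> CCFit:
    """Least-squares logistic fit of one plot's CC trajectory.

    Requires at least four distinct measurement days and at least one
    coverage value >= 0.2 (a flatline near zero carries no growth
    signal and raises :class:`DegenerateSeriesError`).  Bounds:
    ``L in (0, 1.05]``, ``k in (0, 2]``, ``t0`` within the observed day
    range +-30.  Non-convergence returns a flagged fit rather than
    propagating silent NaNs.

    ``window`` is the ACC averaging window; defaults to the first and
    last measurement days.
    """
    t, y = series.dae, series.cc
    if np.unique(t).size < 4:
        raise DegenerateSeriesError("need >= 4 distinct measurement days")
    if float(np.max(y, initial=0.0)) < 0.2:
        raise DegenerateSeriesError("no coverage signal (all cc < 0.2)")
    if window is None:
        window = (float(t[0]), float(t[-1]))

    lo = (1e-6, 1e-6, float(t[0]) - 30.0)
    hi = (1.05, 2.0, float(t[-1]) + 30.0)
    # midpoint of the observed rise as the t0 start value
    half = 0.5 * float(np.max(y))
    p0 = (
        min(max(float(np.max(y)), 0.05), 1.0),
        0.15,
        float(np.interp(half, y, t)) if np.any(y >= half) else float(np.median(t)),
    )
    p0 = tuple(np.clip(p0, lo, hi))

    fit = CCFit(L=math.nan, k=math.nan, t0=math.nan, window=window)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                logistic, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
    except RuntimeError as exc:  # no convergence
        fit.converged = False
        fit.flags.append(f"nonconvergence: {exc}")
        return fit

    L, k, t0 = (float(v) for v in popt)
    resid = y - logistic(t, L, k, t0)
    n, p = y.size, 3
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    adj_r2 = 1.0 - (sse / max(n - p, 1)) / (sst / (n - 1)) if sst > 0 else math.nan
    aic = n * math.log(max(sse / n, 1e-300)) + 2 * (p + 1)

    fit.L, fit.k, fit.t0 = L, k, t0
    fit.adj_r2, fit.aic = adj_r2, aic
    fit.cc50 = t0
    fit.acc = acc(fit, *window)
    fit.mcc_d = mcc_d(fit)
    fit.mcc_w = mcc_w(fit, window if window[1] - window[0] > 7 else (t0 - 30, t0 + 30))
    return fit


def _antideriv(t: float, L: float, k: float, t0: float) -> float:
    """Antiderivative of the logistic: (L/k) * log(1 + exp(k (t - t0)))."""
    return L / k * float(np.logaddexp(0.0, k * (t - t0)))


def acc(fit: CCFit, t_start: float, t_end: float) -> float:
    """Time-average of the fitted curve over ``[t_start, t_end]``.

    Closed form: ``(F(t_end) - F(t_start)) / (t_end - t_start)`` with
    ``F(t) = (L/k) ln(1 + e^{k(t-t0)})``.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    L, k, t0 = fit.L, fit.k, fit.t0
    return (_antideriv(t_end, L, k, t0) - _antideriv(t_start, L, k, t0)) / (
        t_end - t_start
    )


def mcc_d(fit: CCFit) -> float:
    """Maximum daily rate of coverage gain, ``100 L k / 4`` %/day.

    The logistic derivative peaks at ``t0`` with value ``L k / 4``.
    """
    return 100.0 * fit.L * fit.k / 4.0


def mcc_w(fit: CCFit, season_window: tuple[float, float], step: float = 0.1) -> float:
    """Maximum coverage gain over a 7-day sliding window, %/week.

    Maximizes ``100 [CC(t+7) - CC(t)]`` over window start times on a
    fine grid (default 0.1-day step).  For a logistic the maximizer is
    ``t0 - 3.5``, giving ``100 L [sigma(3.5 k) - sigma(-3.5 k)]``.
    """
    t_start, t_end = season_window
    if t_end - t_start <= 7:
        raise ValueError("season window must be longer than 7 days")
    starts = np.arange(t_start, t_end - 7 + step / 2, step)
    gains = logistic(starts + 7.0, fit.L, fit.k, fit.t0) - logistic(
        starts, fit.L, fit.k, fit.t0
    )
    return 100.0 * float(np.max(gains))


def cc_at(fit: CCFit, t: float) -> float:
    """Fitted coverage at day ``t`` (used for CCR2 at the plot R2 date)."""
    return float(logistic(t, fit.L, fit.k, fit.t0))


def rate_profile(series: CCSeries) -> list[tuple[float, float]]:
    """Between-date coverage rates as (interval midpoint, slope %/day).

    Successive finite differences ``100 (cc_{i+1} - cc_i) /
    (dae_{i+1} - dae_i)``; duplicate days are rejected by the series
    invariant.
    """
    t, y = series.dae, series.cc
    if t.size < 2:
        raise ValueError("need >= 2 measurement days")
    mids = 0.5 * (t[1:] + t[:-1])
    slopes = 100.0 * np.diff(y) / np.diff(t)
    return list(zip(mids.tolist(), slopes.tolist()))
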