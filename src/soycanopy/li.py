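"""Within-canopy light-interception profile model.

A line quantum sensor measures photosynthetically active radiation
(PAR) at 0.1 m height increments from the ground to the canopy top.
Transmittance at each height is tPAR = TPAR / iPAR (transmitted over
incident PAR above the canopy).  Because plant heights differ between
accessions, heights are normalized to the plant's own height so every
profile lives on [0, 1].

The transmittance profile is modelled with a constrained logistic that
is pinned to full transmittance at the canopy top:

    T(h) = sigmoid(k_li (h - h0)) / sigmoid(k_li (1 - h0)),   T(1) = 1

with steepness ``k_li`` (per unit normalized height) and unconstrained
half-transition height ``h0``.  Derived light-environment summaries:

* ``PARG``   = T(0), transmittance at the ground;
* ``PAR50H`` = T(0.5), transmittance at half plant height;
* ``H50PAR`` = the normalized height where T = 0.5 (NA when even the
  ground receives more than 50% of incident light).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "LIProfile",
    "LIFit",
    "compute_tpar",
    "transmittance",
    "fit_li",
    "derive_li_params",
]

# below this fitted steepness the canopy is effectively transparent
_TRANSPARENT_K = 1e-3


@dataclass(frozen=True)
class LIProfile:
    """Height-resolved transmittance for one plot.

    ``heights`` are metres from the ground (increasing); readings above
    ``plant_height`` are discarded before normalization.
    """

    accession: str
    year: int
    block: int
    heights: np.ndarray
    tpar: np.ndarray
    plant_height: float

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        t = np.asarray(self.tpar, dtype=float)
        if h.size != t.size:
            raise ValueError("heights and tpar must have equal length")
        if np.any(h < 0) or np.any(np.diff(h) <= 0):
            raise ValueError("heights must be non-negative and increasing")
        if self.plant_height <= 0:
            raise ValueError("plant_height must be positive")
        keep = h <= self.plant_height + 1e-9
        h, t = h[keep], np.clip(t[keep], 0.0, 1.0)
        object.__setattr__(self, "heights", h)
        object.__setattr__(self, "tpar", t)

    @property
    def normalized_heights(self) -> np.ndarray:
        return np.minimum(self.heights / self.plant_height, 1.0)


@dataclass
class LIFit:
    """Constrained-logistic transmittance fit and derived parameters."""

    k_li: float
    h0: float
    parg: float = math.nan
    par50h: float = math.nan
    h50par: float = math.nan      # NaN encodes "never blocked to 50%"
    adj_r2: float = math.nan
    converged: bool = True
    flags: list[str] = field(default_factory=list)


def compute_tpar(tpar_raw: float, ipar: float) -> float:
    """Transmittance fraction TPAR/iPAR, clipped to [0, 1].

    ``ipar`` must be positive; readings exceeding incident PAR (sensor
    noise, sunflecks) clip to 1 with a warning.
    """
    if ipar <= 0:
        raise ValueError("incident PAR must be positive")
    ratio = tpar_raw / ipar
    if ratio > 1.0 or ratio < 0.0:
        logger.warning("tPAR ratio %.3f outside [0, 1]; clipped", ratio)
    return float(np.clip(ratio, 0.0, 1.0))


def transmittance(h, k_li: float, h0: float):
    """Model transmittance at normalized height(s) ``h``; T(1) = 1 exactly."""
    h = np.asarray(h, dtype=float)
    return expit(k_li * (h - h0)) / expit(k_li * (1.0 - h0))


def fit_li(profile: LIProfile) -> LIFit:
    """Least-squares fit of the constrained logistic to one profile.

    Requires at least four height points spanning at least half the
    normalized height range.  A profile with no measurable attenuation
    collapses to the ``k_li -> 0`` limit and is flagged ``transparent
    canopy``.
    """
    h = profile.normalized_heights
    y = profile.tpar
    if h.size < 4:
        raise ValueError("need >= 4 height points")
    if h.max() - h.min() < 0.5:
        raise ValueError("profile must span >= 0.5 of normalized height")

    if float(y.min()) > 0.98:  # no attenuation anywhere
        fit = LIFit(k_li=0.0, h0=0.5, converged=True)
        fit.flags.append("transparent canopy")
        fit.parg, fit.par50h, fit.h50par = 1.0, 1.0, math.nan
        fit.adj_r2 = math.nan
        return fit

    lo, hi = (1e-3, -1.0), (60.0, 2.0)
    p0 = (8.0, float(np.clip(np.interp(0.5, y, h), 0.05, 0.95)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                transmittance, h, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
    except RuntimeError as exc:
        fit = LIFit(k_li=math.nan, h0=math.nan, converged=False)
        fit.flags.append(f"nonconvergence: {exc}")
        return fit

    fit = LIFit(k_li=float(popt[0]), h0=float(popt[1]))
    resid = y - transmittance(h, fit.k_li, fit.h0)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    n = y.size
    fit.adj_r2 = 1.0 - (sse / max(n - 2, 1)) / (sst / (n - 1)) if sst > 0 else math.nan
    fit.parg, fit.par50h, fit.h50par = derive_li_params(fit)
    return fit


def derive_li_params(fit: LIFit) -> tuple[float, float, float]:
    """(PARG, PAR50H, H50PAR) from a fitted transmittance curve.

    H50PAR inverts T(h) = 0.5 in closed form,
    ``h0 + logit(0.5 sigmoid(k_li (1 - h0))) / k_li``, and is NaN when
    PARG > 0.5 (light is never blocked down to 50%).
    """
    k, h0 = fit.k_li, fit.h0
    if not np.isfinite(k) or k < _TRANSPARENT_K:
        return 1.0, 1.0, math.nan
    parg = float(transmittance(0.0, k, h0))
    par50h = float(transmittance(0.5, k, h0))
    if parg > 0.5:
        return parg, par50h, math.nan
    h50par = h0 + float(logit(0.5 * expit(k * (1.0 - h0)))) / k
    return parg, par50h, float(np.clip(h50par, 0.0, 1.0))
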