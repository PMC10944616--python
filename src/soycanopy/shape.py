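"""Beta-pdf plant-outline shape model.

A defoliated soybean plant photographed side-on traces a smooth outline:
half-width (distance from the stem centre line) measured at nine
relative heights from ground (0) to apex (1).  The outline is modelled
with a mode-normalized beta probability density,

    w(x) = Sh_W * f(x; alpha, beta) / f(Sh_H; alpha, beta)

where ``f`` is the beta pdf, ``Sh_H = (alpha-1)/(alpha+beta-2)`` is the
pdf mode, so ``w(Sh_H) = Sh_W`` exactly: ``Sh_W`` is literally the
maximum half-width in metres.  The area under the width curve in the
height-normalized coordinate is

    Sh_A = integral_0^1 w(x) dx = Sh_W / f(Sh_H; alpha, beta)

because the pdf integrates to one.  ``alpha, beta > 1`` is required so
the outline pinches to zero at ground and apex with an interior widest
point.  An alternative raw-amplitude convention (amplitude multiplying
the un-normalized pdf) is exposed via :func:`raw_amplitude`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import betaln, xlog1py, xlogy

__all__ = [
    "ShapeProfile",
    "ShapeFit",
    "outline",
    "fit_shape",
    "mode_of",
    "raw_amplitude",
]


def _beta_pdf(x, a: float, b: float):
    """Beta pdf via log-space gamma functions (fast, endpoint-safe for
    a, b > 1: density is 0 at x = 0 and x = 1)."""
    x = np.asarray(x, dtype=float)
    return np.exp(xlogy(a - 1.0, x) + xlog1py(b - 1.0, -x) - betaln(a, b))


def mode_of(alpha: float, beta: float) -> float:
    """Mode of the beta pdf, ``(alpha-1)/(alpha+beta-2)``, for alpha, beta > 1."""
    if alpha <= 1 or beta <= 1:
        raise ValueError("alpha and beta must exceed 1 for an interior mode")
    return (alpha - 1.0) / (alpha + beta - 2.0)


@dataclass(frozen=True)
class ShapeProfile:
    """Half-width versus relative height for one plant.

    ``rel_height`` 0 is the ground, 1 the apex.  Full-width inputs must
    be halved at ingest (``from_full_width``).
    """

    accession: str
    year: int
    block: int
    plant: int
    rel_height: np.ndarray
    halfwidth: np.ndarray
    plant_height: float = math.nan

    def __post_init__(self) -> None:
        x = np.asarray(self.rel_height, dtype=float)
        w = np.asarray(self.halfwidth, dtype=float)
        if x.size != w.size:
            raise ValueError("rel_height and halfwidth must have equal length")
        if np.any((x < 0) | (x > 1)):
            raise ValueError("rel_height must lie in [0, 1]")
        if np.any(w < 0):
            raise ValueError("halfwidth must be non-negative")
        object.__setattr__(self, "rel_height", x)
        object.__setattr__(self, "halfwidth", w)

    @classmethod
    def from_full_width(cls, accession, year, block, plant, rel_height,
                        full_width, plant_height=math.nan) -> "ShapeProfile":
        return cls(accession, year, block, plant, np.asarray(rel_height, float),
                   np.asarray(full_width, float) / 2.0, plant_height)


@dataclass
class ShapeFit:
    """Re-parameterized beta-outline fit: (Sh_W, Sh_H, Sh_A) + (alpha, beta)."""

    alpha: float
    beta: float
    sh_w: float
    sh_h: float = math.nan
    sh_a: float = math.nan
    rms: float = math.nan
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.converged and np.isfinite(self.alpha):
            self.sh_h = mode_of(self.alpha, self.beta)
            self.sh_a = self.sh_w / float(
                _beta_pdf(self.sh_h, self.alpha, self.beta)
            )


def outline(x, fit: ShapeFit):
    """Outline half-width (m) at relative height(s) ``x`` in [0, 1].

    ``w(x) = Sh_W f(x)/f(Sh_H)``; zero at both ends, maximum Sh_W at Sh_H.
    """
    if fit.alpha <= 1 or fit.beta <= 1:
        raise ValueError("outline requires alpha, beta > 1 (interior mode)")
    x = np.asarray(x, dtype=float)
    peak = _beta_pdf(mode_of(fit.alpha, fit.beta), fit.alpha, fit.beta)
    return fit.sh_w * _beta_pdf(x, fit.alpha, fit.beta) / peak


def raw_amplitude(fit: ShapeFit) -> float:
    """Amplitude under the raw-pdf convention, ``w(x) = a f(x)``: equals Sh_A."""
    return fit.sh_a


def _moments_init(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Method-of-moments start treating the profile as a discrete density."""
    total = float(w.sum())
    if total <= 0:
        return 2.0, 2.0
    m = float((x * w).sum()) / total
    v = float(((x - m) ** 2 * w).sum()) / total
    v = min(max(v, 1e-4), m * (1 - m) * 0.99) if 0 < m < 1 else 0.04
    common = m * (1 - m) / v - 1.0
    a, b = m * common, (1 - m) * common
    return float(np.clip(a, 1.05, 50.0)), float(np.clip(b, 1.05, 50.0))


def fit_shape(profile: ShapeProfile) -> ShapeFit:
    """Nonlinear least-squares beta-outline fit of one width profile.

    Optimizes (Sh_W, alpha, beta) with alpha, beta in (1, 60]; reports
    residual RMS.  Multistart around the method-of-moments initial
    guess; ties broken by lowest RMS then lowest alpha.
    """
    x, w = profile.rel_height, profile.halfwidth
    if x.size < 5:
        raise ValueError("need >= 5 profile points")
    if not np.any(w > 0):
        raise ValueError("all widths are zero")

    a0, b0 = _moments_init(x, w)
    w0 = float(w.max())

    def resid(p):
        sw, a, b = p
        m = (a - 1.0) / (a + b - 2.0)
        model = sw * _beta_pdf(x, a, b) / _beta_pdf(m, a, b)
        return model - w

    lo = (1e-9, 1.0 + 1e-6, 1.0 + 1e-6)
    hi = (10.0, 60.0, 60.0)
    starts = [(w0, a0, b0), (w0, 2.0, 2.0), (w0, 4.0, 1.5), (w0, 1.5, 4.0)]
    best = None
    for p0 in starts:
        p0 = tuple(np.clip(p0, lo, hi))
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-14,
                                ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rms = math.sqrt(float(np.mean(sol.fun ** 2)))
        key = (round(rms, 12), sol.x[1])
        if best is None or key < best[0]:
            best = (key, sol, rms)
    if best is None:
        fit = ShapeFit(alpha=math.nan, beta=math.nan, sh_w=math.nan,
                       converged=False)
        fit.flags.append("nonconvergence")
        return fit

    _, sol, rms = best
    sw, a, b = (float(v) for v in sol.x)
    fit = ShapeFit(alpha=a, beta=b, sh_w=sw)
    fit.rms = rms
    if not sol.success:
        fit.flags.append("optimizer reported failure")
    return fit
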