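"""Prism-canopy CO2 assimilation simulation.

A one-metre stretch of plant row is idealized as a prism whose cross
section is the beta-pdf outline: half-width ``w(x)`` (m) at relative
height ``x``.  Light arrives from straight overhead, so only the
upward-facing part of the outline — the segment above the widest point
``Sh_H`` — is photosynthetically exposed, on both faces of the row.
A surface element between heights x and x+dx projects horizontally to
``-dw`` (w is decreasing above the mode), receives within-canopy PAR
``I0 * T(x)`` from the accession's own transmittance fit, and
assimilates following a non-rectangular hyperbola light response:

    A(I) = [phi I + Amax - sqrt((phi I + Amax)^2 - 4 theta phi I Amax)]
           / (2 theta) - Rd

Row assimilation per metre of row (umol s^-1 m^-1):

    A_row(I0) = 2 * integral_{Sh_H}^{1} A(I0 T(x)) (-dw/dx) dx

evaluated as a Riemann-Stieltjes sum in w over a fine height grid, so
the uniform-light case telescopes exactly to ``2 Sh_W A(I0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .li import LIFit, transmittance
from .shape import ShapeFit, outline

__all__ = [
    "LightResponse",
    "light_response",
    "row_assimilation",
    "assimilation_curve",
    "relative_assimilation",
    "assimilation_slope",
    "shape_assim_correlation",
    "DEFAULT_PAR_GRID",
    "DEFAULT_PAR_LEVELS",
]

DEFAULT_PAR_GRID = np.arange(0.0, 1801.0, 10.0)
DEFAULT_PAR_LEVELS = (250.0, 450.0, 900.0, 1800.0)


@dataclass(frozen=True)
class LightResponse:
    """Non-rectangular hyperbola light-response parameters.

    phi   — apparent quantum yield, mol CO2 (mol photons)^-1, in (0, 0.2)
    amax  — light-saturated gross assimilation, umol m^-2 s^-1
    theta — curvature, (0, 1]
    rd    — dark respiration, umol m^-2 s^-1, >= 0
    """

    phi: float = 0.05
    amax: float = 25.0
    theta: float = 0.7
    rd: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.phi < 0.2):
            raise ValueError("phi must lie in (0, 0.2)")
        if self.amax <= 0:
            raise ValueError("amax must be positive")
        if not (0 < self.theta <= 1):
            raise ValueError("theta must lie in (0, 1]")
        if self.rd < 0:
            raise ValueError("rd must be non-negative")


def light_response(I, lrc: LightResponse):
    """Leaf assimilation A(I), umol m^-2 s^-1, at incident PAR ``I``.

    A(0) = -Rd; A(inf) = Amax - Rd.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("PAR must be non-negative")
    s = lrc.phi * I + lrc.amax
    disc = s * s - 4.0 * lrc.theta * lrc.phi * I * lrc.amax
    return (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * lrc.theta) - lrc.rd


def row_assimilation(
    shape: ShapeFit,
    li: LIFit,
    I0: float,
    lrc: LightResponse,
    plant_height: float = 1.0,
    n_panels: int = 800,
) -> float:
    """CO2 assimilation per metre of row at incident PAR ``I0``.

    Integrates the light response over the horizontal projection of the
    upward-facing outline (above the widest point), both row faces,
    with within-canopy PAR ``I0 * T(x)``.  ``n_panels`` >= 400 height
    panels; panel sums telescope in w so a transparent canopy
    reproduces ``2 Sh_W A(I0)`` exactly.
    """
    if I0 < 0:
        raise ValueError("incident PAR must be non-negative")
    if n_panels < 400:
        raise ValueError("need >= 400 quadrature panels")
    x = np.linspace(shape.sh_h, 1.0, n_panels + 1)
    w = outline(x, shape)
    xm = 0.5 * (x[:-1] + x[1:])
    t = transmittance(xm, li.k_li, li.h0) if li.k_li > 0 else np.ones_like(xm)
    a = light_response(I0 * t, lrc)
    dw = w[:-1] - w[1:]          # -dw >= 0 above the mode
    if np.any(~np.isfinite(dw)):
        raise ArithmeticError("quadrature failure: non-finite outline widths")
    return 2.0 * float(np.sum(a * dw))


def assimilation_curve(
    shape: ShapeFit,
    li: LIFit,
    lrc: LightResponse,
    par_grid: np.ndarray = DEFAULT_PAR_GRID,
    plant_height: float = 1.0,
    n_panels: int = 800,
) -> np.ndarray:
    """A_row evaluated over a grid of incident PAR values."""
    return np.array([
        row_assimilation(shape, li, float(i0), lrc, plant_height, n_panels)
        for i0 in par_grid
    ])


def relative_assimilation(panel: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Deviation of each accession's A_row curve from the panel mean.

    All curves must share the PAR grid; deviations sum to zero across
    the panel at every grid point.
    """
    if len(panel) < 2:
        raise ValueError("need >= 2 accessions")
    curves = list(panel.values())
    n = curves[0].shape[0]
    if any(c.shape[0] != n for c in curves):
        raise ValueError("mismatched PAR grids across panel")
    mean = np.mean(curves, axis=0)
    return {acc: c - mean for acc, c in panel.items()}


def assimilation_slope(
    curve: np.ndarray, par_grid: np.ndarray, I0: float
) -> tuple[float, bool]:
    """d(curve)/d(PAR) at ``I0`` by central finite difference.

    Returns (slope, boundary_flag); at a grid boundary a one-sided
    difference is used and flagged.
    """
    idx = int(np.argmin(np.abs(par_grid - I0)))
    if not np.isclose(par_grid[idx], I0):
        raise ValueError("I0 must lie on the PAR grid")
    if 0 < idx < len(par_grid) - 1:
        slope = (curve[idx + 1] - curve[idx - 1]) / (
            par_grid[idx + 1] - par_grid[idx - 1]
        )
        return float(slope), False
    lo, hi = (idx, idx + 1) if idx == 0 else (idx - 1, idx)
    return float((curve[hi] - curve[lo]) / (par_grid[hi] - par_grid[lo])), True


def shape_assim_correlation(
    shapes: dict[str, ShapeFit],
    panel: dict[str, np.ndarray],
    par_grid: np.ndarray = DEFAULT_PAR_GRID,
    par_levels=DEFAULT_PAR_LEVELS,
) -> pd.DataFrame:
    """Pearson correlations of Sh_H and Sh_W with relative assimilation
    and its PAR slope, across accessions at each PAR level.

    Returns a long DataFrame (quantity, shape_param, par_level, r, p);
    zero-variance shape parameters yield NaN with a flag column.
    """
    if len(panel) < 5:
        raise ValueError("need >= 5 accessions for panel correlations")
    accs = sorted(panel)
    rel = relative_assimilation({a: panel[a] for a in accs})
    rows = []
    for level in par_levels:
        idx = int(np.argmin(np.abs(par_grid - level)))
        rel_at = np.array([rel[a][idx] for a in accs])
        slope_at = np.array([
            assimilation_slope(rel[a], par_grid, float(par_grid[idx]))[0]
            for a in accs
        ])
        for pname, values in (
            ("sh_h", np.array([shapes[a].sh_h for a in accs])),
            ("sh_w", np.array([shapes[a].sh_w for a in accs])),
        ):
            for qname, q in (("relative_a", rel_at), ("slope", slope_at)):
                if np.ptp(values) == 0 or np.ptp(q) == 0:
                    rows.append((qname, pname, level, np.nan, np.nan, "zero variance"))
                    continue
                r, p = pearsonr(values, q)
                rows.append((qname, pname, level, float(r), float(p), ""))
    return pd.DataFrame(
        rows, columns=["quantity", "shape_param", "par_level", "r", "p", "flag"]
    )
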