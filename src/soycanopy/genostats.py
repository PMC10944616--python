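"""Trial-level genetic statistics: REML variance components, BLUPs,
reliability, and FDR-adjusted trait correlations.

Plot-level trait values from a two-year randomized complete block trial
are decomposed with the all-random linear model

    y_ijk = mu + G_i + Y_j + B_k(j) + GY_ij + e_ijk

(genotype, year, block nested in year, genotype-by-year, residual; all
effects random, residuals iid).  Variance components are estimated by
REML with standard deviations as the free parameters (non-negativity by
construction), accession effects are predicted as BLUPs, and the
reliability of accession means in a year with r replicates is

    i2_ACC = sigma2_G / (sigma2_G + sigma2_e / r).

Correlation analytics operate on the accession-by-trait BLUP table:
Pearson/Spearman matrices with Benjamini-Hochberg adjustment over the
upper triangle, and the Z-scored heatmap matrix filtered and ordered by
correlation with an anchor trait (season-average canopy cover, ACC, in
the original analysis).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "VarComp",
    "fit_random_model",
    "reliability",
    "correlation_matrix",
    "heatmap_matrix",
]

_COMPONENTS = ("G", "Y", "B", "GxY")


@dataclass
class VarComp:
    """REML variance components and BLUPs for one trait."""

    trait: str
    sigma2_G: float
    sigma2_Y: float
    sigma2_B: float
    sigma2_GxY: float
    sigma2_eps: float
    blups: pd.Series                      # accession -> deviation
    reliability_by_year: dict[int, float]
    reliability_pooled: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)


def _indicator(codes: pd.Series) -> np.ndarray:
    """Dense 0/1 design matrix for one categorical factor."""
    cats = pd.Categorical(codes)
    Z = np.zeros((len(codes), len(cats.categories)))
    Z[np.arange(len(codes)), cats.codes] = 1.0
    return Z


def _reml_nll(sds, y, X, Zs):
    n = y.size
    V = sds[-1] ** 2 * np.eye(n)
    for sd, Z in zip(sds[:-1], Zs):
        V += sd * sd * (Z @ Z.T)
    try:
        c = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return 1e12
    Vi_y = cho_solve(c, y)
    Vi_X = cho_solve(c, X)
    XtViX = X.T @ Vi_X
    XtVi_y = X.T @ Vi_y
    beta = np.linalg.solve(XtViX, XtVi_y)
    quad = float(y @ Vi_y - XtVi_y @ beta)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12
    return 0.5 * (logdetV + logdetXtViX + quad)


def fit_random_model(
    table: pd.DataFrame, trait: str,
    components: tuple[str, ...] = _COMPONENTS,
) -> VarComp:
    """REML fit of the all-random year/block/genotype/GxY model.

    ``table`` is long format with columns accession, year, block, trait,
    value; missing plot values are dropped (the restricted likelihood is
    evaluated on observed cells only).  Requires >= 2 accessions and
    >= 2 plots in total.  A factor that is inestimable — single level,
    or confounded with another term (year and GxY in a one-year table,
    block-in-year with one block per year) — is flagged and its
    component pinned to zero.  ``components`` restricts the model to a
    subset of random terms (e.g. ``("G",)`` for a one-way model).
    """
    df = table.loc[table["trait"] == trait].dropna(subset=["value"]).copy()
    if df.empty:
        raise ValueError(f"no data for trait {trait!r}")
    if df["accession"].nunique() < 2:
        raise ValueError("need >= 2 accessions")
    if len(df) < df["accession"].nunique() + 1:
        raise ValueError("need replication to separate genotype and residual")

    y_raw = df["value"].to_numpy(dtype=float)
    scale = float(np.std(y_raw)) or 1.0
    y = (y_raw - y_raw.mean()) / scale
    n = y.size
    X = np.ones((n, 1))

    acc = df["accession"].astype(str)
    yr = df["year"].astype(str)
    blk = yr + ":" + df["block"].astype(str)
    gxy = acc + ":" + yr
    factors = {"G": acc, "Y": yr, "B": blk, "GxY": gxy}
    n_years = yr.nunique()
    estimable = {
        "G": acc.nunique() >= 2,
        "Y": n_years >= 2,
        "B": blk.nunique() > n_years,   # else confounded with year
        "GxY": n_years >= 2,            # else confounded with genotype
    }
    flags: list[str] = []
    active: list[str] = []
    Zs = []
    for name in _COMPONENTS:
        if name not in components:
            continue
        if not estimable[name]:
            flags.append(f"{name} inestimable; pinned to 0")
            continue
        active.append(name)
        Zs.append(_indicator(factors[name]))

    k = len(Zs)
    x0 = np.full(k + 1, 1.0 / math.sqrt(k + 1))
    bounds = [(0.0, None)] * k + [(1e-6, None)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(
            _reml_nll, x0, args=(y, X, Zs), method="L-BFGS-B",
            bounds=bounds, options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
    sds = np.abs(res.x)
    if not res.success:
        flags.append(f"optimizer: {res.message}")

    sig2 = {name: 0.0 for name in _COMPONENTS}
    for name, sd in zip(active, sds[:-1]):
        sig2[name] = float(sd * sd) * scale * scale
    sig2_eps = float(sds[-1] ** 2) * scale * scale

    # BLUPs of accession effects: sigma2_G Z_G' V^-1 (y - X beta)
    V = sds[-1] ** 2 * np.eye(n)
    for sd, Z in zip(sds[:-1], Zs):
        V += sd * sd * (Z @ Z.T)
    c = cho_factor(V, lower=True)
    Vi_y = cho_solve(c, y)
    Vi_X = cho_solve(c, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    resid_w = cho_solve(c, y - X @ beta)
    Zg = _indicator(acc)
    g_sd = sds[active.index("G")] if "G" in active else 0.0
    u = g_sd ** 2 * (Zg.T @ resid_w) * scale
    accessions = pd.Categorical(acc).categories
    blups = pd.Series(u, index=accessions, name=trait)

    rel_by_year: dict[int, float] = {}
    for year, sub in df.groupby("year"):
        r = sub.groupby("accession").size().mean()
        rel_by_year[year] = reliability(sig2["G"], sig2_eps, float(r))
    vals = [v for v in rel_by_year.values() if not math.isnan(v)]
    pooled = float(np.mean(vals)) if vals else math.nan

    return VarComp(
        trait=trait,
        sigma2_G=sig2["G"], sigma2_Y=sig2["Y"], sigma2_B=sig2["B"],
        sigma2_GxY=sig2["GxY"], sigma2_eps=sig2_eps,
        blups=blups, reliability_by_year=rel_by_year,
        reliability_pooled=pooled,
        converged=bool(res.success), flags=flags,
    )


def reliability(sigma2_G: float, sigma2_eps: float, r: float) -> float:
    """Reliability of accession means: sigma2_G / (sigma2_G + sigma2_eps / r).

    NA when both variances are zero.
    """
    if r < 1:
        raise ValueError("replicate count must be >= 1")
    denom = sigma2_G + sigma2_eps / r
    if denom <= 0:
        return math.nan
    return sigma2_G / denom


def _pairwise_corr(x: np.ndarray, y: np.ndarray, method: str):
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return math.nan, math.nan
    if method == "pearson":
        r, p = pearsonr(x[ok], y[ok])
    else:
        r, p = spearmanr(x[ok], y[ok])
    return float(r), float(p)


def correlation_matrix(
    blups: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Trait-by-trait correlation of accession BLUPs.

    ``blups`` is wide (accession rows, trait columns; missing values
    handled pairwise-complete).  Returns (r, p, BH-adjusted p), all
    symmetric with unit diagonal / zero-p diagonal; the BH adjustment
    runs over the upper-triangle tests only.  Zero-variance traits get
    NaN rows/columns with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if len(blups) < 4:
        raise ValueError("need >= 4 accessions")
    traits = list(blups.columns)
    m = len(traits)
    R = np.eye(m)
    P = np.zeros((m, m))
    degenerate = [t for t in traits
                  if np.nanstd(blups[t].to_numpy(dtype=float)) == 0]
    if degenerate:
        logger.warning("zero-variance traits: %s", degenerate)
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    for i, j in pairs:
        if traits[i] in degenerate or traits[j] in degenerate:
            R[i, j] = R[j, i] = P[i, j] = P[j, i] = math.nan
            continue
        r, p = _pairwise_corr(
            blups[traits[i]].to_numpy(dtype=float),
            blups[traits[j]].to_numpy(dtype=float), method,
        )
        R[i, j] = R[j, i] = r
        P[i, j] = P[j, i] = p
    for t in degenerate:
        i = traits.index(t)
        R[i, i] = P[i, i] = math.nan

    Q = np.full((m, m), math.nan)
    np.fill_diagonal(Q, 0.0)
    raw = np.array([P[i, j] for i, j in pairs])
    ok = np.isfinite(raw)
    adj = np.full_like(raw, math.nan)
    if ok.any():
        adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
    for (i, j), q in zip(pairs, adj):
        Q[i, j] = Q[j, i] = q
    idx = pd.Index(traits)
    return (pd.DataFrame(R, idx, idx), pd.DataFrame(P, idx, idx),
            pd.DataFrame(Q, idx, idx))


def heatmap_matrix(
    blups: pd.DataFrame, anchor_trait: str = "ACC", alpha: float = 0.05,
    method: str = "pearson",
) -> tuple[pd.DataFrame, list, list[str]]:
    """Z-scored BLUP heatmap restricted to traits FDR-correlated with an
    anchor trait.

    Each non-anchor trait is tested for correlation with the anchor;
    the p-values are BH-adjusted and traits with adjusted p < ``alpha``
    are retained.  Retained columns are Z-scored (mean 0, sd 1, ddof 1)
    and ordered by |r| with the anchor, descending (the anchor itself
    first); rows (accessions) are ordered by anchor BLUP, descending.

    Returns (matrix, row_order, column_order).
    """
    if anchor_trait not in blups.columns:
        raise ValueError(f"anchor trait {anchor_trait!r} not present")
    anchor = blups[anchor_trait].to_numpy(dtype=float)
    others = [t for t in blups.columns if t != anchor_trait]
    stats = {}
    for t in others:
        r, p = _pairwise_corr(anchor, blups[t].to_numpy(dtype=float), method)
        stats[t] = (r, p)
    raw = np.array([stats[t][1] for t in others])
    ok = np.isfinite(raw)
    keep: list[str] = []
    if ok.any():
        adj = np.full_like(raw, math.nan)
        adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
        keep = [t for t, q in zip(others, adj) if np.isfinite(q) and q < alpha]
    if not keep:
        logger.warning("no trait passes the FDR filter vs %s", anchor_trait)
    cols = [anchor_trait] + sorted(keep, key=lambda t: -abs(stats[t][0]))
    rows = blups[anchor_trait].sort_values(ascending=False).index.tolist()
    mat = blups.loc[rows, cols].astype(float)
    z = (mat - mat.mean()) / mat.std(ddof=1)
    return z, rows, cols
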