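"""Shoot-architecture traits from per-plant measurements.

Nodes are indexed from the top of the plant: node 1 is the uppermost.
Trait vocabulary (per-plant, then averaged to plot level):

PH  plant height (m)               NO  main-stem node count
CH  canopy height: sum of the top six internode lengths (m)
ILn internode length at node n     PLn petiole length at node n (m)
IS4 OLS slope of the top-four internode lengths on node index (m/node)
PS4 same for petioles              PAn petiole angle at node n (deg)
LL/LW/LA  leaflet length / width (m) / area (m^2), plant means
BA  mean branch insertion angle (deg)    BO  mean branch orientation (deg)
BN  branch count
BZ  branching zone: ground -> insertion height of the highest branch (m)
BD  BN / BZ (branches per m of branching zone)
BR  BZ / PH (fraction of the stem bearing branches)

A lateral appendage with at least one petiole counts as a branch.  A
branchless plant gets BZ = 0, BR = 0 and BD = NA, flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Branch",
    "Leaflet",
    "PlantRecord",
    "petiole_slope",
    "internode_slope",
    "canopy_height",
    "branching_traits",
    "leaf_stats",
    "plant_traits",
    "aggregate_plot",
    "plants_to_trait_table",
]

#: traits produced per plant / per plot
TRAIT_NAMES = [
    "PH", "NO", "CH", "IL4", "IL5", "IS4", "PL4", "PL5", "PS4",
    "PA4", "PA5", "LL", "LW", "LA", "BA", "BO", "BN", "BZ", "BD", "BR",
]


@dataclass(frozen=True)
class Branch:
    node_height: float   # insertion height from the ground, m
    angle: float         # insertion angle from the main stem, degrees
    orientation: float   # azimuthal orientation, degrees


@dataclass(frozen=True)
class Leaflet:
    length: float  # m
    width: float   # m
    area: float    # m^2


@dataclass
class PlantRecord:
    plant: int
    plant_height: float
    node_count: int
    petiole_lengths: dict[int, float] = field(default_factory=dict)    # node->m
    internode_lengths: dict[int, float] = field(default_factory=dict)  # node->m
    branches: list[Branch] = field(default_factory=list)
    leaflets: list[Leaflet] = field(default_factory=list)
    petiole_angles: dict[int, float] = field(default_factory=dict)     # node->deg

    def __post_init__(self) -> None:
        if self.plant_height <= 0:
            raise ValueError("plant height must be positive")
        for b in self.branches:
            if b.node_height > self.plant_height + 1e-9:
                raise ValueError("branch insertion above plant height")


def _ols_slope(lengths) -> float:
    """OLS slope of length on node index 1..4; NaN if any value missing."""
    y = np.asarray(lengths, dtype=float)
    if y.size < 4 or np.any(~np.isfinite(y[:4])):
        return math.nan
    x = np.arange(1, 5, dtype=float)
    xc = x - x.mean()
    return float(xc @ (y[:4] - y[:4].mean()) / (xc @ xc))


def petiole_slope(lengths) -> float:
    """PS4: OLS slope of the top-four petiole lengths on node index (m/node)."""
    return _ols_slope(lengths)


def internode_slope(lengths) -> float:
    """IS4: OLS slope of the top-four internode lengths on node index."""
    return _ols_slope(lengths)


def canopy_height(internodes) -> float:
    """CH: sum of the top six internode lengths (m); NaN if any missing."""
    y = np.asarray(internodes, dtype=float)
    if y.size < 6 or np.any(~np.isfinite(y[:6])):
        return math.nan
    return float(y[:6].sum())


def branching_traits(plant: PlantRecord) -> dict[str, float]:
    """BN, BZ, BD, BR and the per-plant mean branch angle/orientation.

    BZ is the insertion height of the most distal branch along the stem.
    """
    bn = len(plant.branches)
    if bn == 0:
        return {"BN": 0.0, "BZ": 0.0, "BD": math.nan, "BR": 0.0,
                "BA": math.nan, "BO": math.nan}
    bz = max(b.node_height for b in plant.branches)
    return {
        "BN": float(bn),
        "BZ": bz,
        "BD": bn / bz if bz > 0 else math.nan,
        "BR": bz / plant.plant_height,
        "BA": float(np.mean([b.angle for b in plant.branches])),
        "BO": float(np.mean([b.orientation for b in plant.branches])),
    }


def leaf_stats(leaflets) -> dict[str, float]:
    """Plant-mean leaflet length (LL), width (LW) and area (LA)."""
    if not leaflets:
        return {"LL": math.nan, "LW": math.nan, "LA": math.nan}
    return {
        "LL": float(np.mean([lf.length for lf in leaflets])),
        "LW": float(np.mean([lf.width for lf in leaflets])),
        "LA": float(np.mean([lf.area for lf in leaflets])),
    }


def plant_traits(plant: PlantRecord) -> dict[str, float]:
    """All per-plant trait values for one plant."""
    pet = [plant.petiole_lengths.get(n, math.nan) for n in range(1, 8)]
    inter = [plant.internode_lengths.get(n, math.nan) for n in range(1, 8)]
    out = {
        "PH": plant.plant_height,
        "NO": float(plant.node_count),
        "CH": canopy_height(inter),
        "IL4": inter[3],
        "IL5": inter[4],
        "IS4": internode_slope(inter),
        "PL4": pet[3],
        "PL5": pet[4],
        "PS4": petiole_slope(pet),
        "PA4": plant.petiole_angles.get(4, math.nan),
        "PA5": plant.petiole_angles.get(5, math.nan),
    }
    out.update(leaf_stats(plant.leaflets))
    out.update(branching_traits(plant))
    return out


def aggregate_plot(plants: list[PlantRecord]) -> dict[str, float]:
    """Per-plot trait means across plants; per trait, missing plants are
    excluded (an all-missing trait stays NaN)."""
    if not plants:
        raise ValueError("plot has no plants")
    per_plant = [plant_traits(p) for p in plants]
    out: dict[str, float] = {}
    for trait in TRAIT_NAMES:
        vals = np.array([pp[trait] for pp in per_plant], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[trait] = float(vals.mean()) if vals.size else math.nan
    return out


def plants_to_trait_table(
    plots: dict[tuple[str, int, int], list[PlantRecord]]
) -> pd.DataFrame:
    """Long-format plot trait table (accession, year, block, trait, value)."""
    rows = []
    for (accession, year, block), plants in plots.items():
        for trait, value in aggregate_plot(plants).items():
            rows.append((accession, year, block, trait, value))
    return pd.DataFrame(rows, columns=["accession", "year", "block", "trait", "value"])
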