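"""Readers and writers for the pipeline's CSV interchange files.

All interchange is headered CSV in long or per-entity layouts; branch
and leaflet lists inside ``plants.csv`` are packed as
``;``-separated ``value:value:value`` triples so the file stays a flat
text table.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .cc import CCSeries
from .li import LIProfile
from .shape import ShapeProfile
from .traits import Branch, Leaflet, PlantRecord

__all__ = [
    "read_cc_series",
    "read_li_profiles",
    "read_shape_profiles",
    "read_plants",
    "read_phenology",
]

_PLOT_KEYS = ["accession", "year", "block"]


def read_cc_series(path: str | Path) -> list[CCSeries]:
    df = pd.read_csv(path)
    out = []
    for (acc, year, block), g in df.groupby(_PLOT_KEYS, sort=True):
        g = g.sort_values("dae")
        out.append(CCSeries(str(acc), int(year), int(block),
                            g["dae"].to_numpy(float), g["cc"].to_numpy(float)))
    return out


def read_li_profiles(path: str | Path) -> list[LIProfile]:
    df = pd.read_csv(path)
    out = []
    for (acc, year, block), g in df.groupby(_PLOT_KEYS, sort=True):
        g = g.sort_values("height_m")
        out.append(LIProfile(str(acc), int(year), int(block),
                             g["height_m"].to_numpy(float),
                             g["tpar"].to_numpy(float),
                             float(g["plant_height_m"].iloc[0])))
    return out


def read_shape_profiles(path: str | Path) -> list[ShapeProfile]:
    df = pd.read_csv(path)
    out = []
    for (acc, year, block, plant), g in df.groupby(_PLOT_KEYS + ["plant"],
                                                   sort=True):
        g = g.sort_values("rel_height")
        ph = float(g["plant_height_m"].iloc[0]) if "plant_height_m" in g else math.nan
        out.append(ShapeProfile(str(acc), int(year), int(block), int(plant),
                                g["rel_height"].to_numpy(float),
                                g["halfwidth_m"].to_numpy(float), ph))
    return out


def _unpack(packed, factory):
    if not isinstance(packed, str) or not packed:
        return []
    return [factory(*(float(v) for v in item.split(":")))
            for item in packed.split(";")]


def read_plants(path: str | Path) -> dict[tuple[str, int, int], list[PlantRecord]]:
    df = pd.read_csv(path)
    plots: dict[tuple[str, int, int], list[PlantRecord]] = {}
    for _, row in df.iterrows():
        key = (str(row["accession"]), int(row["year"]), int(row["block"]))
        rec = PlantRecord(
            plant=int(row["plant"]),
            plant_height=float(row["plant_height_m"]),
            node_count=int(row["node_count"]),
            petiole_lengths={
                n: float(row[f"petiole_{n}_m"])
                for n in range(1, 8)
                if f"petiole_{n}_m" in row and np.isfinite(row[f"petiole_{n}_m"])
            },
            internode_lengths={
                n: float(row[f"internode_{n}_m"])
                for n in range(1, 8)
                if f"internode_{n}_m" in row and np.isfinite(row[f"internode_{n}_m"])
            },
            branches=_unpack(row.get("branches"), Branch),
            leaflets=_unpack(row.get("leaflets"), Leaflet),
            petiole_angles={
                n: float(row[f"pa{n}_deg"])
                for n in (4, 5)
                if f"pa{n}_deg" in row and np.isfinite(row[f"pa{n}_deg"])
            },
        )
        plots.setdefault(key, []).append(rec)
    return plots


def read_phenology(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
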