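"""Synthetic field-trial generator with known ground truth.

Emulates the study design behind the real data: a 40-accession soybean
panel grown as a randomized complete block design over two years (four
replicate blocks in the first year, two in the second), with every
observable layer — canopy-coverage time series, PAR transmittance
transects, plant width-by-height outlines, per-plant architecture
measurements and phenology — driven by one additive random-effects
decomposition per underlying trait:

    plot value = trait mean + genotype + year + block(year) + GxY + plot residual

Accession (genotype) effects are drawn once per truth object with
variance ``sigma2_G``; year, block-in-year, genotype-by-year and plot
residual effects are drawn per trial with their own components.
Observation noise is layer-specific: Gaussian on the coverage fraction
(clipped to [0, 1]), Gaussian on transmittance (clipped), multiplicative
Gaussian on outline widths (floored at 0), Gaussian within-plot
variation on plant measurements.  Everything derives from a single
seed, so identical seeds give identical datasets, and the generating
values are returned alongside the observations for parameter-recovery
testing.

What this emulates — and what it does not: the variance structure,
design imbalance and measurement grids of a real two-year trial, but
not spatial field trend, weather, lodging, or image-segmentation error,
all of which are absent by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cc import CCSeries, logistic
from .li import LIProfile, transmittance
from .shape import ShapeFit, ShapeProfile, outline
from .traits import Branch, Leaflet, PlantRecord

__all__ = [
    "TrialDesign",
    "TruthParams",
    "SimulatedTrial",
    "generate_cc_series",
    "generate_trial",
    "DEFAULT_REL_HEIGHTS",
]

#: measurement fractions of plant height for the width profile
#: (uniform eighths of plant height)
DEFAULT_REL_HEIGHTS = (0.0, 0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875, 1.0)

#: reproductive-stage mean dates, days after emergence
DEFAULT_STAGE_MEANS = {"R1": 36.0, "R2": 44.0, "R3": 51.0, "R4": 59.0, "R5": 67.0}


class ConfigurationError(ValueError):
    """Inconsistent design/truth dimensions."""


@dataclass(frozen=True)
class TrialDesign:
    """Shape of the simulated trial (who, when, and on what grids)."""

    n_accessions: int = 40
    years: tuple[int, ...] = (2018, 2019)
    reps_per_year: dict[int, int] = field(
        default_factory=lambda: {2018: 4, 2019: 2}
    )
    cc_days: tuple[float, ...] = tuple(float(d) for d in range(10, 78, 6))
    li_height_step: float = 0.1
    shape_rel_heights: tuple[float, ...] = DEFAULT_REL_HEIGHTS
    plants_per_plot: int = 6

    def __post_init__(self) -> None:
        if self.n_accessions < 1:
            raise ConfigurationError("need at least one accession")
        if any(self.reps_per_year.get(y, 0) < 1 for y in self.years):
            raise ConfigurationError("every year needs >= 1 replicate")
        if np.any(np.diff(self.cc_days) <= 0):
            raise ConfigurationError("cc_days must be strictly increasing")
        rh = np.asarray(self.shape_rel_heights)
        if rh[0] != 0 or rh[-1] != 1 or np.any(np.diff(rh) <= 0):
            raise ConfigurationError(
                "shape_rel_heights must be sorted from 0 to 1"
            )

    @property
    def accessions(self) -> list[str]:
        return [f"ACC{i + 1:03d}" for i in range(self.n_accessions)]

    @property
    def plots(self) -> list[tuple[str, int, int]]:
        return [
            (a, y, b)
            for y in self.years
            for b in range(1, self.reps_per_year[y] + 1)
            for a in self.accessions
        ]


# latent per-plot traits and their defaults:
# (mean, sigma_G, sigma_Y, sigma_B, sigma_GxY, sigma_eps), trait units
_TRAIT_DEFAULTS: dict[str, tuple[float, float, float, float, float, float]] = {
    # logistic CC parameters
    "cc_L":   (0.92, 0.05, 0.01, 0.005, 0.015, 0.02),
    "cc_k":   (0.18, 0.025, 0.008, 0.004, 0.008, 0.012),
    "cc_t0":  (38.0, 4.0, 1.5, 0.8, 1.5, 1.5),
    # transmittance parameters
    "li_k":   (8.0, 1.5, 0.4, 0.2, 0.5, 0.8),
    "li_h0":  (0.60, 0.08, 0.02, 0.01, 0.03, 0.04),
    # beta outline: alpha = 1 + exp(latent), same for beta
    "sh_w":       (0.25, 0.035, 0.008, 0.004, 0.012, 0.022),
    "log_alpham1": (0.40, 0.25, 0.05, 0.03, 0.10, 0.30),
    "log_betam1":  (-0.20, 0.25, 0.05, 0.03, 0.10, 0.30),
    # architecture traits (m, degrees, counts)
    "PH":  (0.95, 0.10, 0.03, 0.02, 0.04, 0.06),
    "NO":  (15.0, 1.6, 0.5, 0.3, 0.6, 0.9),
    "IL4": (0.055, 0.007, 0.002, 0.001, 0.003, 0.004),
    "IS4": (0.010, 0.0022, 0.0006, 0.0003, 0.0008, 0.0012),
    "PL4": (0.15, 0.022, 0.006, 0.003, 0.008, 0.012),
    "PS4": (0.020, 0.004, 0.001, 0.0006, 0.0015, 0.0022),
    "PA4": (45.0, 5.5, 1.5, 1.0, 2.5, 4.0),
    "PA5": (50.0, 5.5, 1.5, 1.0, 2.5, 4.0),
    "LL":  (0.12, 0.013, 0.004, 0.002, 0.005, 0.007),
    "LW":  (0.07, 0.008, 0.002, 0.001, 0.003, 0.004),
    "LA":  (0.0065, 0.0008, 0.0002, 0.0001, 0.0003, 0.0004),
    "BA":  (40.0, 5.0, 1.5, 1.0, 2.5, 3.5),
    "BO":  (90.0, 9.0, 2.5, 1.5, 4.0, 7.0),
    "BN":  (5.0, 1.0, 0.3, 0.2, 0.4, 0.6),
    "BZ":  (0.35, 0.05, 0.015, 0.008, 0.02, 0.03),
}

_CLIPS = {
    "cc_L": (0.3, 1.0), "cc_k": (0.04, 1.5), "cc_t0": (15.0, 70.0),
    "li_k": (2.0, 40.0), "li_h0": (0.2, 0.95), "sh_w": (0.05, 0.8),
    "PH": (0.3, None), "NO": (6.0, None), "IL4": (0.01, None),
    "PL4": (0.02, None), "PA4": (5.0, 175.0), "PA5": (5.0, 175.0),
    "LL": (0.02, None), "LW": (0.01, None), "LA": (0.0005, None),
    "BA": (5.0, 175.0), "BO": (0.0, 179.0), "BN": (0.0, None),
    "BZ": (0.02, None),
}


def _clip(name: str, v: float) -> float:
    lo, hi = _CLIPS.get(name, (None, None))
    if lo is not None:
        v = max(v, lo)
    if hi is not None:
        v = min(v, hi)
    return v


@dataclass
class TruthParams:
    """Ground truth for one simulated trial.

    ``accession_values[trait]`` holds the per-accession true values
    (trait mean + genotype effect); ``variance_components[trait]`` maps
    G/Y/B/GxY/eps to variances.  Observation-noise levels sit beside
    the structural components so a fully noise-free dataset is one
    configuration away.
    """

    accession_values: dict[str, np.ndarray]
    variance_components: dict[str, dict[str, float]]
    rng_seed: int
    cc_noise_sd: float = 0.02
    tpar_noise_sd: float = 0.02
    width_noise_frac: float = 0.05
    within_plot_frac: float = 0.03
    stage_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MEANS)
    )

    def __post_init__(self) -> None:
        for trait, comps in self.variance_components.items():
            if any(v < 0 for v in comps.values()):
                raise ConfigurationError(f"negative variance for {trait}")
        for trait, vals in self.accession_values.items():
            if trait == "cc_L" and np.any((vals <= 0) | (vals > 1)):
                raise ConfigurationError("cc_L must lie in (0, 1]")
            if trait in ("cc_k", "li_k") and np.any(vals <= 0):
                raise ConfigurationError(f"{trait} must be positive")

    @classmethod
    def default(cls, design: TrialDesign, seed: int = 0, **overrides) -> "TruthParams":
        """Draw per-accession truth at the default trait means/components."""
        rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
        acc_values: dict[str, np.ndarray] = {}
        comps: dict[str, dict[str, float]] = {}
        for trait, (mean, sg, sy, sb, sgy, se) in _TRAIT_DEFAULTS.items():
            draws = mean + sg * rng.standard_normal(design.n_accessions)
            acc_values[trait] = np.array([_clip(trait, v) for v in draws])
            comps[trait] = {
                "G": sg ** 2, "Y": sy ** 2, "B": sb ** 2,
                "GxY": sgy ** 2, "eps": se ** 2,
            }
        return cls(accession_values=acc_values, variance_components=comps,
                   rng_seed=seed, **overrides)

    def shape_truth(self, i: int) -> ShapeFit:
        """True (Sh_W, Sh_H, Sh_A) outline for accession ``i``."""
        a = 1.0 + math.exp(self.accession_values["log_alpham1"][i])
        b = 1.0 + math.exp(self.accession_values["log_betam1"][i])
        return ShapeFit(alpha=a, beta=b, sh_w=float(self.accession_values["sh_w"][i]))


@dataclass
class SimulatedTrial:
    """One generated dataset plus the values that generated it."""

    design: TrialDesign
    truth: TruthParams
    cc_series: list[CCSeries]
    li_profiles: list[LIProfile]
    shape_profiles: list[ShapeProfile]
    plants: dict[tuple[str, int, int], list[PlantRecord]]
    phenology: pd.DataFrame
    trait_table: pd.DataFrame
    plot_values: dict[str, dict[tuple[str, int, int], float]]
    effects: dict[str, dict[str, dict]]

    def to_csvs(self, outdir: str | Path) -> dict[str, Path]:
        """Write the generator's CSV/JSON interface files; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        rows = [
            (s.accession, s.year, s.block, d, c)
            for s in self.cc_series
            for d, c in zip(s.dae, s.cc)
        ]
        paths["cc_series"] = outdir / "cc_series.csv"
        pd.DataFrame(rows, columns=["accession", "year", "block", "dae", "cc"]
                     ).to_csv(paths["cc_series"], index=False)

        rows = [
            (p.accession, p.year, p.block, h, t, p.plant_height)
            for p in self.li_profiles
            for h, t in zip(p.heights, p.tpar)
        ]
        paths["li_profiles"] = outdir / "li_profiles.csv"
        pd.DataFrame(rows, columns=["accession", "year", "block", "height_m",
                                    "tpar", "plant_height_m"]
                     ).to_csv(paths["li_profiles"], index=False)

        rows = [
            (p.accession, p.year, p.block, p.plant, x, w, p.plant_height)
            for p in self.shape_profiles
            for x, w in zip(p.rel_height, p.halfwidth)
        ]
        paths["shape_profiles"] = outdir / "shape_profiles.csv"
        pd.DataFrame(rows, columns=["accession", "year", "block", "plant",
                                    "rel_height", "halfwidth_m", "plant_height_m"]
                     ).to_csv(paths["shape_profiles"], index=False)

        rows = []
        for (acc, year, block), plist in self.plants.items():
            for p in plist:
                rows.append({
                    "accession": acc, "year": year, "block": block,
                    "plant": p.plant, "plant_height_m": p.plant_height,
                    "node_count": p.node_count,
                    **{f"petiole_{n}_m": p.petiole_lengths.get(n, math.nan)
                       for n in range(1, 8)},
                    **{f"internode_{n}_m": p.internode_lengths.get(n, math.nan)
                       for n in range(1, 8)},
                    "pa4_deg": p.petiole_angles.get(4, math.nan),
                    "pa5_deg": p.petiole_angles.get(5, math.nan),
                    "branches": ";".join(
                        f"{b.node_height:.6g}:{b.angle:.6g}:{b.orientation:.6g}"
                        for b in p.branches),
                    "leaflets": ";".join(
                        f"{lf.length:.6g}:{lf.width:.6g}:{lf.area:.6g}"
                        for lf in p.leaflets),
                })
        paths["plants"] = outdir / "plants.csv"
        pd.DataFrame(rows).to_csv(paths["plants"], index=False)

        paths["phenology"] = outdir / "phenology.csv"
        self.phenology.to_csv(paths["phenology"], index=False)

        paths["truth"] = outdir / "truth.json"
        truth_doc = {
            "rng_seed": self.truth.rng_seed,
            "accessions": self.design.accessions,
            "accession_values": {
                k: v.tolist() for k, v in self.truth.accession_values.items()
            },
            "variance_components": self.truth.variance_components,
            "noise": {
                "cc_noise_sd": self.truth.cc_noise_sd,
                "tpar_noise_sd": self.truth.tpar_noise_sd,
                "width_noise_frac": self.truth.width_noise_frac,
                "within_plot_frac": self.truth.within_plot_frac,
            },
        }
        paths["truth"].write_text(json.dumps(truth_doc, indent=1))
        return paths


def generate_cc_series(
    L: float, k: float, t0: float, days, noise_sd: float,
    rng: np.random.Generator | None = None,
    accession: str = "SYN", year: int = 0, block: int = 0,
) -> CCSeries:
    """Logistic CC trajectory with Gaussian noise, clipped to [0, 1]."""
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise ValueError("empty day list")
    if not (0 < L <= 1):
        raise ValueError("L must lie in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    cc = logistic(days, L, k, t0)
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        cc = cc + noise_sd * rng.standard_normal(days.size)
    return CCSeries(accession, year, block, days, np.clip(cc, 0.0, 1.0))


def _draw_effects(rng, design: TrialDesign, comps: dict[str, float]):
    """Year / block(year) / GxY / plot-residual effects for one trait."""
    years = design.years
    eff = {
        "year": {y: rng.normal(0.0, math.sqrt(comps["Y"])) for y in years},
        "block": {
            (y, b): rng.normal(0.0, math.sqrt(comps["B"]))
            for y in years for b in range(1, design.reps_per_year[y] + 1)
        },
        "gxy": {
            (a, y): rng.normal(0.0, math.sqrt(comps["GxY"]))
            for a in design.accessions for y in years
        },
        "eps": {
            plot: rng.normal(0.0, math.sqrt(comps["eps"]))
            for plot in design.plots
        },
    }
    return eff


def generate_trial(design: TrialDesign, truth: TruthParams) -> SimulatedTrial:
    """Simulate every observation layer of one field trial.

    Deterministic in ``truth.rng_seed``; the returned object carries the
    generating plot values and random effects next to the observations.
    """
    for trait, vals in truth.accession_values.items():
        if len(vals) != design.n_accessions:
            raise ConfigurationError(
                f"truth for {trait!r} has {len(vals)} accessions, "
                f"design expects {design.n_accessions}"
            )
    ss = np.random.SeedSequence([int(truth.rng_seed), 77])
    rng_eff, rng_cc, rng_li, rng_shape, rng_plant, rng_phen = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    acc_index = {a: i for i, a in enumerate(design.accessions)}
    traits = list(truth.accession_values)
    effects = {t: _draw_effects(rng_eff, design, truth.variance_components[t])
               for t in traits}

    plot_values: dict[str, dict[tuple[str, int, int], float]] = {
        t: {} for t in traits
    }
    for t in traits:
        eff = effects[t]
        base = truth.accession_values[t]
        for plot in design.plots:
            a, y, b = plot
            v = (base[acc_index[a]] + eff["year"][y] + eff["block"][(y, b)]
                 + eff["gxy"][(a, y)] + eff["eps"][plot])
            plot_values[t][plot] = _clip(t, float(v))

    days = np.asarray(design.cc_days, dtype=float)
    cc_series = [
        generate_cc_series(
            plot_values["cc_L"][plot], plot_values["cc_k"][plot],
            plot_values["cc_t0"][plot], days, truth.cc_noise_sd,
            rng_cc, accession=plot[0], year=plot[1], block=plot[2],
        )
        for plot in design.plots
    ]

    li_profiles = []
    for plot in design.plots:
        ph = plot_values["PH"][plot]
        heights = np.arange(0.0, ph + 1e-9, design.li_height_step)
        tp = transmittance(heights / ph, plot_values["li_k"][plot],
                           plot_values["li_h0"][plot])
        if truth.tpar_noise_sd > 0:
            tp = tp + truth.tpar_noise_sd * rng_li.standard_normal(tp.size)
        li_profiles.append(LIProfile(plot[0], plot[1], plot[2], heights,
                                     np.clip(tp, 0.0, 1.0), ph))

    rel_h = np.asarray(design.shape_rel_heights, dtype=float)
    shape_profiles = []
    plants: dict[tuple[str, int, int], list[PlantRecord]] = {}
    wp = truth.within_plot_frac
    for plot in design.plots:
        acc, year, block = plot
        pv = {t: plot_values[t][plot] for t in traits}
        plist = []
        for j in range(1, design.plants_per_plot + 1):
            def plant_val(name, floor=None, scale=None):
                m = pv[name]
                s = wp * (scale if scale is not None else abs(m))
                v = m + (rng_plant.normal(0.0, s) if s > 0 else 0.0)
                return max(v, floor) if floor is not None else v

            # outline widths from the plot's beta parameters
            a_p = 1.0 + math.exp(plant_val("log_alpham1", scale=1.0))
            b_p = 1.0 + math.exp(plant_val("log_betam1", scale=1.0))
            sw_p = plant_val("sh_w", floor=1e-3)
            ph_p = plant_val("PH", floor=0.2)
            fit = ShapeFit(alpha=a_p, beta=b_p, sh_w=sw_p)
            w = outline(rel_h, fit)
            if truth.width_noise_frac > 0:
                w = w * (1.0 + truth.width_noise_frac
                         * rng_shape.standard_normal(w.size))
            shape_profiles.append(ShapeProfile(
                acc, year, block, j, rel_h, np.maximum(w, 0.0), ph_p))

            il4, is4 = plant_val("IL4", floor=5e-3), plant_val("IS4")
            pl4, ps4 = plant_val("PL4", floor=5e-3), plant_val("PS4")
            internodes = {n: max(il4 + is4 * (n - 4), 1e-4) for n in range(1, 8)}
            petioles = {n: max(pl4 + ps4 * (n - 4), 1e-4) for n in range(1, 8)}
            bn = int(round(max(plant_val("BN"), 0.0)))
            bz = min(plant_val("BZ", floor=0.02), ph_p)
            branches = []
            if bn > 0:
                hts = np.sort(rng_plant.uniform(0.02, bz, size=bn))
                hts[-1] = bz  # highest branch defines the branching zone
                for hgt in hts:
                    branches.append(Branch(
                        node_height=float(hgt),
                        angle=float(np.clip(
                            rng_plant.normal(pv["BA"], wp * pv["BA"] + 1e-9),
                            1.0, 179.0)),
                        orientation=float(
                            rng_plant.normal(pv["BO"], wp * pv["BO"] + 1e-9)
                            % 180.0),
                    ))
            leaflets = [
                Leaflet(length=plant_val("LL", floor=1e-3),
                        width=plant_val("LW", floor=1e-3),
                        area=plant_val("LA", floor=1e-6))
                for _ in range(3)
            ]
            plist.append(PlantRecord(
                plant=j, plant_height=ph_p,
                node_count=max(int(round(plant_val("NO"))), 8),
                petiole_lengths=petioles, internode_lengths=internodes,
                branches=branches, leaflets=leaflets,
                petiole_angles={4: plant_val("PA4"), 5: plant_val("PA5")},
            ))
        plants[plot] = plist

    # phenology: accession-level stage shifts plus small plot noise
    stage_shift = {
        a: rng_phen.normal(0.0, 2.0) for a in design.accessions
    }
    phen_rows = []
    for plot in design.plots:
        a, y, b = plot
        row = {"accession": a, "year": y, "block": b}
        for stage, mean in truth.stage_means.items():
            row[stage] = round(mean + stage_shift[a] + rng_phen.normal(0.0, 1.0), 1)
        phen_rows.append(row)
    phenology = pd.DataFrame(phen_rows)

    # long-format trait table of the latent plot values (+ derived traits)
    tt_rows = []
    for plot in design.plots:
        a, y, b = plot
        pv = {t: plot_values[t][plot] for t in traits}
        derived = {
            "CH": 6.0 * pv["IL4"] - 3.0 * pv["IS4"],
            "IL5": pv["IL4"] + pv["IS4"],
            "PL5": pv["PL4"] + pv["PS4"],
            "BD": pv["BN"] / pv["BZ"] if pv["BZ"] > 0 else math.nan,
            "BR": min(pv["BZ"] / pv["PH"], 1.0),
        }
        for t, v in {**pv, **derived}.items():
            tt_rows.append((a, y, b, t, v))
    trait_table = pd.DataFrame(
        tt_rows, columns=["accession", "year", "block", "trait", "value"]
    )

    return SimulatedTrial(
        design=design, truth=truth, cc_series=cc_series,
        li_profiles=li_profiles, shape_profiles=shape_profiles,
        plants=plants, phenology=phenology, trait_table=trait_table,
        plot_values=plot_values, effects=effects,
    )
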