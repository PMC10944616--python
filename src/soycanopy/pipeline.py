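"""End-to-end orchestration: simulate -> fit -> traits -> assimilate -> stats.

Each stage is a pure function from named CSV inputs to named CSV
outputs; :func:`run_pipeline` chains them under one declarative
:class:`RunConfig` and writes a JSON manifest recording the seed, every
numeric parameter in effect, per-file row counts and content checksums,
so a rerun with the same config and seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assim, genostats, io
from .cc import cc_at, fit_cc
from .li import fit_li
from .shape import ShapeFit, fit_shape
from .synthetic import TrialDesign, TruthParams, generate_trial
from .traits import plants_to_trait_table

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "stage_simulate",
    "stage_fit_cc",
    "stage_fit_li",
    "stage_fit_shape",
    "stage_traits",
    "stage_assimilate",
    "stage_blup",
    "stage_correlate",
    "stage_heatmap",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


@dataclass
class RunConfig:
    """Declarative run description.

    Exactly one of ``inputs`` (paths to existing CSV layers) or
    ``simulate`` (True, generating them) must be active.
    """

    outdir: str = "soycanopy_run"
    seed: int = 0
    simulate: bool = True
    inputs: dict[str, str] | None = None
    n_accessions: int = 40
    acc_window: tuple[float, float] | None = None
    lrc: dict[str, float] = field(default_factory=lambda: {
        "phi": 0.05, "amax": 25.0, "theta": 0.7, "rd": 1.0})
    par_levels: tuple[float, ...] = assim.DEFAULT_PAR_LEVELS
    par_step: float = 10.0
    fdr_alpha: float = 0.05
    anchor_trait: str = "ACC"

    def __post_init__(self) -> None:
        if self.simulate and self.inputs:
            raise ValueError("config must set either simulate or inputs, not both")
        if not self.simulate and not self.inputs:
            raise ValueError("config needs input paths when simulate is off")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.inputs:
            required = ("cc_series", "li_profiles", "shape_profiles",
                        "plants", "phenology")
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ValueError(f"missing input path(s): {', '.join(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "acc_window" in doc and doc["acc_window"] is not None:
            doc["acc_window"] = tuple(doc["acc_window"])
        if "par_levels" in doc:
            doc["par_levels"] = tuple(doc["par_levels"])
        return cls(**doc)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def stage_simulate(config: RunConfig, outdir: Path) -> dict[str, Path]:
    design = TrialDesign(n_accessions=config.n_accessions)
    truth = TruthParams.default(design, seed=config.seed)
    trial = generate_trial(design, truth)
    return trial.to_csvs(outdir)


def stage_fit_cc(cc_path: Path, phenology_path: Path | None, outdir: Path,
                 window: tuple[float, float] | None = None) -> Path:
    series = io.read_cc_series(cc_path)
    r2 = {}
    if phenology_path is not None:
        phen = io.read_phenology(phenology_path)
        r2 = {
            (str(r.accession), int(r.year), int(r.block)): float(r.R2)
            for r in phen.itertuples()
        }
    rows = []
    for s in series:
        fit = fit_cc(s, window=window)
        key = (s.accession, s.year, s.block)
        ccr2 = cc_at(fit, r2[key]) if fit.converged and key in r2 else math.nan
        rows.append({
            "accession": s.accession, "year": s.year, "block": s.block,
            "L": fit.L, "k": fit.k, "t0": fit.t0,
            "ACC": fit.acc, "CC50": fit.cc50, "CCR2": ccr2,
            "MCC_d": fit.mcc_d, "MCC_w": fit.mcc_w,
            "adj_r2": fit.adj_r2, "aic": fit.aic,
            "converged": fit.converged, "flags": "|".join(fit.flags),
        })
    out = outdir / "cc_fits.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def stage_fit_li(li_path: Path, outdir: Path) -> Path:
    rows = []
    for p in io.read_li_profiles(li_path):
        fit = fit_li(p)
        rows.append({
            "accession": p.accession, "year": p.year, "block": p.block,
            "k_li": fit.k_li, "h0": fit.h0,
            "PARG": fit.parg, "PAR50H": fit.par50h, "H50PAR": fit.h50par,
            "adj_r2": fit.adj_r2, "converged": fit.converged,
            "flags": "|".join(fit.flags),
        })
    out = outdir / "li_fits.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def stage_fit_shape(shape_path: Path, outdir: Path) -> Path:
    rows = []
    for p in io.read_shape_profiles(shape_path):
        fit = fit_shape(p)
        rows.append({
            "accession": p.accession, "year": p.year, "block": p.block,
            "plant": p.plant, "alpha": fit.alpha, "beta": fit.beta,
            "Sh_W": fit.sh_w, "Sh_H": fit.sh_h, "Sh_A": fit.sh_a,
            "rms": fit.rms, "converged": fit.converged,
            "flags": "|".join(fit.flags),
        })
    out = outdir / "shape_fits.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def stage_traits(plants_path: Path, outdir: Path) -> Path:
    table = plants_to_trait_table(io.read_plants(plants_path))
    out = outdir / "plot_traits.csv"
    table.to_csv(out, index=False)
    return out


def stage_assimilate(shape_fits_path: Path, li_fits_path: Path, outdir: Path,
                     lrc_params: dict[str, float],
                     par_levels, par_step: float = 10.0) -> tuple[Path, Path]:
    shapes_df = pd.read_csv(shape_fits_path)
    li_df = pd.read_csv(li_fits_path)
    lrc = assim.LightResponse(**lrc_params)
    grid = np.arange(0.0, 1801.0, par_step)

    shapes: dict[str, ShapeFit] = {}
    for acc, g in shapes_df[shapes_df["converged"]].groupby("accession"):
        shapes[str(acc)] = ShapeFit(alpha=float(g["alpha"].mean()),
                                    beta=float(g["beta"].mean()),
                                    sh_w=float(g["Sh_W"].mean()))
    from .li import LIFit
    lifits: dict[str, LIFit] = {}
    for acc, g in li_df[li_df["converged"]].groupby("accession"):
        lifits[str(acc)] = LIFit(k_li=float(g["k_li"].mean()),
                                 h0=float(g["h0"].mean()))
    common = sorted(set(shapes) & set(lifits))
    panel = {
        acc: assim.assimilation_curve(shapes[acc], lifits[acc], lrc, grid)
        for acc in common
    }
    curves_rows = [
        (acc, i0, a)
        for acc, curve in panel.items()
        for i0, a in zip(grid, curve)
    ]
    curves_out = outdir / "assimilation_curves.csv"
    pd.DataFrame(curves_rows, columns=["accession", "par", "a_row"]
                 ).to_csv(curves_out, index=False)

    corr = assim.shape_assim_correlation(
        {a: shapes[a] for a in common}, panel, grid, par_levels)
    corr_out = outdir / "shape_assim_correlations.csv"
    corr.to_csv(corr_out, index=False)
    return curves_out, corr_out


_DERIVED_TRAIT_COLS = {
    "cc": ["ACC", "CC50", "CCR2", "MCC_d", "MCC_w"],
    "li": ["PARG", "PAR50H", "H50PAR"],
    "shape": ["Sh_W", "Sh_H", "Sh_A"],
}


def assemble_trait_table(plot_traits_path: Path, cc_fits_path: Path,
                         li_fits_path: Path, shape_fits_path: Path
                         ) -> pd.DataFrame:
    """Merge architecture traits with fitted CC/LI/shape traits into one
    long plot-level table."""
    parts = [pd.read_csv(plot_traits_path)]
    keys = ["accession", "year", "block"]
    for kind, path in (("cc", cc_fits_path), ("li", li_fits_path),
                       ("shape", shape_fits_path)):
        df = pd.read_csv(path)
        if "converged" in df:
            df = df[df["converged"]]
        if kind == "shape":   # plant-level fits -> plot means
            df = df.groupby(keys, as_index=False)[
                _DERIVED_TRAIT_COLS[kind]].mean()
        part = df.melt(id_vars=keys, value_vars=_DERIVED_TRAIT_COLS[kind],
                       var_name="trait", value_name="value")
        parts.append(part)
    table = pd.concat(parts, ignore_index=True)
    table["accession"] = table["accession"].astype(str)
    return table


def stage_blup(trait_table: pd.DataFrame, outdir: Path
               ) -> tuple[Path, Path, Path]:
    varcomp_rows, rel_rows, blup_cols = [], [], {}
    for trait in sorted(trait_table["trait"].unique()):
        try:
            vc = genostats.fit_random_model(trait_table, trait)
        except ValueError as exc:
            logger.warning("skipping trait %s: %s", trait, exc)
            continue
        varcomp_rows.append({
            "trait": trait, "sigma2_G": vc.sigma2_G, "sigma2_Y": vc.sigma2_Y,
            "sigma2_B": vc.sigma2_B, "sigma2_GxY": vc.sigma2_GxY,
            "sigma2_eps": vc.sigma2_eps, "converged": vc.converged,
            "flags": "|".join(vc.flags),
        })
        for year, rel in vc.reliability_by_year.items():
            rel_rows.append({"trait": trait, "year": year, "reliability": rel})
        rel_rows.append({"trait": trait, "year": "pooled",
                         "reliability": vc.reliability_pooled})
        blup_cols[trait] = vc.blups
    varcomp_out = outdir / "varcomp.csv"
    pd.DataFrame(varcomp_rows).to_csv(varcomp_out, index=False)
    rel_out = outdir / "reliability.csv"
    pd.DataFrame(rel_rows).to_csv(rel_out, index=False)
    blups = pd.DataFrame(blup_cols)
    blups.index.name = "accession"
    blups_out = outdir / "blups.csv"
    blups.to_csv(blups_out)
    return varcomp_out, blups_out, rel_out


def stage_correlate(blups_path: Path, outdir: Path) -> Path:
    blups = pd.read_csv(blups_path, index_col="accession")
    rows = []
    for method in ("pearson", "spearman"):
        r, p, q = genostats.correlation_matrix(blups, method=method)
        traits = list(r.columns)
        for i, t1 in enumerate(traits):
            for t2 in traits[i + 1:]:
                rows.append({"method": method, "trait_1": t1, "trait_2": t2,
                             "r": r.loc[t1, t2], "p": p.loc[t1, t2],
                             "p_fdr": q.loc[t1, t2]})
    out = outdir / "correlations.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def stage_heatmap(blups_path: Path, outdir: Path, anchor: str = "ACC",
                  alpha: float = 0.05) -> Path:
    blups = pd.read_csv(blups_path, index_col="accession")
    z, rows, cols = genostats.heatmap_matrix(blups, anchor_trait=anchor,
                                             alpha=alpha)
    out = outdir / "heatmap_matrix.csv"
    z.to_csv(out)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def run(stage_name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {stage_name!r} failed: {exc}") from exc

    if config.simulate:
        inputs = run("simulate", stage_simulate, config, outdir)
    else:
        inputs = {k: Path(v) for k, v in config.inputs.items()}
        for k, v in inputs.items():
            if not v.exists():
                raise StageError(f"stage 'inputs' failed: missing file {v} "
                                 f"for field {k!r}")
    files.update(inputs)

    files["cc_fits"] = run("fit-cc", stage_fit_cc, inputs["cc_series"],
                           inputs.get("phenology"), outdir,
                           window=config.acc_window)
    files["li_fits"] = run("fit-li", stage_fit_li, inputs["li_profiles"], outdir)
    files["shape_fits"] = run("fit-shape", stage_fit_shape,
                              inputs["shape_profiles"], outdir)
    files["plot_traits"] = run("traits", stage_traits, inputs["plants"], outdir)
    files["assimilation_curves"], files["shape_assim_correlations"] = run(
        "assimilate", stage_assimilate, files["shape_fits"], files["li_fits"],
        outdir, config.lrc, config.par_levels, config.par_step)
    table = assemble_trait_table(files["plot_traits"], files["cc_fits"],
                                 files["li_fits"], files["shape_fits"])
    files["varcomp"], files["blups"], files["reliability"] = run(
        "blup", stage_blup, table, outdir)
    files["correlations"] = run("correlate", stage_correlate,
                                files["blups"], outdir)
    files["heatmap_matrix"] = run("heatmap", stage_heatmap, files["blups"],
                                  outdir, config.anchor_trait, config.fdr_alpha)

    manifest = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "files": {},
    }
    for name, path in files.items():
        entry = {"path": str(path), "checksum": _checksum(path)}
        if path.suffix == ".csv":
            entry["rows"] = int(len(pd.read_csv(path)))
        manifest["files"][name] = entry
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
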