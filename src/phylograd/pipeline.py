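"""End-to-end orchestration: data in, grafted tree, NRI, SEMs, tables out.

`run_all` drives the full analysis for either a synthetic study or user-
supplied files: graft species missing from the tree at their congeneric MRCA,
prune to the recorded species, compute patristic distances, per life-form
richness and NRI, then fit the a priori piecewise SEM twice per group —
species richness with a Poisson family and NRI with a Gaussian family — and
write the fit statistics and a total-effects table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import phylo, sem, simulate

__all__ = ["RunConfig", "run_all", "summarize_gradient", "load_study_inputs",
           "significance_stars", "table1"]

logger = logging.getLogger(__name__)

GROUPS = ("all",) + simulate.LIFE_FORMS


@dataclass
class RunConfig:
    """Inputs and knobs for one full pipeline run.

    Exactly one of ``input_dir`` (tree.nwk, community.tsv, environment.tsv,
    species.tsv) or ``synthetic=True`` must be chosen. ``groups`` selects the
    life-form subsets analyzed alongside the pooled ("all") community.
    """

    synthetic: bool = True
    input_dir: str | None = None
    outdir: str | None = None
    n_null: int = 1000
    seed: int = 0
    groups: tuple = GROUPS
    weighted: bool = True
    swap_thin: int = 1000
    n_species: int = 689
    n_genera: int = 60
    plots_per_cell: int = 5
    filter_strength: float = 1.0
    beta: dict | None = None

    def __post_init__(self):
        if self.synthetic == (self.input_dir is not None):
            raise ValueError("choose exactly one of synthetic or input_dir")
        if self.n_null < 2:
            raise ValueError("n_null must be >= 2")
        unknown = [g for g in self.groups if g not in GROUPS]
        if unknown:
            raise ValueError(f"unknown groups {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)


def load_study_inputs(input_dir) -> tuple:
    """Load tree, community, environment and species tables from a directory.

    Expects ``tree.nwk`` (Newick), ``community.tsv`` (plot x species, first
    column ``plot``), ``environment.tsv`` (plot, site, FUI, Temp, Precip,
    PET[, PET2]) and ``species.tsv`` (species, life_form) as written by
    :meth:`phylograd.simulate.SyntheticStudy.write`.
    """
    d = Path(input_dir)
    tree = phylo.read_newick(d / "tree.nwk")
    community = pd.read_csv(d / "community.tsv", sep="\t", index_col="plot")
    env = pd.read_csv(d / "environment.tsv", sep="\t")
    species = pd.read_csv(d / "species.tsv", sep="\t")
    if "PET2" not in env.columns:
        env["PET2"] = env["PET"] ** 2
    return tree, community, env, species


def _prepare_tree(tree, community) -> tuple:
    """Graft community species missing from the tree, then prune to them."""
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    recorded = [phylo.canonical_name(s) for s in community.columns]
    missing = sorted(set(recorded) - tips)
    report = phylo.GraftReport()
    if missing:
        tree, report = phylo.graft_missing(tree, missing)
        if report.excluded:
            raise ValueError(
                "species absent from the tree with no congeners to graft "
                f"onto: {report.excluded[:10]}")
    pruned = phylo.prune_to_species(tree, recorded)
    return pruned, report


def _group_members(species: pd.DataFrame, group: str) -> list:
    if group == "all":
        return list(species["species"])
    known = species.dropna(subset=["life_form"])
    unknown = len(species) - len(known)
    if unknown:
        logger.warning("%d species with unknown life form kept only in 'all'",
                       unknown)
    return list(known.loc[known["life_form"] == group, "species"])


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def table1(results: dict) -> pd.DataFrame:
    """Total standardized effects per group x predictor with stars.

    Mirrors a publication-style layout: one row per (measure, group), one
    column per predictor; a cell shows the total standardized effect with
    stars for the direct edge's Wald p at 0.05 / 0.01 / 0.001.
    """
    predictors = ("Temp", "Precip", "PET", "PET2", "FUI")
    rows = []
    for (measure, group), fit in results.items():
        row = {"measure": measure, "group": group}
        comp = fit.components[fit.response]
        for p in predictors:
            if p not in fit.effects.index:
                row[p] = ""
                continue
            total = fit.effects.loc[p, "total"]
            pval = comp.pvalues.get(p, float("nan"))
            row[p] = f"{total:.3f}{significance_stars(pval)}"
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_gradient(nri_tables: dict, env: pd.DataFrame) -> pd.DataFrame:
    """Per site x group mean richness and mean NRI with standard errors.

    Plots with missing NRI are excluded from the NRI mean and its n.
    """
    site_of = env.set_index("plot")["site"]
    elev_of = env.set_index("plot")["elevation"]
    rows = []
    for group, tab in nri_tables.items():
        t = tab.copy()
        t["site"] = site_of.reindex(t.index).to_numpy()
        t["elevation"] = elev_of.reindex(t.index).to_numpy()
        for site, sub in t.groupby("site", sort=False):
            nri_ok = sub["nri"].dropna()
            rows.append({
                "group": group, "site": site,
                "elevation": float(sub["elevation"].iloc[0]),
                "n_plots": len(sub),
                "mean_richness": float(sub["richness"].mean()),
                "se_richness": float(sub["richness"].sem()),
                "n_nri": len(nri_ok),
                "mean_nri": float(nri_ok.mean()) if len(nri_ok) else float("nan"),
                "se_nri": float(nri_ok.sem()) if len(nri_ok) > 1 else float("nan"),
            })
    out = pd.DataFrame(rows)
    return out.sort_values(["group", "elevation"]).reset_index(drop=True)


@dataclass
class RunResult:
    fits: dict                  # (measure, group) -> SEMFit
    nri_tables: dict            # group -> per-plot table
    table1: pd.DataFrame
    gradient: pd.DataFrame
    graft_report: phylo.GraftReport
    log: list = field(default_factory=list)


def run_all(config: RunConfig) -> RunResult:
    """Execute the full gradient analysis and (optionally) write outputs."""
    t0 = time.time()
    log: list = []

    def stage(name, **counts):
        entry = {"stage": name, "elapsed_s": round(time.time() - t0, 2),
                 **counts}
        log.append(entry)
        logger.info("%s %s", name, counts)

    if config.synthetic:
        params = simulate.AssemblyParams(
            n_species=config.n_species,
            filter_strength=config.filter_strength,
            **({"beta": dict(config.beta)} if config.beta else {}))
        design = simulate.DesignSpec(plots_per_cell=config.plots_per_cell,
                                     seed=config.seed)
        study = simulate.simulate_study(design=design, params=params,
                                        n_genera=config.n_genera,
                                        seed=config.seed)
        tree, community_df = study.tree, study.community
        env, species = study.environment, study.species
        stage("synthesize", plots=len(env), species=community_df.shape[1])
    else:
        tree, community_df, env, species = load_study_inputs(config.input_dir)
        stage("load", plots=len(env), species=community_df.shape[1])

    tree, graft_report = _prepare_tree(tree, community_df)
    stage("graft_prune", grafted=len(graft_report.grafted),
          excluded=len(graft_report.excluded))
    D = phylo.cophenetic_matrix(tree)
    stage("distances", tips=D.shape[0])

    nri_tables: dict = {}
    fits: dict = {}
    rng = np.random.SeedSequence(config.seed).spawn(len(config.groups))
    for gseed, group in zip(rng, config.groups):
        members = [s for s in _group_members(species, group)
                   if s in community_df.columns]
        sub = community_df[members]
        occupied = sub.columns[(sub > 0).any(axis=0)]
        sub = sub[occupied]
        if sub.shape[1] < 2:
            logger.warning("group %s has < 2 recorded species; skipped", group)
            continue
        tab = comm.nri_table(sub, D, n_null=config.n_null,
                             weighted=config.weighted,
                             seed=int(gseed.generate_state(1)[0] % (2 ** 31)),
                             thin=config.swap_thin)
        nri_tables[group] = tab
        n_missing = int(tab["nri"].isna().sum())
        stage(f"nri[{group}]", plots=len(tab), excluded_plots=n_missing)

        data = env.merge(tab, left_on="plot", right_index=True, how="left")
        data["richness"] = data["richness"].fillna(0).astype(int)
        for measure, family, col in (("richness", "poisson", "richness"),
                                     ("nri", "gaussian", "nri")):
            model = sem.a_priori_model(response=col, family=family)
            try:
                fits[(measure, group)] = sem.run_psem(model, data)
            except Exception as exc:
                logger.error("SEM for %s/%s failed: %s", measure, group, exc)
            stage(f"sem[{measure},{group}]")

    t1 = table1(fits)
    gradient = summarize_gradient(nri_tables, env)
    result = RunResult(fits=fits, nri_tables=nri_tables, table1=t1,
                       gradient=gradient, graft_report=graft_report, log=log)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        t1.to_csv(out / "table1.tsv", sep="\t", index=False)
        gradient.to_csv(out / "gradient_summary.tsv", sep="\t", index=False)
        for group, tab in nri_tables.items():
            tab.to_csv(out / f"nri_{group}.tsv", sep="\t",
                       index=True, index_label="plot")
        payload = {f"{m}:{g}": fit.to_dict() for (m, g), fit in fits.items()}
        (out / "sem_fits.json").write_text(json.dumps(
            {"seed": config.seed, "n_null": config.n_null,
             "r2_note": "comparisons to single published r2 use conditional",
             "fits": payload, "log": log}, indent=2))
        graft_report.write_tsv(out / "graft_report.tsv")
    return result
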