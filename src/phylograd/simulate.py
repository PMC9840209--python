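"""Synthetic elevational study generator with known ground truth.

Emulates a nested sampling design — plots nested in forest-use levels nested
in elevational sites — together with a dated phylogeny, a conserved thermal
niche trait, climate covariates with the qualitative elevational shapes of
tropical-mountain data (temperature linear, precipitation hump-shaped, PET
U-shaped), and community assembly in which plot richness is Poisson with a
log-linear response to scaled covariates plus a site random intercept, and
membership is niche-filtered on the trait. Every stage is deterministic under
its seed, and the generator returns the ground truth (path coefficients, site
effects, expected richness) so downstream estimates have a recoverable target.

Defaults reproduce the study design this package targets: 8 sites from 30 to
3500 m a.s.l., 3 forest-use levels (old-growth < degraded < secondary), 5
plots per cell (120 plots), 689 species in five life forms.
"""

from __future__ import annotations

import json
import logging
import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .phylo import genus_of, node_depths, to_newick

__all__ = [
    "DesignSpec",
    "AssemblyParams",
    "SyntheticStudy",
    "simulate_tree",
    "simulate_environment",
    "simulate_trait",
    "assemble_communities",
    "simulate_study",
]

logger = logging.getLogger(__name__)

FUI_LEVELS = ("OG", "DE", "SE")  # old-growth < degraded < secondary
LIFE_FORMS = ("tree", "shrub", "herb", "epiphyte", "liana")

DEFAULT_ELEVATIONS = (30.0, 650.0, 1000.0, 1500.0, 2100.0, 2500.0, 3100.0, 3500.0)

#: Default true standardized path coefficients on log-richness. The magnitudes
#: echo the total-richness effect sizes typical of wet tropical elevational
#: gradients: temperature dominant and positive, precipitation positive, a
#: concave PET response (positive linear, negative quadratic term), and a
#: small negative disturbance effect.
DEFAULT_BETA = {
    "Temp": 0.40,
    "Precip": 0.30,
    "PET": 0.23,
    "PET2": -0.12,
    "FUI": -0.12,
}

DEFAULT_LIFE_FORM_FRACTIONS = {
    # fractions mirror the field proportions of a 689-species angiosperm pool
    "tree": 0.222,
    "shrub": 0.179,
    "herb": 0.332,
    "epiphyte": 0.238,
    "liana": 0.029,
}


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design: sites x forest-use levels x plots."""

    n_sites: int = 8
    elevations: tuple = DEFAULT_ELEVATIONS
    fui_levels: tuple = FUI_LEVELS
    plots_per_cell: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_sites != len(self.elevations):
            raise ValueError("n_sites must equal len(elevations)")
        if any(b <= a for a, b in zip(self.elevations, self.elevations[1:])):
            raise ValueError("elevations must be strictly increasing")
        if self.plots_per_cell < 1:
            raise ValueError("plots_per_cell must be >= 1")

    @property
    def n_plots(self) -> int:
        return self.n_sites * len(self.fui_levels) * self.plots_per_cell


@dataclass(frozen=True)
class AssemblyParams:
    """Ground-truth parameters of community assembly.

    ``beta`` maps covariate name (Temp, Precip, PET, PET2, FUI) to the true
    standardized coefficient on log plot richness. ``filter_strength`` scales
    the Gaussian thermal-niche filter on species membership (0 = neutral) and
    ``niche_breadth`` is its bandwidth in deg C. ``sd_site`` is the standard
    deviation of the site random intercept on the log scale.
    """

    n_species: int = 689
    life_form_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_LIFE_FORM_FRACTIONS))
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    intercept_log_richness: float = math.log(30.0)
    niche_breadth: float = 5.0
    filter_strength: float = 1.0
    sd_site: float = 0.2
    abundances: bool = False  # False = incidence (0/1), True = Poisson counts

    def __post_init__(self):
        total = sum(self.life_form_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("life_form_fractions must sum to 1")
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be > 0")
        if self.filter_strength < 0:
            raise ValueError("filter_strength must be >= 0")


def simulate_tree(n_species: int, birth_rate: float = 1.0,
                  death_rate: float = 0.0, n_genera: int = 60,
                  seed: int = 0) -> dendropy.Tree:
    """Simulate an ultrametric birth-death tree with monophyletic genera.

    Tips are labeled ``G<k>_s<j>``. Genera are defined by cutting the tree at
    the height at which exactly ``n_genera`` lineages are extant, so each genus
    is a clade by construction. Deterministic under ``seed``.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if death_rate >= birth_rate:
        raise ValueError("death_rate must be < birth_rate")
    if n_genera > n_species:
        raise ValueError("n_genera cannot exceed n_species")
    if n_genera < 1:
        raise ValueError("n_genera must be >= 1")
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_species, is_retain_extinct_tips=False,
        rng=random.Random(seed),
    )
    tree.is_rooted = True
    # equalize tip depths (the simulator leaves tiny numerical slack)
    depths = node_depths(tree)
    height = max(depths[l] for l in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += height - depths[leaf]

    # genus assignment: the n_genera - 1 shallowest internal nodes form an
    # ancestor-closed backbone (parents are always shallower than children);
    # on a binary tree the subtrees hanging off it are exactly n_genera
    # clades, so each genus is monophyletic and ties in depth are harmless
    depths = node_depths(tree)
    internal = sorted(tree.preorder_internal_node_iter(),
                      key=lambda nd: depths[nd])
    backbone = set(internal[:n_genera - 1])
    genera: list[list] = []
    for node in tree.preorder_node_iter():
        if node in backbone:
            continue
        parent = node.parent_node
        if parent in backbone or parent is None:
            genera.append(list(node.leaf_iter()) if not node.is_leaf()
                          else [node])
    if len(genera) != n_genera:
        raise RuntimeError(
            f"genus partition produced {len(genera)} clades, "
            f"expected {n_genera} (is the tree non-binary?)")
    for k, clade in enumerate(sorted(genera, key=lambda c: -len(c)), start=1):
        for j, leaf in enumerate(
                sorted(clade, key=lambda l: l.taxon.label), start=1):
            leaf.taxon.label = f"G{k}_s{j}"
    return tree


# environmental response surfaces: MAT linear, MAP Gaussian bump, PET convex.
# Constants give a realistic humid-tropical mountain: ~26 degC sea-level MAT
# with a 5.5 degC/km lapse rate, MAP peaking ~2300 mm at mid elevations, PET
# ~600-1400 mm/yr with an interior minimum.
_MAT_SEA_LEVEL = 26.0
_MAT_LAPSE_PER_M = 0.0055
_MAP_BASE = 800.0
_MAP_AMPLITUDE = 1500.0
_MAP_PEAK_M = 1500.0
_MAP_WIDTH_M = 800.0
_PET_A = 1400.0
_PET_B = 0.9
_PET_C = 0.00025  # vertex (minimum) at B/(2C) = 1800 m


def _mat_of(elev):
    return _MAT_SEA_LEVEL - _MAT_LAPSE_PER_M * np.asarray(elev)


def _map_of(elev):
    e = np.asarray(elev)
    return _MAP_BASE + _MAP_AMPLITUDE * np.exp(-((e - _MAP_PEAK_M) ** 2)
                                               / (2 * _MAP_WIDTH_M ** 2))


def _pet_of(elev):
    e = np.asarray(elev)
    return _PET_A - _PET_B * e + _PET_C * e ** 2


def simulate_environment(design: DesignSpec, jitter_frac: float = 0.01) -> pd.DataFrame:
    """One row per plot with site, elevation, FUI and climate covariates.

    MAT decreases linearly with elevation, MAP is unimodal with an interior
    maximum, PET is convex with an interior minimum; each plot gets Gaussian
    jitter with sd = ``jitter_frac`` x the across-site range of the variable.
    ``PET2`` is PET squared, computed before any scaling. FUI is coded
    OG=1 < DE=2 < SE=3.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    site_mat = _mat_of(design.elevations)
    site_map = _map_of(design.elevations)
    site_pet = _pet_of(design.elevations)
    ranges = {name: float(np.ptp(v)) for name, v in
              (("Temp", site_mat), ("Precip", site_map), ("PET", site_pet))}
    for s in range(design.n_sites):
        for f, level in enumerate(design.fui_levels, start=1):
            for p in range(1, design.plots_per_cell + 1):
                rows.append({
                    "plot": f"S{s + 1}_{level}_P{p}",
                    "site": f"S{s + 1}",
                    "elevation": design.elevations[s],
                    "fui_label": level,
                    "FUI": f,
                    "Temp": site_mat[s] + rng.normal(0, jitter_frac * ranges["Temp"]),
                    "Precip": site_map[s] + rng.normal(0, jitter_frac * ranges["Precip"]),
                    "PET": site_pet[s] + rng.normal(0, jitter_frac * ranges["PET"]),
                })
    env = pd.DataFrame(rows)
    env["PET2"] = env["PET"] ** 2
    return env


def simulate_trait(tree: dendropy.Tree, sigma2: float = 1.0,
                   seed: int = 0, root_value: float = 18.0) -> dict:
    """Brownian-motion thermal optimum (deg C) for every tip.

    Increments along each branch are Normal(0, sigma2 * branch length), summed
    from the root value down; close relatives therefore share similar optima
    (phylogenetic niche conservatism). Deterministic under ``seed``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = np.random.default_rng(seed)
    values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = root_value
        else:
            bl = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, math.sqrt(sigma2 * bl))
    return {leaf.taxon.label: float(values[leaf])
            for leaf in tree.leaf_node_iter()}


@dataclass
class SyntheticStudy:
    """Bundle of generated inputs plus the ground truth used to make them."""

    tree: dendropy.Tree
    environment: pd.DataFrame
    community: pd.DataFrame          # plots x species, incidence or counts
    species: pd.DataFrame            # species, life_form, thermal optimum
    truth: dict                      # betas, site effects, expected richness

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(to_newick(self.tree) + "\n")
        self.environment.to_csv(outdir / "environment.tsv", sep="\t", index=False)
        self.community.to_csv(outdir / "community.tsv", sep="\t",
                              index=True, index_label="plot")
        self.species.to_csv(outdir / "species.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))


def _scale(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def assemble_communities(env: pd.DataFrame, tree: dendropy.Tree,
                         optima: dict, params: AssemblyParams,
                         seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Sample plot communities from the richness model and the niche filter.

    Per plot: richness ``N ~ Poisson(exp(a + sum_k beta_k z_k + u_site))`` with
    ``z_k`` the z-scored covariates; then ``N`` species are drawn without
    replacement with probability proportional to
    ``exp(-filter_strength * (optimum - MAT_plot)^2 / (2 * niche_breadth^2))``.
    Requested richness larger than the pool is capped at the pool size with a
    logged warning. Returns the plots x species table (incidence by default)
    and the truth record.
    """
    rng = np.random.default_rng(seed)
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    missing = [s for s in species if s not in optima]
    if missing:
        raise KeyError(f"optima missing for {missing[:5]}")
    opt = np.array([optima[s] for s in species])
    n_plots = len(env)

    z = {name: _scale(env[name].to_numpy(dtype=float))
         for name in ("Temp", "Precip", "PET", "PET2", "FUI")}
    sites = env["site"].to_numpy()
    site_levels = list(dict.fromkeys(sites))
    site_fx = dict(zip(site_levels,
                       rng.normal(0.0, params.sd_site, size=len(site_levels))))
    eta = np.full(n_plots, params.intercept_log_richness)
    for name, beta in params.beta.items():
        if name not in z:
            raise KeyError(f"unknown path name {name!r} in beta")
        eta += beta * z[name]
    eta += np.array([site_fx[s] for s in sites])
    mu = np.exp(eta)

    richness = rng.poisson(mu)
    capped = richness > len(species)
    if capped.any():
        logger.warning("richness capped at pool size for %d plots",
                       int(capped.sum()))
        richness = np.minimum(richness, len(species))

    mat = env["Temp"].to_numpy(dtype=float)
    table = np.zeros((n_plots, len(species)),
                     dtype=int if not params.abundances else int)
    for i in range(n_plots):
        n_i = int(richness[i])
        if n_i == 0:
            continue
        logw = -params.filter_strength * (opt - mat[i]) ** 2 / (
            2.0 * params.niche_breadth ** 2)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        members = rng.choice(len(species), size=n_i, replace=False, p=w)
        if params.abundances:
            table[i, members] = 1 + rng.poisson(2.0, size=n_i)
        else:
            table[i, members] = 1

    community = pd.DataFrame(table, index=env["plot"].to_numpy(), columns=species)
    truth = {
        "beta": dict(params.beta),
        "intercept_log_richness": params.intercept_log_richness,
        "site_effects": {k: float(v) for k, v in site_fx.items()},
        "expected_richness": {p: float(m) for p, m in
                              zip(env["plot"], mu)},
        "filter_strength": params.filter_strength,
        "niche_breadth": params.niche_breadth,
        "n_capped": int(capped.sum()),
    }
    return community, truth


def _assign_life_forms(species: list, fractions: dict,
                       rng: np.random.Generator) -> list:
    """Deterministic multinomial split with exact largest-remainder counts."""
    n = len(species)
    names = list(fractions)
    raw = np.array([fractions[k] * n for k in names])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    for i in order[:rem]:
        counts[i] += 1
    labels = np.repeat(names, counts)
    rng.shuffle(labels)
    return list(labels)


def simulate_study(design: DesignSpec | None = None,
                   params: AssemblyParams | None = None,
                   birth_rate: float = 1.0, death_rate: float = 0.0,
                   n_genera: int = 60, sigma2_trait: float = 4.0,
                   seed: int = 0) -> SyntheticStudy:
    """Generate the full study: tree, trait, environment, communities, truth.

    Sub-stage seeds are derived from ``seed`` so the whole bundle is
    bit-reproducible; ``sigma2_trait`` (deg C^2 per unit branch length) sets
    how conserved the thermal optimum is and hence how strongly cold-site
    communities cluster phylogenetically.
    """
    design = design or DesignSpec(seed=seed)
    params = params or AssemblyParams()
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    tree = simulate_tree(params.n_species, birth_rate, death_rate,
                         n_genera=min(n_genera, params.n_species), seed=seeds[0])
    design = DesignSpec(design.n_sites, design.elevations, design.fui_levels,
                        design.plots_per_cell, seed=seeds[1])
    env = simulate_environment(design)
    optima = simulate_trait(tree, sigma2=sigma2_trait, seed=seeds[2],
                            root_value=float(np.mean(_mat_of(design.elevations))))
    community, truth = assemble_communities(env, tree, optima, params,
                                            seed=seeds[3])
    rng = np.random.default_rng(seeds[3] + 1)
    species = list(community.columns)
    species_df = pd.DataFrame({
        "species": species,
        "life_form": _assign_life_forms(species, params.life_form_fractions, rng),
        "thermal_optimum": [optima[s] for s in species],
    })
    truth["seed"] = seed
    truth["design"] = {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(design).items()}
    return SyntheticStudy(tree=tree, environment=env, community=community,
                          species=species_df, truth=truth)
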