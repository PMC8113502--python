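"""Synthetic phylogenies, trait tables and abundance tables.

The generator reproduces the statistical structure the analysis assumes: a
gradient with three elevation sites (1000/2000/3000 m), three plots per
site, 20/20/12 species assigned disjointly to sites, 8-10 individuals per
species, and log-normal traits generated under exactly the fitted model —
species effects drawn from MVN(0, tau_phyl^2 rho + tau_ind^2 I) on a Yule
tree, Gaussian plot effects and residuals, and fixed site effects.  Every
draw is reproducible from the config seed, and the generating truth is
returned alongside the table for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import random
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .exceptions import PhyloTraitsError, ValidationError
from .io import SITE_LEVELS, TRAIT_COLUMNS, AbundanceTable, SiteDesign, TraitTable
from .phylo import PhyloCorrelation, phylo_correlation, read_newick

__all__ = [
    "TraitParams",
    "SyntheticConfig",
    "SyntheticDataset",
    "default_trait_params",
    "simulate_tree",
    "simulate_traits",
    "simulate_abundances",
    "simulate_correlated_means",
    "simulate_dataset",
]


@dataclasses.dataclass
class TraitParams:
    """Generating parameters for one trait on the log scale.

    ``alpha0`` is the log-scale mean at the reference site (1000 m); ``beta``
    the contrasts for 2000 m and 3000 m; the taus/sigma the random-effect and
    residual standard deviations.
    """

    alpha0: float
    beta: tuple[float, float]
    tau_plot: float
    tau_phyl: float
    tau_ind: float
    sigma: float

    def __post_init__(self) -> None:
        for k in ("tau_plot", "tau_phyl", "tau_ind", "sigma"):
            if getattr(self, k) < 0:
                raise ValidationError(f"{k} must be >= 0")


def default_trait_params() -> dict[str, TraitParams]:
    """Log-scale generating parameters for the 12 leaf traits.

    Intercepts are logs of typical trait magnitudes for tropical montane
    canopy trees (leaf area ~60 cm^2, SLA ~110 cm^2/g, thickness ~0.25 mm,
    toughness ~1.2 kN/m, DMC ~380 mg/g, N ~20, P ~1.3, Ca ~7, K ~9,
    Mg ~2.5, Al ~0.5 mg/g, N/P ~16).  Site contrasts follow the gradient's
    qualitative trends (SLA, N, Ca and N/P decline with elevation; thickness,
    toughness and DMC increase; K and Al show no clear trend).  Variance
    components emphasise phylogeny for most traits, elevation for SLA,
    thickness and Ca, the independent species effect for thickness and N/P,
    and a large residual for K.
    """
    p = TraitParams
    return {
        "leaf_area": p(4.09, (-0.20, -0.70), 0.08, 0.90, 0.30, 0.25),
        "sla": p(4.70, (-0.25, -0.50), 0.08, 0.25, 0.20, 0.25),
        "thickness": p(-1.39, (0.20, 0.40), 0.05, 0.25, 0.45, 0.20),
        "toughness": p(0.18, (0.15, 0.35), 0.08, 0.50, 0.20, 0.30),
        "dmc": p(5.94, (0.08, 0.15), 0.05, 0.35, 0.15, 0.35),
        "n": p(3.00, (-0.12, -0.30), 0.06, 0.40, 0.15, 0.25),
        "p": p(0.26, (-0.05, -0.10), 0.06, 0.45, 0.15, 0.30),
        "ca": p(1.95, (-0.35, -0.50), 0.10, 0.35, 0.20, 0.40),
        "k": p(2.20, (0.00, 0.05), 0.08, 0.30, 0.10, 0.45),
        "mg": p(0.92, (0.00, 0.10), 0.08, 0.50, 0.15, 0.35),
        "al": p(-0.69, (0.00, 0.00), 0.08, 1.00, 0.20, 0.40),
        "np_ratio": p(2.77, (-0.15, -0.20), 0.05, 0.15, 0.40, 0.35),
    }


@dataclasses.dataclass
class SyntheticConfig:
    """Configuration of the generator; the seed is mandatory."""

    seed: int
    design: SiteDesign = dataclasses.field(default_factory=SiteDesign)
    params: dict[str, TraitParams] = dataclasses.field(default_factory=default_trait_params)
    tree: str | dendropy.Tree | None = None  # fixed Newick; None -> Yule simulation
    abundance_concentration: float = 1.5
    trait_corr: np.ndarray | None = None  # used by simulate_correlated_means
    heavy_tails: bool = False  # t(3)-scaled residuals for robustness experiments


@dataclasses.dataclass
class SyntheticDataset:
    tree: dendropy.Tree
    table: TraitTable
    abundances: AbundanceTable
    truth: dict


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) tree with tips relabelled Species_001.. and depth
    rescaled to 1.

    The pure-birth simulation stops at the n-th speciation event, which
    leaves the last cherry with zero-length terminal branches; a common
    increment of 5% of tree depth is added to every terminal edge (keeping
    the tree ultrametric) so that no two tips are phylogenetically
    identical.
    """
    if n_species < 2:
        raise PhyloTraitsError("need at least 2 species")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=random.Random(int(seed)),
    )
    tree.is_rooted = True
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    bump = 0.05 * depth if depth > 0 else 1.0
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + bump
    depth += bump
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"Species_{i:03d}"
    return tree


def _assign_species(
    tree: dendropy.Tree, design: SiteDesign, seed: int
) -> dict[int, list[str]]:
    """Disjoint species-to-site assignment, randomized over the tree's tips.

    Randomization (seeded) avoids building in a confound between site and
    clade membership; the complete species turnover between sites is kept.
    """
    tips = sorted(t.label for t in tree.taxon_namespace)
    if len(tips) < design.n_species:
        raise PhyloTraitsError(
            f"tree has {len(tips)} tips but design needs {design.n_species} species"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    tips = list(rng.permutation(tips))
    out: dict[int, list[str]] = {}
    start = 0
    for site, k in zip(design.sites, design.species_per_site):
        out[site] = sorted(tips[start : start + k])
        start += k
    return out


def simulate_traits(
    tree: dendropy.Tree, config: SyntheticConfig
) -> tuple[TraitTable, dict]:
    """Generate the individual-level trait table under the model equations.

    Per trait: species effects ~ MVN(0, tau_phyl^2 rho + tau_ind^2 I) over
    all species jointly (one global tree), plot effects ~ Normal(0,
    tau_plot), residuals ~ Normal(0, sigma), y = alpha0 + beta_site +
    effects, trait = exp(y).  Returns the table plus a truth record carrying
    the generating parameters, realized effects and design assignment.
    """
    design = config.design
    species_by_site = _assign_species(tree, design, config.seed)
    all_species = [s for site in design.sites for s in species_by_site[site]]
    rho = phylo_correlation(tree, all_species)
    S = len(all_species)

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 17]))
    # design: plots and per-species replication
    plots_by_site = {
        site: [f"P{site}_{i + 1}" for i in range(design.plots_per_site)]
        for site in design.sites
    }
    all_plots = [p for site in design.sites for p in plots_by_site[site]]
    n_indiv = {
        sp: int(rng.integers(design.individuals_min, design.individuals_max + 1))
        for sp in all_species
    }

    rows: list[dict] = []
    site_of_species = {
        sp: site for site, sps in species_by_site.items() for sp in sps
    }
    tree_counter = 0
    for site in design.sites:
        for sp in species_by_site[site]:
            for _ in range(n_indiv[sp]):
                tree_counter += 1
                rows.append(
                    {
                        "tree_id": f"t{tree_counter:04d}",
                        "species": sp,
                        "plot": plots_by_site[site][
                            int(rng.integers(design.plots_per_site))
                        ],
                        "site": site,
                    }
                )
    base = pd.DataFrame(rows)

    # eigendecomposition of rho, shared by every trait's species-effect draw
    lam, Q = np.linalg.eigh(rho.rho)
    lam = np.clip(lam, 0.0, None)

    sp_index = {sp: i for i, sp in enumerate(all_species)}
    plot_index = {p: i for i, p in enumerate(all_plots)}
    obs_sp = base["species"].map(sp_index).to_numpy()
    obs_plot = base["plot"].map(plot_index).to_numpy()
    obs_site = base["site"].to_numpy()

    truth: dict = {
        "seed": config.seed,
        "species_by_site": species_by_site,
        "n_individuals": n_indiv,
        "params": {},
        "species_effects": {},
        "plot_effects": {},
        "fractions": {},
    }
    for trait in TRAIT_COLUMNS:
        tp = config.params[trait]
        z = rng.standard_normal(S)
        a_sp = (Q * np.sqrt(tp.tau_phyl**2 * lam + tp.tau_ind**2)) @ (Q.T @ z)
        a_plot = rng.normal(0.0, tp.tau_plot, size=len(all_plots))
        if config.heavy_tails:
            eps = rng.standard_t(3, size=len(base)) * tp.sigma / np.sqrt(3.0)
        else:
            eps = rng.normal(0.0, tp.sigma, size=len(base))
        beta_of_site = {design.sites[0]: 0.0}
        beta_of_site.update(dict(zip(design.sites[1:], tp.beta)))
        fixed = tp.alpha0 + np.array([beta_of_site[s] for s in obs_site])
        y = fixed + a_sp[obs_sp] + a_plot[obs_plot] + eps
        base[trait] = np.exp(y)
        truth["params"][trait] = tp
        truth["species_effects"][trait] = a_sp
        truth["plot_effects"][trait] = a_plot
        v_site = float(np.var(fixed))
        comps = np.array(
            [v_site, tp.tau_plot**2, tp.tau_phyl**2, tp.tau_ind**2, tp.sigma**2]
        )
        frac = comps / comps.sum() if comps.sum() > 0 else np.full(5, np.nan)
        truth["fractions"][trait] = dict(
            zip(("site", "plot", "phylogeny", "species", "residual"), frac)
        )
    return TraitTable(base), truth


def simulate_abundances(
    species_by_site: Mapping[int, Sequence[str]],
    seed: int,
    concentration: float = 1.5,
) -> AbundanceTable:
    """Symmetric-Dirichlet basal-area shares per site (sum to 1 per site).

    The default concentration of 1.5 yields the uneven shares typical of
    basal-area distributions; concentration -> infinity approaches equal
    shares.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    rows = []
    for site in sorted(species_by_site):
        sps = list(species_by_site[site])
        if not sps:
            raise ValidationError(f"no species for site {site}")
        shares = (
            np.ones(1)
            if len(sps) == 1
            else rng.dirichlet(np.full(len(sps), float(concentration)))
        )
        rows.extend(
            {"species": sp, "site": site, "abundance": float(w)}
            for sp, w in zip(sps, shares)
        )
    return AbundanceTable(pd.DataFrame(rows))


def simulate_correlated_means(
    n_species: int,
    trait_corr: np.ndarray,
    seed: int,
    traits: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Multivariate-normal species-mean matrix with a target correlation.

    Used to drive trait-network tests with a known edge structure.  Requires
    a symmetric PSD target with unit diagonal and n_species >= 4 (the
    network builder's minimum).
    """
    C = np.asarray(trait_corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("trait_corr must be square")
    if not np.allclose(C, C.T, atol=1e-10) or not np.allclose(np.diag(C), 1.0):
        raise ValidationError("trait_corr must be symmetric with unit diagonal")
    lam, Q = np.linalg.eigh(C)
    if lam[0] < -1e-8:
        raise ValidationError(
            f"trait_corr is not positive semidefinite (min eigenvalue {lam[0]:.3e})"
        )
    if n_species < 4:
        raise ValidationError("need n_species >= 4 for downstream network building")
    k = C.shape[0]
    traits = list(traits) if traits is not None else list(TRAIT_COLUMNS[:k])
    if len(traits) != k:
        raise ValidationError("traits length must match trait_corr dimension")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 43]))
    Z = rng.standard_normal((n_species, k))
    root = (Q * np.sqrt(np.clip(lam, 0.0, None))) @ Q.T
    M = Z @ root
    return pd.DataFrame(
        M, index=[f"Species_{i + 1:03d}" for i in range(n_species)], columns=traits
    )


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full synthetic dataset: tree, trait table, abundances and truth."""
    if config.tree is None:
        tree = simulate_tree(config.design.n_species, config.seed)
    else:
        tree = read_newick(config.tree)
    table, truth = simulate_traits(tree, config)
    abundances = simulate_abundances(
        truth["species_by_site"], config.seed, config.abundance_concentration
    )
    return SyntheticDataset(tree=tree, table=table, abundances=abundances, truth=truth)
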