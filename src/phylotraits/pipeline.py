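"""End-to-end orchestration: run the analysis stages from a config and write
per-stage CSV artifacts, a run manifest and a human-readable report.

Stages (in dependency order): io -> phylo -> {pglmm, rao, pca/tukey,
network}.  The four analysis stages are independent of each other; failure of
one is recorded in the manifest and does not abort the rest.  Every run is
self-describing: the manifest echoes the full config, the seed and package
versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import traceback
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import PhyloTraitsError
from .io import (
    TRAIT_COLUMNS,
    AbundanceTable,
    SiteDesign,
    TraitTable,
    read_abundance_table,
    read_trait_table,
    write_table,
    write_trait_table,
)
from .network import build_network, global_metrics, node_metrics
from .pglmm import PhylogeneticMixedLM, PriorSpec
from .phylo import phylo_correlation, read_newick
from .rao import decompose_all
from .simulate import SyntheticConfig, TraitParams, default_trait_params, simulate_dataset
from .traitspace import pca_traits, species_means, tukey_site_comparison

logger = logging.getLogger(__name__)

ALL_STAGES = ("pglmm", "rao", "pca", "tukey", "network")


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration.

    Either the three input paths or a ``simulate`` block must be present.
    The seed drives both simulation and any stochastic fitting stage.
    """

    outdir: str
    seed: int = 0
    trait_table: str | None = None
    abundance_table: str | None = None
    newick: str | None = None
    simulate: dict | None = None
    stages: tuple[str, ...] = ALL_STAGES
    traits: tuple[str, ...] = TRAIT_COLUMNS
    backend: str = "ml"  # ml | mcmc
    chains: int = 2
    iters: int = 10_000
    warmup: int = 10_000
    target_accept: float = 0.99
    priors: dict = dataclasses.field(default_factory=dict)
    alpha: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        have_inputs = self.trait_table is not None and self.newick is not None
        if not have_inputs and self.simulate is None:
            raise PhyloTraitsError(
                "config must provide either input paths (trait_table, newick, "
                "abundance_table) or a simulate block"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PhyloTraitsError(f"unknown stage(s): {sorted(unknown)}")
        if self.backend not in ("ml", "mcmc"):
            raise PhyloTraitsError(f"backend must be 'ml' or 'mcmc', got {self.backend!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PhyloTraitsError(f"unknown config field(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["traits"] = list(self.traits)
        return d


def _simulate_config(block: dict, seed: int) -> SyntheticConfig:
    block = dict(block or {})
    design_kwargs = block.pop("design", {})
    if "species_per_site" in design_kwargs:
        design_kwargs["species_per_site"] = tuple(design_kwargs["species_per_site"])
    if "sites" in design_kwargs:
        design_kwargs["sites"] = tuple(design_kwargs["sites"])
    params = default_trait_params()
    for trait, kw in (block.pop("params", None) or {}).items():
        kw = dict(kw)
        if "beta" in kw:
            kw["beta"] = tuple(kw["beta"])
        params[trait] = dataclasses.replace(params[trait], **kw)
    return SyntheticConfig(
        seed=block.pop("seed", seed),
        design=SiteDesign(**design_kwargs),
        params=params,
        **block,
    )


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Writes one CSV (or more) per stage plus ``manifest.json``.  A failing
    stage is logged and recorded; independent stages still run.  Raises only
    if every requested stage failed.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("phylotraits").addHandler(log_handler)

    manifest: dict[str, Any] = {
        "package": "phylotraits",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "versions": _library_versions(),
        "stages": {},
        "warnings": [],
    }

    # --- io stage: load or simulate inputs --------------------------------
    if config.simulate is not None:
        sim = simulate_dataset(_simulate_config(config.simulate, config.seed))
        table, abundances, tree = sim.table, sim.abundances, sim.tree
        write_trait_table(table, outdir / "trait_table.csv")
        write_table(abundances.data, outdir / "abundance_table.csv")
        (outdir / "phylogeny.nwk").write_text(
            tree.as_string(schema="newick", suppress_rooting=True)
        )
        _write_truth(sim.truth, outdir / "truth.json")
        manifest["stages"]["simulate"] = {"status": "ok", "n_rows": table.n_individuals}
    else:
        table = read_trait_table(config.trait_table)
        abundances = (
            read_abundance_table(config.abundance_table)
            if config.abundance_table
            else None
        )
        tree = read_newick(config.newick)
        manifest["stages"]["io"] = {"status": "ok", "n_rows": table.n_individuals}

    traits = [t for t in config.traits if t in TRAIT_COLUMNS]

    def _stage(name, fn):
        if name not in config.stages:
            manifest["stages"][name] = {"status": "skipped"}
            return
        t0 = time.time()
        try:
            fn()
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 2),
            }
        except Exception as exc:  # stage isolation: record, continue
            logger.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
            }

    # --- pglmm ------------------------------------------------------------
    def _pglmm():
        frames_species = sorted(table.data["species"].unique())
        rho = phylo_correlation(tree, frames_species)
        param_rows, frac_rows = [], []
        for trait in traits:
            model = PhylogeneticMixedLM.from_trait_table(
                table, trait, rho, priors=PriorSpec(**config.priors)
            )
            if config.backend == "mcmc":
                res = model.fit_mcmc(
                    chains=config.chains,
                    iters=config.iters,
                    warmup=config.warmup,
                    seed=config.seed,
                    target_accept=config.target_accept,
                )
                pt = res.param_table()
                pt.insert(0, "trait", trait)
                param_rows.append(pt)
                if not res.converged:
                    manifest["warnings"].append(
                        f"pglmm[{trait}]: max Rhat {res.diagnostics['max_rhat']:.4f} "
                        "above threshold"
                    )
            else:
                res = model.fit(seed=config.seed)
                pt = res.param_table()
                pt.insert(0, "trait", trait)
                param_rows.append(pt)
            vp = res.variance_partition().to_series()
            frac_rows.append({"trait": trait, **vp.to_dict(), "explained": 1 - vp["residual"]})
        write_table(pd.concat(param_rows, ignore_index=True), outdir / "pglmm_parameters.csv")
        write_table(pd.DataFrame(frac_rows), outdir / "variance_fractions.csv")

    # --- rao --------------------------------------------------------------
    def _rao():
        if abundances is None:
            raise PhyloTraitsError("rao stage needs an abundance table")
        write_table(
            decompose_all(table, abundances, traits=traits),
            outdir / "rao_decomposition.csv",
        )

    # --- pca --------------------------------------------------------------
    def _pca():
        means = species_means(table, list(traits))
        res = pca_traits(means, list(traits))
        write_table(res.loadings_frame().reset_index(names="trait"), outdir / "pca_loadings.csv")
        write_table(res.scores.reset_index(), outdir / "pca_scores.csv")
        write_table(
            pd.DataFrame(
                {
                    "component": [f"PC{i + 1}" for i in range(len(res.explained))],
                    "explained": res.explained,
                }
            ),
            outdir / "pca_explained.csv",
        )

    # --- tukey ------------------------------------------------------------
    def _tukey():
        rows = [tukey_site_comparison(table, t, config.alpha).to_frame() for t in traits]
        write_table(pd.concat(rows, ignore_index=True), outdir / "tukey_letters.csv")

    # --- network ----------------------------------------------------------
    def _network():
        means = species_means(table, list(traits))
        edge_rows, node_rows, glob_rows = [], [], []
        for site in table.sites:
            net = build_network(
                means[means["site"] == site], site=site, alpha=config.alpha, traits=list(traits)
            )
            e = net.edge_list()
            e.insert(0, "site", site)
            edge_rows.append(e)
            nm = node_metrics(net)
            nm.insert(0, "site", site)
            node_rows.append(nm)
            glob_rows.append({"site": site, **global_metrics(net).to_dict()})
        write_table(pd.concat(edge_rows, ignore_index=True), outdir / "network_edges.csv")
        write_table(pd.concat(node_rows, ignore_index=True), outdir / "network_nodes.csv")
        write_table(pd.DataFrame(glob_rows), outdir / "network_global.csv")

    _stage("pglmm", _pglmm)
    _stage("rao", _rao)
    _stage("pca", _pca)
    _stage("tukey", _tukey)
    _stage("network", _network)

    manifest["elapsed_seconds"] = round(time.time() - t_start, 2)
    log_handler.close()
    logging.getLogger("phylotraits").removeHandler(log_handler)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    failed = [k for k, v in manifest["stages"].items() if v.get("status") == "failed"]
    requested = [s for s in config.stages]
    if failed and set(failed) >= set(requested):
        raise PhyloTraitsError(f"all requested stages failed: {failed}")
    return outdir


def _library_versions() -> dict[str, str]:
    import dendropy
    import networkx
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "dendropy": dendropy.__version__,
        "networkx": networkx.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _write_truth(truth: dict, path: Path) -> None:
    out = {
        "seed": truth["seed"],
        "species_by_site": truth["species_by_site"],
        "n_individuals": truth["n_individuals"],
        "params": {k: dataclasses.asdict(v) for k, v in truth["params"].items()},
        "fractions": truth["fractions"],
    }
    path.write_text(json.dumps(out, indent=2, default=str))


# ---------------------------------------------------------------------------
# reporting


def report(results_dir: str | Path) -> str:
    """Markdown summary of a completed run.

    Mirrors the analysis' reporting: per-trait variance fractions,
    within-species shares per site, PC1/PC2 explained variance, and the three
    global network parameters per site.  Sections whose artifacts are missing
    are marked "not run".  Byte-identical for identical results.
    """
    d = Path(results_dir)
    lines = ["# phylotraits run report", ""]

    def _fmt(df: pd.DataFrame) -> str:
        return df.to_string(index=False, float_format=lambda v: f"{v:.3f}")

    lines.append("## Variance partition (per trait)")
    f = d / "variance_fractions.csv"
    if f.exists():
        lines += ["", "```", _fmt(pd.read_csv(f)), "```"]
    else:
        lines.append("_not run_")
    lines.append("")

    lines.append("## Rao decomposition: within-species share (trait x site)")
    f = d / "rao_decomposition.csv"
    if f.exists():
        df = pd.read_csv(f)
        pivot = df.pivot(index="trait", columns="site", values="within_share").reset_index()
        lines += ["", "```", _fmt(pivot), "```"]
    else:
        lines.append("_not run_")
    lines.append("")

    lines.append("## PCA of species-mean traits")
    f = d / "pca_explained.csv"
    if f.exists():
        df = pd.read_csv(f).head(2)
        for _, row in df.iterrows():
            lines.append(
                f"- {row['component']}: {100 * row['explained']:.1f}% of variance"
            )
    else:
        lines.append("_not run_")
    lines.append("")

    lines.append("## Site comparisons (Tukey HSD letters)")
    f = d / "tukey_letters.csv"
    if f.exists():
        df = pd.read_csv(f)
        pivot = df.pivot(index="trait", columns="site", values="letters").reset_index()
        lines += ["", "```", pivot.to_string(index=False), "```"]
    else:
        lines.append("_not run_")
    lines.append("")

    lines.append("## Trait-network parameters (per site)")
    f = d / "network_global.csv"
    if f.exists():
        df = pd.read_csv(f)[
            ["site", "edge_density", "average_path_length", "average_clustering"]
        ]
        lines += ["", "```", _fmt(df), "```"]
    else:
        lines.append("_not run_")
    lines.append("")
    return "\n".join(lines)
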