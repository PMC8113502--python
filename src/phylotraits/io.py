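"""Domain tables, readers/writers and validation.

The package works with three tabular inputs:

* an individual-level trait table (one row per sampled tree) carrying
  twelve leaf traits plus tree/species/plot/site labels,
* a species-abundance table (relative basal-area share per site),
* a Newick phylogeny (handled in :mod:`phylotraits.phylo`).

All tables are plain delimited text (comma by default, tab accepted) and are
held in memory as :class:`pandas.DataFrame` objects wrapped in thin dataclasses
that enforce the package's invariants.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical trait column names, in reporting order.  Units are declared, not
#: converted: leaf_area cm^2, sla cm^2/g, thickness mm, toughness kN/m,
#: dmc mg/g, n/p/ca/k/mg/al mg/g, np_ratio dimensionless.
TRAIT_COLUMNS: tuple[str, ...] = (
    "leaf_area",
    "sla",
    "thickness",
    "toughness",
    "dmc",
    "n",
    "p",
    "ca",
    "k",
    "mg",
    "al",
    "np_ratio",
)

ID_COLUMNS: tuple[str, ...] = ("tree_id", "species", "plot", "site")

#: Elevation levels (m a.s.l.) used as the categorical site predictor.
SITE_LEVELS: tuple[int, ...] = (1000, 2000, 3000)


def normalize_species_label(label: str) -> str:
    """Normalize a species label for matching against phylogeny tip labels.

    Trims, collapses internal whitespace, maps underscores to single spaces and
    lower-cases.  Mega-tree tip labels conventionally use underscores while
    field tables often use spaces; both normalize to the same key.
    """
    s = re.sub(r"[\s_]+", " ", str(label).strip())
    return s.lower()


@dataclasses.dataclass
class TraitTable:
    """Individual-level trait observations.

    ``data`` has the columns of :data:`ID_COLUMNS` followed by
    :data:`TRAIT_COLUMNS`.  Trait cells may be NaN (explicit missing values);
    all non-missing trait values are strictly positive so the log transform is
    defined.  Every plot belongs to exactly one site.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_trait_frame(self.data)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def sites(self) -> list[int]:
        return sorted(self.data["site"].unique())

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    def subset_site(self, site: int) -> pd.DataFrame:
        return self.data[self.data["site"] == site]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitTable):
            return NotImplemented
        return self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))


def _validate_trait_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ID_COLUMNS + TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trait table is missing required columns: {missing}")
    df = df.loc[:, list(ID_COLUMNS + TRAIT_COLUMNS)].copy()
    df["site"] = pd.to_numeric(df["site"], errors="raise")
    bad_sites = sorted(set(df["site"].unique()) - set(SITE_LEVELS))
    if bad_sites:
        raise ValidationError(
            f"unknown site level(s) {bad_sites}; expected one of {list(SITE_LEVELS)}"
        )
    df["site"] = df["site"].astype(int)
    for col in ("tree_id", "species", "plot"):
        df[col] = df[col].astype(str)
    for col in TRAIT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        vals = df[col]
        nonpos = vals.notna() & (vals <= 0)
        if nonpos.any():
            row = int(np.flatnonzero(nonpos.to_numpy())[0])
            raise ValidationError(
                f"trait {col!r} has non-positive value {vals.iloc[row]} at row {row}"
            )
    # each plot label must belong to a single site
    plot_sites = df.groupby("plot")["site"].nunique()
    shared = plot_sites[plot_sites > 1]
    if len(shared):
        raise ValidationError(
            f"plot label(s) {list(shared.index)} appear under more than one site"
        )
    return df


@dataclasses.dataclass
class AbundanceTable:
    """Relative species abundances per site (basal-area shares).

    ``data`` has columns (species, site, abundance); abundances are
    nonnegative.  :meth:`shares` renormalizes over a requested species subset
    so that analyses restricted to the sampled species use weights summing
    to one.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("species", "site", "abundance") if c not in self.data.columns]
        if missing:
            raise SchemaError(f"abundance table is missing required columns: {missing}")
        df = self.data.loc[:, ["species", "site", "abundance"]].copy()
        df["species"] = df["species"].astype(str)
        df["site"] = pd.to_numeric(df["site"], errors="raise").astype(int)
        df["abundance"] = pd.to_numeric(df["abundance"], errors="raise").astype(float)
        if (df["abundance"] < 0).any():
            raise ValidationError("abundances must be nonnegative")
        self.data = df

    def shares(self, site: int, species: Sequence[str]) -> pd.Series:
        """Renormalized abundance shares for ``species`` at ``site``.

        Raises :class:`ValidationError` listing any requested species absent
        from the table at that site.
        """
        sub = self.data[self.data["site"] == site].set_index("species")["abundance"]
        missing = [s for s in species if s not in sub.index]
        if missing:
            raise ValidationError(
                f"species missing from abundance table at site {site}: {missing}"
            )
        w = sub.loc[list(species)].astype(float)
        total = w.sum()
        if total <= 0:
            raise ValidationError(f"abundances at site {site} sum to zero")
        return w / total


@dataclasses.dataclass
class SiteDesign:
    """Sampling design: sites, plots per site, species and replication."""

    sites: tuple[int, ...] = SITE_LEVELS
    plots_per_site: int = 3
    species_per_site: tuple[int, ...] = (20, 20, 12)
    individuals_min: int = 8
    individuals_max: int = 10

    def __post_init__(self) -> None:
        if len(self.species_per_site) != len(self.sites):
            raise ValidationError("species_per_site must match number of sites")
        if min(self.species_per_site) < 2:
            raise ValidationError("need at least 2 species per site")
        if self.plots_per_site < 1 or self.individuals_min < 1:
            raise ValidationError("counts must be positive")
        if self.individuals_min > self.individuals_max:
            raise ValidationError("individuals_min must be <= individuals_max")

    @property
    def n_species(self) -> int:
        return int(sum(self.species_per_site))


def _sniff_sep(path: Path) -> str:
    head = Path(path).open().readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def read_trait_table(path: str | Path, sep: str | None = None) -> TraitTable:
    """Read and validate an individual-level trait table (CSV or TSV)."""
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return TraitTable(df)


def read_abundance_table(path: str | Path, sep: str | None = None) -> AbundanceTable:
    """Read and validate a species-abundance table (CSV or TSV)."""
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    return AbundanceTable(pd.read_csv(path, sep=sep, float_precision="round_trip"))


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    write_table(table.data, path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as CSV with full float precision.

    ``%.17g`` guarantees the write→read round trip recovers doubles exactly,
    comfortably beyond the 12-significant-digit round-trip contract.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def validate_against_tree(table: TraitTable, tree) -> dict[str, list[str]]:
    """Report species present in the table but not the tree and vice versa.

    Matching is case-insensitive with underscore/whitespace normalization.
    Purely a reporting operation; never raises on mismatches.
    """
    tip_labels = [t.label for t in tree.taxon_namespace]
    tips_norm = {normalize_species_label(t): t for t in tip_labels}
    table_norm = {normalize_species_label(s): s for s in table.species}
    only_table = sorted(table_norm[k] for k in table_norm.keys() - tips_norm.keys())
    only_tree = sorted(tips_norm[k] for k in tips_norm.keys() - table_norm.keys())
    return {"unmatched_table_species": only_table, "unmatched_tree_tips": only_tree}


def drop_missing_for_trait(table: TraitTable, trait: str) -> tuple[pd.DataFrame, int]:
    """Per-trait deletion of rows with a missing value in ``trait``.

    Returns the retained rows and the number dropped.  Missingness is handled
    trait by trait, never whole-row, so one missing lab value does not discard
    the individual's other traits.
    """
    if trait not in TRAIT_COLUMNS:
        raise SchemaError(f"unknown trait {trait!r}; expected one of {list(TRAIT_COLUMNS)}")
    keep = table.data[trait].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("trait %s: dropped %d rows with missing values", trait, n_dropped)
    return table.data[keep], n_dropped
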