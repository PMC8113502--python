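"""Rao quadratic entropy and its between-/within-species decomposition.

For a single trait with the half-squared-difference dissimilarity
``d_ij = (x_i - x_j)^2 / 2``, Rao's quadratic entropy
``Q = sum_ij w_i w_j d_ij`` equals the weight-weighted variance of x.  The
community entropy at a site then splits additively (law of total variance)
into the abundance-weighted mean within-species entropy and the entropy of
the species means:

    Q_total = Q_between + Q_within
    Q_within = sum_s p_s Q_s            (individuals weighted equally within s)
    Q_between = Q over species means with weights p_s.

Traits are standardized by their pooled range (max - min over all
individuals of all sites) before the decomposition so that entropies are
comparable across traits and sites.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .exceptions import DesignError, ValidationError
from .io import TRAIT_COLUMNS, AbundanceTable, TraitTable

__all__ = [
    "standardize_by_range",
    "rao_q",
    "decompose",
    "decompose_all",
    "RaoDecomposition",
]


def standardize_by_range(values: np.ndarray, trait: str = "") -> np.ndarray:
    """Divide a pooled trait vector by its range (max - min); order preserved."""
    x = np.asarray(values, dtype=float)
    rng = np.nanmax(x) - np.nanmin(x)
    if not np.isfinite(rng) or rng <= 0:
        raise ValidationError(
            f"trait {trait or '<unnamed>'} has zero range; cannot standardize"
        )
    return x / rng


def rao_q(values: np.ndarray, weights: np.ndarray) -> float:
    """Rao quadratic entropy with d_ij = (x_i - x_j)^2 / 2.

    Identical to the weighted variance sum_i w_i (x_i - xbar_w)^2; computed in
    that form for O(n) cost.  Weights must be nonnegative and sum to 1 within
    1e-8.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValidationError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValidationError(f"weights sum to {w.sum():.10f}, expected 1")
    mu = float(w @ x)
    return float(w @ (x - mu) ** 2)


@dataclasses.dataclass
class RaoDecomposition:
    """Per-(trait, site) entropy decomposition on range-standardized values."""

    trait: str
    site: int
    q_total: float
    q_between: float
    q_within: float

    @property
    def within_share(self) -> float:
        return self.q_within / self.q_total if self.q_total > 0 else np.nan

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "site": self.site,
            "q_total": self.q_total,
            "q_between": self.q_between,
            "q_within": self.q_within,
            "within_share": self.within_share,
        }


def decompose(
    table: TraitTable,
    abundances: AbundanceTable,
    trait: str,
    site: int,
) -> RaoDecomposition:
    """Decompose community entropy for one trait at one site.

    Abundances are renormalized over the species actually sampled for traits
    at the site; a species sampled but absent from the abundance table is an
    error listing the species.  Standardization uses the pooled range across
    all sites so that sites remain comparable.
    """
    df = table.data[table.data[trait].notna()]
    std = standardize_by_range(df[trait].to_numpy(), trait)
    df = df.assign(_x=std)
    sub = df[df["site"] == site]
    species = sorted(sub["species"].unique())
    if len(species) < 2:
        raise DesignError(f"site {site}: need >=2 species with data for {trait!r}")
    p = abundances.shares(site, species).to_numpy()

    q_s = np.empty(len(species))
    means = np.empty(len(species))
    all_vals: list[np.ndarray] = []
    all_w: list[np.ndarray] = []
    for i, sp in enumerate(species):
        x = sub.loc[sub["species"] == sp, "_x"].to_numpy()
        w_eq = np.full(len(x), 1.0 / len(x))
        q_s[i] = rao_q(x, w_eq)
        means[i] = x.mean()
        all_vals.append(x)
        all_w.append(np.full(len(x), p[i] / len(x)))

    q_within = float(p @ q_s)
    q_between = rao_q(means, p)
    q_total = rao_q(np.concatenate(all_vals), np.concatenate(all_w))
    return RaoDecomposition(trait, int(site), q_total, q_between, q_within)


def decompose_all(
    table: TraitTable,
    abundances: AbundanceTable,
    traits: list[str] | None = None,
    sites: list[int] | None = None,
) -> pd.DataFrame:
    """Long-format decomposition over trait x site combinations."""
    traits = traits or list(TRAIT_COLUMNS)
    sites = sites or table.sites
    rows = [decompose(table, abundances, t, s).to_dict() for t in traits for s in sites]
    return pd.DataFrame(rows)
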